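"""Poisson composite-likelihood fitting of demographic models to observed spectra.

theta is profiled analytically (the Poisson MLE given shape is
``theta_hat = sum(observed) / sum(expected at theta = 1)``), which removes one
dimension from the search. Size and time parameters are optimized in log10
space; migration rates in linear space so exact zero is reachable. Multi-start
Nelder-Mead provides the run-to-run scatter that the split-time median/IQR
summaries describe.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from glacialsplit.demog.models import expected_sfs, model_from_id
from glacialsplit.demog.units import UnitSystem, convert_units
from glacialsplit.spectrum import FrequencySpectrum

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = {"nu": (1e-3, 1e2), "t": (1e-4, 10.0), "m": (0.0, 20.0)}
# random multi-start draws come from a moderate interior region; the
# optimizer may still walk to the full bounds
DEFAULT_START_REGION = {"nu": (0.05, 5.0), "t": (5e-3, 1.0), "m": (0.0, 5.0)}

_FLOOR = 1e-300


def _param_kind(name: str) -> str:
    if name.startswith("nu"):
        return "nu"
    if name.startswith("t"):
        return "t"
    if name.startswith("m"):
        return "m"
    raise ValueError(f"cannot classify parameter {name!r}")


def composite_loglik(
    observed: FrequencySpectrum, expected: FrequencySpectrum
) -> tuple[float, float]:
    """Poisson composite log-likelihood and the profiled theta-hat.

    ``expected`` must be at unit theta; the optimal scaling is
    ``theta_hat = sum(obs) / sum(exp)`` over unmasked cells, and
    ``ll = sum n log(theta_hat e) - theta_hat e - log n!``.
    """
    if observed.data.shape != expected.data.shape:
        raise ValueError("observed and expected spectra have different shapes")
    if observed.folded != expected.folded:
        raise ValueError("observed and expected spectra have different folding")
    if not np.array_equal(observed.mask, expected.mask):
        raise ValueError("observed and expected spectra have different masks")
    keep = ~observed.mask
    n = observed.data[keep]
    e = expected.data[keep]
    e_tot = e.sum()
    if e_tot <= 0:
        raise ValueError("expected spectrum has no mass on unmasked cells")
    theta_hat = float(n.sum() / e_tot)
    lam = np.maximum(theta_hat * e, _FLOOR)
    ll = float(np.sum(n * np.log(lam) - lam - gammaln(n + 1)))
    return ll, theta_hat


@dataclass
class FitRun:
    start: dict
    params: dict
    loglik: float
    theta: float
    converged: bool
    n_eval: int
    message: str = ""


@dataclass
class FitResult:
    model_id: str
    sample_sizes: tuple[int, ...]
    folded: bool
    runs: list[FitRun]

    @property
    def converged_runs(self) -> list[FitRun]:
        return [r for r in self.runs if r.converged]

    @property
    def best(self) -> FitRun:
        cand = self.converged_runs or self.runs
        return max(cand, key=lambda r: r.loglik)

    def summary(self) -> dict:
        """Median and 25-75% interquartile range per parameter over converged runs."""
        runs = self.converged_runs
        if not runs:
            raise RuntimeError("no converged optimization runs to summarize")
        out = {}
        names = list(runs[0].params)
        for name in names:
            vals = np.array([r.params[name] for r in runs])
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            out[name] = {"median": float(med), "q25": float(q25), "q75": float(q75)}
        thetas = np.array([r.theta for r in runs])
        q25, med, q75 = np.percentile(thetas, [25, 50, 75])
        out["theta"] = {"median": float(med), "q25": float(q25), "q75": float(q75)}
        return out

    def to_json(self, path) -> None:
        payload = {
            "model_id": self.model_id,
            "sample_sizes": list(self.sample_sizes),
            "folded": self.folded,
            "runs": [dataclasses.asdict(r) for r in self.runs],
            "summary": self.summary() if self.converged_runs else None,
            "best_loglik": self.best.loglik,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def fit_model(
    observed: FrequencySpectrum,
    model_id: str,
    n_starts: int = 50,
    seed: int = 0,
    bounds: dict | None = None,
    init: dict | None = None,
    fixed: dict | None = None,
    oversample: int = 4,
    maxiter: int | None = None,
) -> FitResult:
    """Multi-start bounded Nelder-Mead fit of a demographic model.

    Each start draws parameters log-uniformly (migration: uniformly) within
    bounds, except the first, which uses ``init`` (or model defaults) when
    provided. Runs that fail validation or the optimizer's own convergence
    test are recorded with ``converged=False`` and excluded from summaries.
    Deterministic under a fixed seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    cls = model_from_id(model_id)
    fixed = dict(fixed or {})
    free_names = [p for p in cls.free_params if p not in fixed]
    kinds = [_param_kind(p) for p in free_names]
    bnds = dict(DEFAULT_BOUNDS)
    bnds.update(bounds or {})
    sample_sizes = observed.sample_sizes
    rng = np.random.default_rng(seed)

    def to_internal(values: np.ndarray) -> np.ndarray:
        out = values.copy()
        for k, kind in enumerate(kinds):
            if kind != "m":
                out[k] = np.log10(max(values[k], bnds[kind][0]))
        return out

    def to_natural(internal: np.ndarray) -> np.ndarray:
        out = internal.copy()
        for k, kind in enumerate(kinds):
            if kind != "m":
                out[k] = 10.0 ** internal[k]
        return out

    internal_bounds = []
    for kind in kinds:
        lo, hi = bnds[kind]
        if kind == "m":
            internal_bounds.append((lo, hi))
        else:
            internal_bounds.append((np.log10(lo), np.log10(hi)))

    def objective(internal: np.ndarray) -> float:
        nat = to_natural(internal)
        kwargs = dict(zip(free_names, nat))
        kwargs.update(fixed)
        try:
            model = cls(**kwargs)
            exp = expected_sfs(
                model, sample_sizes, folded=observed.folded, oversample=oversample
            )
            ll, _ = composite_loglik(observed, exp)
        except (ValueError, FloatingPointError):
            return np.inf
        if not np.isfinite(ll):
            return np.inf
        return -ll

    def random_start() -> np.ndarray:
        vals = np.empty(len(free_names))
        for k, kind in enumerate(kinds):
            lo, hi = DEFAULT_START_REGION[kind]
            if kind == "m":
                vals[k] = rng.uniform(lo, hi)
            else:
                vals[k] = rng.uniform(np.log10(lo), np.log10(hi))
        return vals

    starts = []
    if init is not None:
        base = np.array([init.get(p, getattr(cls(), p)) for p in free_names])
        starts.append(np.clip(to_internal(base), *zip(*internal_bounds)))
    while len(starts) < n_starts:
        starts.append(random_start())

    runs: list[FitRun] = []
    for start in starts:
        f0 = objective(start)
        if not np.isfinite(f0):
            start = random_start()
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            bounds=internal_bounds,
            options={
                "xatol": 1e-5,
                "fatol": 1e-8 * max(1.0, abs(f0) if np.isfinite(f0) else 1.0),
                "maxiter": maxiter or 400 * len(free_names),
                "adaptive": True,
            },
        )
        nat = to_natural(np.asarray(res.x))
        kwargs = {k: float(v) for k, v in zip(free_names, nat)}
        kwargs.update(fixed)
        # a run that merely exhausted its iteration budget still ends at a
        # usable point; only non-finite likelihoods or failed evaluations
        # disqualify a run from the across-run summaries
        hit_maxiter = not res.success and "iteration" in str(res.message).lower()
        converged = bool(np.isfinite(res.fun)) and (bool(res.success) or hit_maxiter)
        theta = np.nan
        ll = -float(res.fun)
        if np.isfinite(res.fun):
            try:
                model = cls(**kwargs)
                exp = expected_sfs(
                    model, sample_sizes, folded=observed.folded, oversample=oversample
                )
                ll, theta = composite_loglik(observed, exp)
            except (ValueError, FloatingPointError):
                converged = False
        runs.append(
            FitRun(
                start={k: float(v) for k, v in zip(free_names, to_natural(start))},
                params=kwargs,
                loglik=ll,
                theta=float(theta),
                converged=converged,
                n_eval=int(res.nfev),
                message=str(res.message),
            )
        )
    result = FitResult(model_id, tuple(sample_sizes), observed.folded, runs)
    if not result.converged_runs:
        diag = "; ".join(f"run {k}: {r.message}" for k, r in enumerate(runs))
        raise RuntimeError(f"no optimization run converged ({diag})")
    return result


def summarize_split_times(
    fit: FitResult,
    units: UnitSystem,
    param: str = "t_split",
) -> dict:
    """Median and 25-75% IQR of converted split times across runs, in kya.

    Each run is converted with its own profiled theta (hence its own N_ref),
    then summarized with linear-interpolation quantiles. Fewer than three
    converged runs triggers a warning and the raw per-run values are returned
    unsummarized alongside NaN quantiles.
    """
    runs = fit.converged_runs
    years = []
    for r in runs:
        real = convert_units({param: r.params[param]}, r.theta, units)
        years.append(real[f"{param}_years"])
    kya = np.array(years) / 1000.0
    if len(runs) < 3:
        warnings.warn(
            f"only {len(runs)} converged runs; split-time summary unreliable",
            stacklevel=2,
        )
        return {"median_kya": float("nan"), "q25_kya": float("nan"),
                "q75_kya": float("nan"), "runs_kya": kya.tolist()}
    q25, med, q75 = np.percentile(kya, [25, 50, 75])
    return {
        "median_kya": float(med),
        "q25_kya": float(q25),
        "q75_kya": float(q75),
        "runs_kya": kya.tolist(),
    }
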