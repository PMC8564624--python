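"""Split-with-migration demographic models and their expected joint SFS.

Two model families are provided, mirroring the inference chain for a
three-cluster system (an early-diverging southern lineage plus a recent
split within the remaining cluster):

- ``two_pop_sizechange_split_mig``: an ancestral size change of relative
  magnitude ``nu_anc`` lasting ``t_anc``, followed by a split into daughters
  of sizes ``nu1``/``nu2`` that exchange migrants at scaled rates
  ``m12``/``m21`` for ``t_split`` time units up to the present.
- ``three_pop_two_splits_mig``: the same, with two successive splits — the
  first daughter separates at ``t_split``, the remaining ancestor (size
  ``nu23``) splits again at ``t_split2`` into sizes ``nu2``/``nu3``; all
  extant pairs may exchange migrants.

All quantities are in diffusion units: times in 2*N_ref generations, sizes
relative to N_ref, migration as M = 2*N_ref*m. Spectra are returned at unit
theta and are exactly linear in theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from glacialsplit.demog import engine
from glacialsplit.spectrum import FrequencySpectrum


@dataclass
class TwoPopSizeChangeSplitMig:
    """Ancestral size change + split with bidirectional migration."""

    nu_anc: float = 1.0
    t_anc: float = 0.1
    nu1: float = 1.0
    nu2: float = 1.0
    t_split: float = 0.1
    m12: float = 0.0
    m21: float = 0.0

    model_id = "two_pop_sizechange_split_mig"
    free_params = ("nu_anc", "t_anc", "nu1", "nu2", "t_split", "m12", "m21")
    n_pops = 2

    def validate(self) -> None:
        for name in ("nu_anc", "nu1", "nu2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0 (got {v})")
        for name in ("t_anc", "t_split", "m12", "m21"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v})")

    def param_vector(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in self.free_params])

    @classmethod
    def from_vector(cls, vec) -> "TwoPopSizeChangeSplitMig":
        return cls(**dict(zip(cls.free_params, map(float, vec))))


@dataclass
class ThreePopTwoSplits:
    """Ancestral size change + two successive splits with migration.

    ``nu23`` (size of the ancestor of populations 2 and 3 between the splits)
    and the inter-split migration rates ``m1_23``/``m23_1`` default to ``nu2``
    and ``m12``/``m21`` when left as None; the printed source never states
    them separately.
    """

    nu_anc: float = 1.0
    t_anc: float = 0.1
    nu1: float = 1.0
    nu2: float = 1.0
    nu3: float = 1.0
    t_split: float = 0.2
    t_split2: float = 0.05
    m12: float = 0.0
    m21: float = 0.0
    m13: float = 0.0
    m31: float = 0.0
    m23: float = 0.0
    m32: float = 0.0
    nu23: float | None = None
    m1_23: float | None = None
    m23_1: float | None = None

    model_id = "three_pop_two_splits_mig"
    free_params = (
        "nu_anc", "t_anc", "nu1", "nu2", "nu3", "t_split", "t_split2",
        "m12", "m21", "m13", "m31", "m23", "m32",
    )
    n_pops = 3

    def resolved(self) -> "ThreePopTwoSplits":
        out = ThreePopTwoSplits(**{f.name: getattr(self, f.name) for f in fields(self)})
        out.nu23 = self.nu23 if self.nu23 is not None else self.nu2
        out.m1_23 = self.m1_23 if self.m1_23 is not None else self.m12
        out.m23_1 = self.m23_1 if self.m23_1 is not None else self.m21
        return out

    def validate(self) -> None:
        r = self.resolved()
        for name in ("nu_anc", "nu1", "nu2", "nu3", "nu23"):
            v = getattr(r, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0 (got {v})")
        for name in ("t_anc", "t_split", "t_split2", "m12", "m21", "m13",
                     "m31", "m23", "m32", "m1_23", "m23_1"):
            v = getattr(r, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v})")
        if r.t_split2 > r.t_split:
            raise ValueError("t_split2 must not exceed t_split")

    def param_vector(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in self.free_params])

    @classmethod
    def from_vector(cls, vec) -> "ThreePopTwoSplits":
        return cls(**dict(zip(cls.free_params, map(float, vec))))


_MODELS = {
    TwoPopSizeChangeSplitMig.model_id: TwoPopSizeChangeSplitMig,
    ThreePopTwoSplits.model_id: ThreePopTwoSplits,
}


def model_from_id(model_id: str):
    try:
        return _MODELS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model_id {model_id!r}; available: {sorted(_MODELS)}"
        ) from None


def _one_pop_history(n_tot: int, nu_anc: float, t_anc: float) -> np.ndarray:
    phi = engine.equilibrium_phi(n_tot)
    if t_anc > 0:
        a_op, src = engine.epoch_operator((n_tot,), (nu_anc,))
        phi = engine.integrate_epoch(phi, a_op, src, t_anc)
    return phi


def expected_sfs(
    model,
    sample_sizes: tuple[int, ...],
    folded: bool = False,
    oversample: int = 4,
    pop_ids: tuple[str, ...] | None = None,
) -> FrequencySpectrum:
    """Expected joint SFS at unit theta under a split-with-migration model.

    ``oversample`` integrates the moment system at ``n + oversample`` haploids
    per population and projects down: the jackknife closure error shrinks with
    sample size while hypergeometric projection is exact, so a small buffer
    buys accuracy at modest cost. Sample sizes above 40 haploids per
    population are refused (desk-scale contract).
    """
    if any(n < 2 for n in sample_sizes):
        raise ValueError("need >= 2 haploids per sampled population")
    if any(n > 40 for n in sample_sizes):
        raise ValueError("sample sizes above 40 haploids per population unsupported")
    if oversample < 0:
        raise ValueError("oversample must be >= 0")
    model.validate()
    work_sizes = tuple(n + oversample for n in sample_sizes)

    if model.n_pops == 2:
        if len(sample_sizes) != 2:
            raise ValueError("two-population model needs two sample sizes")
        n1, n2 = work_sizes
        phi = _one_pop_history(n1 + n2, model.nu_anc, model.t_anc)
        phi = engine.split_matrix(n1 + n2, n1, n2) @ phi
        a_op, src = engine.epoch_operator(
            (n1, n2),
            (model.nu1, model.nu2),
            {(0, 1): model.m12, (1, 0): model.m21},
        )
        phi = engine.integrate_epoch(phi, a_op, src, model.t_split)
        data = phi.reshape(n1 + 1, n2 + 1)
    elif model.n_pops == 3:
        if len(sample_sizes) != 3:
            raise ValueError("three-population model needs three sample sizes")
        r = model.resolved()
        n1, n2, n3 = work_sizes
        n23 = n2 + n3
        phi = _one_pop_history(n1 + n23, r.nu_anc, r.t_anc)
        phi = (engine.split_matrix(n1 + n23, n1, n23) @ phi).reshape(n1 + 1, n23 + 1)
        a_op, src = engine.epoch_operator(
            (n1, n23), (r.nu1, r.nu23), {(0, 1): r.m1_23, (1, 0): r.m23_1}
        )
        phi = engine.integrate_epoch(
            phi.ravel(), a_op, src, r.t_split - r.t_split2
        ).reshape(n1 + 1, n23 + 1)
        phi = engine.split_axis(phi, 1, n2, n3)
        a_op, src = engine.epoch_operator(
            (n1, n2, n3),
            (r.nu1, r.nu2, r.nu3),
            {
                (0, 1): r.m12, (1, 0): r.m21,
                (0, 2): r.m13, (2, 0): r.m31,
                (1, 2): r.m23, (2, 1): r.m32,
            },
        )
        phi = engine.integrate_epoch(phi.ravel(), a_op, src, r.t_split2)
        data = phi.reshape(n1 + 1, n2 + 1, n3 + 1)
    else:  # pragma: no cover - model classes fix n_pops
        raise ValueError(f"unsupported number of populations: {model.n_pops}")

    if not np.all(np.isfinite(data)):
        raise FloatingPointError("expected-SFS integration produced non-finite values")
    fs = FrequencySpectrum(data, folded=False, pop_ids=pop_ids)
    if oversample:
        fs = fs.project(sample_sizes)
    # tiny negative ringing from the closure is clipped to keep Poisson
    # likelihoods defined; magnitudes are checked in tests
    fs.data = np.clip(fs.data, 0.0, None)
    if folded:
        fs = fs.fold()
    return fs
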