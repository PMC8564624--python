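"""Transparent SDM learners: penalized quadratic logistic and range envelope.

The ensemble contract (TSS gating, median aggregation, MESS, projection) is
the machinery under test; the member learners are deliberately simple and
fully inspectable:

- ``logistic_quadratic``: L2-penalized logistic regression on standardized
  linear + squared terms of each variable, suitability = predicted
  probability of presence;
- ``range_envelope``: per-variable percentile-distance score
  ``1 - |2 F_v(x) - 1|`` against the presence sample (1 at the presence
  median, 0 at or beyond the presence range), aggregated by the minimum
  across variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from glacialsplit.sdm.raster import EnvStack, Raster

logger = logging.getLogger(__name__)

LEARNER_KINDS = ("logistic_quadratic", "range_envelope")


@dataclass
class Member:
    """A fitted ensemble member with its cross-evaluation skill."""

    kind: str
    var_names: list[str]
    params: dict = field(default_factory=dict)
    tss: float = float("nan")
    threshold: float = 0.5

    def predict(self, x_mat: np.ndarray) -> np.ndarray:
        x_mat = np.asarray(x_mat, dtype=float)
        if x_mat.shape[1] != len(self.var_names):
            raise ValueError("predictor count mismatch")
        if self.kind == "logistic_quadratic":
            used = self.params["used"]
            mean, scale = self.params["mean"], self.params["scale"]
            z = (x_mat[:, used] - mean) / scale
            feats = np.concatenate([z, z**2], axis=1)
            lin = feats @ self.params["coef"] + self.params["intercept"]
            return 1.0 / (1.0 + np.exp(-lin))
        if self.kind == "range_envelope":
            refs = self.params["presence_values"]
            score = np.ones(len(x_mat))
            for v, ref in enumerate(refs):
                f = np.searchsorted(ref, x_mat[:, v], side="left") + 0.5 * (
                    np.searchsorted(ref, x_mat[:, v], side="right")
                    - np.searchsorted(ref, x_mat[:, v], side="left")
                )
                f = f / len(ref)
                sv = 1.0 - np.abs(2.0 * f - 1.0)
                outside = (x_mat[:, v] < ref[0]) | (x_mat[:, v] > ref[-1])
                sv[outside] = 0.0
                score = np.minimum(score, sv)
            return score
        raise ValueError(f"unknown learner kind {self.kind!r}")

    def to_dict(self) -> dict:
        """JSON-serializable member (arrays become lists)."""
        params = {}
        for key, val in self.params.items():
            if key == "presence_values":
                params[key] = [np.asarray(v).tolist() for v in val]
            elif isinstance(val, np.ndarray):
                params[key] = np.asarray(val).tolist()
            else:
                params[key] = val
        return {"kind": self.kind, "var_names": list(self.var_names),
                "params": params, "tss": self.tss, "threshold": self.threshold}

    @classmethod
    def from_dict(cls, payload: dict) -> "Member":
        params = dict(payload["params"])
        if "presence_values" in params:
            params["presence_values"] = [np.asarray(v) for v in params["presence_values"]]
        for key in ("used", "mean", "scale", "coef"):
            if key in params:
                params[key] = np.asarray(params[key])
        if "used" in params:
            params["used"] = params["used"].astype(int)
        return cls(payload["kind"], list(payload["var_names"]), params,
                   tss=payload.get("tss", float("nan")),
                   threshold=payload.get("threshold", 0.5))

    def predict_raster(self, env: EnvStack) -> Raster:
        suit = np.full(env.grid.shape, np.nan)
        suit[env.mask] = self.predict(env.table())
        return Raster(suit, x0=env.grid.x0, y0=env.grid.y0,
                      cell=env.grid.cell, name=f"suitability_{self.kind}")


def fit_learner(
    kind: str,
    presences: np.ndarray,
    background: np.ndarray,
    env: EnvStack,
    min_presences: int = 20,
) -> Member:
    """Fit one member on presence/background points over an EnvStack.

    Zero-variance predictors are dropped with a warning (logistic learner).
    """
    if kind not in LEARNER_KINDS:
        raise ValueError(f"kind must be one of {LEARNER_KINDS}")
    presences = np.atleast_2d(presences)
    if len(presences) < min_presences:
        raise ValueError(f"need >= {min_presences} presences (got {len(presences)})")
    x_pres = env.extract(presences[:, 0], presences[:, 1])
    if kind == "range_envelope":
        refs = [np.sort(x_pres[:, v]) for v in range(x_pres.shape[1])]
        return Member(kind, env.var_names, {"presence_values": refs})
    x_back = env.extract(background[:, 0], background[:, 1])
    x_mat = np.concatenate([x_pres, x_back])
    y = np.concatenate([np.ones(len(x_pres)), np.zeros(len(x_back))])
    var = x_mat.var(axis=0)
    used = np.flatnonzero(var > 0)
    if len(used) < x_mat.shape[1]:
        dropped = [env.var_names[v] for v in range(x_mat.shape[1]) if v not in used]
        logger.warning("dropping zero-variance predictors: %s", dropped)
    if len(used) == 0:
        raise ValueError("no informative predictors")
    mean = x_mat[:, used].mean(axis=0)
    scale = np.sqrt(x_mat[:, used].var(axis=0))
    z = (x_mat[:, used] - mean) / scale
    feats = np.concatenate([z, z**2], axis=1)
    clf = LogisticRegression(C=1.0, max_iter=2000)
    clf.fit(feats, y)
    return Member(
        kind,
        env.var_names,
        {
            "used": used,
            "mean": mean,
            "scale": scale,
            "coef": clf.coef_.ravel(),
            "intercept": float(clf.intercept_[0]),
        },
    )


def max_tss(scores: np.ndarray, labels: np.ndarray, n_grid: int = 101):
    """Max of (sensitivity + specificity - 1) over an evenly spaced threshold grid.

    Returns (tss, threshold). Invariant to strictly monotone transforms of
    the score up to grid resolution.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("evaluation set needs both classes")
    thresholds = np.linspace(0.0, 1.0, n_grid)
    pos, neg = scores[labels], scores[~labels]
    best_tss, best_thr = -1.0, 0.5
    for thr in thresholds:
        sens = np.mean(pos >= thr)
        spec = np.mean(neg < thr)
        tss = sens + spec - 1.0
        if tss > best_tss:
            best_tss, best_thr = float(tss), float(thr)
    return best_tss, best_thr
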