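"""Cross-evaluation, TSS gating and median ensembles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glacialsplit.sdm.learners import Member, fit_learner, max_tss
from glacialsplit.sdm.occurrences import OccurrenceSet
from glacialsplit.sdm.raster import EnvStack, Raster


def cross_evaluate(
    kind: str,
    occ: OccurrenceSet,
    env: EnvStack,
    split: float = 0.70,
    repeats: int = 2,
    seed: int = 0,
) -> list[dict]:
    """Repeated random 70/30 calibration/validation evaluation of one learner.

    Each repeat independently splits presences and background, fits on the
    calibration fraction and scores the validation fraction with the max-TSS
    statistic. A validation fold lacking either class invalidates that repeat
    (flagged, not silently skipped).
    """
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(repeats):
        rec: dict = {"repeat": rep, "valid": True}
        idx_p = rng.permutation(len(occ.presence))
        idx_b = rng.permutation(len(occ.background))
        n_cal_p = int(round(split * len(idx_p)))
        n_cal_b = int(round(split * len(idx_b)))
        val_p = occ.presence[idx_p[n_cal_p:]]
        val_b = occ.background[idx_b[n_cal_b:]]
        if len(val_p) == 0 or len(val_b) == 0:
            rec.update(valid=False, reason="validation fold lacks a class")
            out.append(rec)
            continue
        member = fit_learner(
            kind, occ.presence[idx_p[:n_cal_p]], occ.background[idx_b[:n_cal_b]], env
        )
        scores = np.concatenate(
            [
                member.predict(env.extract(val_p[:, 0], val_p[:, 1])),
                member.predict(env.extract(val_b[:, 0], val_b[:, 1])),
            ]
        )
        labels = np.concatenate([np.ones(len(val_p)), np.zeros(len(val_b))])
        tss, thr = max_tss(scores, labels)
        rec.update(tss=tss, threshold=thr)
        out.append(rec)
    return out


def evaluate_and_finalize(
    kind: str, occ: OccurrenceSet, env: EnvStack,
    split: float = 0.70, repeats: int = 2, seed: int = 0,
) -> Member:
    """Cross-evaluate, then refit on the entire occurrence dataset.

    The member's TSS is the mean over valid repeats and its threshold the
    mean max-TSS threshold; the final coefficients use all occurrences.
    """
    evals = [e for e in cross_evaluate(kind, occ, env, split, repeats, seed) if e["valid"]]
    if not evals:
        raise ValueError("no valid cross-evaluation repeat")
    member = fit_learner(kind, occ.presence, occ.background, env)
    member.tss = float(np.mean([e["tss"] for e in evals]))
    member.threshold = float(np.mean([e["threshold"] for e in evals]))
    return member


@dataclass
class SDMEnsemble:
    """TSS-gated member set aggregated by the cell-wise median."""

    members: list[Member]
    gate: float = 0.8

    def __post_init__(self) -> None:
        self.passing = [m for m in self.members if m.tss >= self.gate]
        if not self.passing:
            raise ValueError(
                f"no member reaches the TSS gate {self.gate}; "
                f"member TSS: {[round(m.tss, 3) for m in self.members]}"
            )

    @property
    def var_names(self) -> list[str]:
        return self.passing[0].var_names

    @property
    def threshold(self) -> float:
        """Binary-map threshold: mean of passing members' max-TSS thresholds."""
        return float(np.mean([m.threshold for m in self.passing]))

    def predict(self, x_mat: np.ndarray) -> np.ndarray:
        return np.median([m.predict(x_mat) for m in self.passing], axis=0)

    def predict_raster(self, env: EnvStack) -> Raster:
        if env.var_names != self.var_names:
            missing = set(self.var_names) - set(env.var_names)
            raise ValueError(
                f"slice variables {env.var_names} do not match training "
                f"variables {self.var_names}"
                + (f" (missing: {sorted(missing)})" if missing else "")
            )
        suit = np.full(env.grid.shape, np.nan)
        suit[env.mask] = self.predict(env.table())
        return Raster(suit, x0=env.grid.x0, y0=env.grid.y0,
                      cell=env.grid.cell, name="ensemble_suitability")


def build_ensemble(members: list[Member], gate: float = 0.8) -> SDMEnsemble:
    """Gate members by cross-evaluation TSS >= gate and aggregate by median."""
    if not members:
        raise ValueError("need at least one member")
    return SDMEnsemble(members, gate=gate)


def save_ensemble(ensemble: SDMEnsemble, path) -> None:
    import json

    payload = {"gate": ensemble.gate,
               "members": [m.to_dict() for m in ensemble.members]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_ensemble(path) -> SDMEnsemble:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    members = [Member.from_dict(m) for m in payload["members"]]
    return SDMEnsemble(members, gate=payload["gate"])
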