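"""Joint site-frequency-spectrum container and dadi-style ``.fs`` text I/O.

A :class:`FrequencySpectrum` holds a d-dimensional array (d in 1..3) of site
counts (or expected densities) indexed by the derived/minor allele count in
each population, together with a boolean exclusion mask and a folded flag.
The absorbing corners — all-ancestral and all-derived — carry no information
about segregating variation and are always masked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln


def _corner_mask(shape: tuple[int, ...]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(0 for _ in shape)] = True
    mask[tuple(s - 1 for s in shape)] = True
    return mask


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """Matrix mapping a size-``n_from`` spectrum axis to size ``n_to`` < n_from.

    Entry [a, i] is the probability that a subsample of ``n_to`` haploids drawn
    without replacement from ``n_from`` haploids of which ``i`` carry the
    derived allele contains exactly ``a`` derived copies.
    """
    if not 0 < n_to <= n_from:
        raise ValueError("projection requires 0 < n_to <= n_from")
    i = np.arange(n_from + 1)[None, :]
    a = np.arange(n_to + 1)[:, None]
    with np.errstate(invalid="ignore"):
        logp = _log_comb(i, a) + _log_comb(n_from - i, n_to - a) - _log_comb(n_from, n_to)
    p = np.exp(logp)
    p[(a > i) | (n_to - a > n_from - i)] = 0.0
    return p


@dataclass
class FrequencySpectrum:
    """Site counts indexed by per-population derived/minor allele count.

    Parameters
    ----------
    data:
        Array of shape ``(n_1 + 1, ..., n_d + 1)`` for haploid sample sizes
        ``n_k``.
    mask:
        Boolean array of the same shape; ``True`` cells are excluded from any
        likelihood. The two absorbing corners are forced to ``True``.
    folded:
        Whether entries are indexed by minor-allele configuration (canonical
        half-lattice) rather than derived-allele count.
    pop_ids:
        Optional population labels, one per axis.
    """

    data: np.ndarray
    folded: bool = False
    mask: np.ndarray | None = None
    pop_ids: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (1, 2, 3):
            raise ValueError("spectrum must have 1-3 population axes")
        if self.mask is None:
            self.mask = _corner_mask(self.data.shape)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
            self.mask |= _corner_mask(self.data.shape)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")
        if self.pop_ids is not None:
            self.pop_ids = tuple(self.pop_ids)
            if len(self.pop_ids) != self.data.ndim:
                raise ValueError("one pop_id per axis required")

    # ------------------------------------------------------------------ basic
    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(s - 1 for s in self.data.shape)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def total(self) -> float:
        """Total count over unmasked cells."""
        return float(self.data[~self.mask].sum())

    def copy(self) -> "FrequencySpectrum":
        return FrequencySpectrum(
            self.data.copy(), folded=self.folded, mask=self.mask.copy(), pop_ids=self.pop_ids
        )

    # ---------------------------------------------------------------- folding
    def _canonical(self, idx: tuple[int, ...]) -> bool:
        comp = tuple(n - i for n, i in zip(self.sample_sizes, idx))
        d, dc = sum(idx), sum(comp)
        if d != dc:
            return d < dc
        return idx <= comp

    def fold(self) -> "FrequencySpectrum":
        """Fold onto the canonical minor-allele half-lattice.

        Each cell is merged with its complement (the configuration obtained by
        swapping allele labels at every population); the member with the
        smaller total derived count (ties: lexicographically smaller index) is
        canonical. Total unmasked count is conserved and folding is
        idempotent.
        """
        if self.folded:
            return self.copy()
        out = np.zeros_like(self.data)
        outmask = np.ones_like(self.mask)
        ns = self.sample_sizes
        for idx in itertools.product(*(range(s) for s in self.data.shape)):
            if not self._canonical(idx):
                continue
            comp = tuple(n - i for n, i in zip(ns, idx))
            if self.mask[idx] and self.mask[comp]:
                continue
            val = 0.0
            if not self.mask[idx]:
                val += self.data[idx]
            if comp != idx and not self.mask[comp]:
                val += self.data[comp]
            out[idx] = val
            outmask[idx] = False
        return FrequencySpectrum(out, folded=True, mask=outmask, pop_ids=self.pop_ids)

    # ------------------------------------------------------------- projection
    def project(self, new_sizes: tuple[int, ...]) -> "FrequencySpectrum":
        """Project to smaller haploid sample sizes by hypergeometric averaging.

        Only defined for unfolded spectra (fold after projecting if needed).
        Masked cells are treated as zero; corners of the result are masked.
        """
        if self.folded:
            raise ValueError("project unfolded spectra, then fold")
        if len(new_sizes) != self.ndim:
            raise ValueError("one target size per axis")
        data = np.where(self.mask, 0.0, self.data)
        for ax, (n_from, n_to) in enumerate(zip(self.sample_sizes, new_sizes)):
            if n_to == n_from:
                continue
            pm = hypergeom_projection_matrix(n_from, n_to)
            data = np.tensordot(pm, data, axes=(1, ax))
            data = np.moveaxis(data, 0, ax)
        return FrequencySpectrum(data, folded=False, pop_ids=self.pop_ids)

    # ------------------------------------------------------------------- I/O
    def to_file(self, path) -> None:
        """Write in the dadi-style ``.fs`` plain-text format."""
        shape = " ".join(str(s) for s in self.data.shape)
        fold = "folded" if self.folded else "unfolded"
        header = f"{shape} {fold}"
        if self.pop_ids is not None:
            header += " " + " ".join(f'"{p}"' for p in self.pop_ids)
        lines = [
            header,
            " ".join(repr(float(v)) for v in self.data.ravel()),
            " ".join("1" if m else "0" for m in self.mask.ravel()),
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "FrequencySpectrum":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        if len(lines) < 2:
            raise ValueError(f"malformed .fs file: {path}")
        tokens = lines[0].split()
        shape, rest = [], []
        for tok in tokens:
            if tok.isdigit() and not rest:
                shape.append(int(tok))
            else:
                rest.append(tok)
        if not rest or rest[0] not in ("folded", "unfolded"):
            raise ValueError(f"missing folded/unfolded flag in {path}")
        folded = rest[0] == "folded"
        pop_ids = tuple(t.strip('"') for t in rest[1:]) or None
        data = np.array([float(v) for v in lines[1].split()]).reshape(shape)
        mask = None
        if len(lines) > 2:
            mask = np.array([t == "1" for t in lines[2].split()]).reshape(shape)
        return cls(data, folded=folded, mask=mask, pop_ids=pop_ids)
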