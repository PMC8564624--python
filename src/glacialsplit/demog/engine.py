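"""Deterministic moment-system integrator for the expected joint SFS.

The expected sample SFS of a Wright-Fisher diffusion is a set of Bernstein
moments of the population allele-frequency density: for haploid sample size
``n``, entry ``i`` is ``Phi(i) = E[C(n,i) x^i (1-x)^(n-i)]``. Applying the
diffusion generator to the Bernstein basis yields a closed linear ODE system
for drift and mutation; migration couples a population's moments to moments
one sample larger in the source population, which are closed with a quadratic
jackknife (local quadratic approximation of the frequency density).

Time is measured in units of 2*N_ref generations, sizes as ratios nu = N/N_ref
and migration as M = 2*N_ref*m, matching diffusion-based SFS software
conventions. The mutation source injects theta/2 per haploid sample per unit
time at the singleton entry of each population, so the single-population
equilibrium is exactly Phi(i) = theta/i.

Numerical accuracy is pinned by tests to the closed-form equilibrium and to
coalescent simulation, not to any external SFS package.
"""

from __future__ import annotations

import functools
import math

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply
from scipy.special import gammaln

from glacialsplit.spectrum import hypergeom_projection_matrix


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@functools.lru_cache(maxsize=None)
def drift_matrix(n: int) -> sp.csr_matrix:
    """Tridiagonal drift operator on a size-``n`` spectrum (1/(2 nu) scaling applied later).

    Row ``i``: ``(i-1)(n-i+1) Phi[i-1] - 2 i (n-i) Phi[i] + (i+1)(n-i-1) Phi[i+1]``.
    The absorbing corners decouple: rows 1 and n-1 carry zero coefficients for
    the corner entries.
    """
    rows, cols, vals = [], [], []
    for i in range(n + 1):
        if i >= 1:
            rows.append(i), cols.append(i - 1), vals.append((i - 1) * (n - i + 1))
        rows.append(i), cols.append(i), vals.append(-2 * i * (n - i))
        if i <= n - 1:
            rows.append(i), cols.append(i + 1), vals.append((i + 1) * (n - i - 1))
    return sp.csr_matrix((vals, (rows, cols)), shape=(n + 1, n + 1), dtype=float)


@functools.lru_cache(maxsize=None)
def bernstein_power_moments(n: int) -> np.ndarray:
    """G[k, p] = integral of C(n,k) x^k (1-x)^(n-k) x^p dx for p = 0, 1, 2."""
    k = np.arange(n + 1, dtype=float)
    out = np.empty((n + 1, 3))
    for p in range(3):
        logv = (
            _log_comb(n, k)
            + gammaln(k + p + 1)
            + gammaln(n - k + 1)
            - gammaln(n + p + 2)
        )
        out[:, p] = np.exp(logv)
    return out


@functools.lru_cache(maxsize=None)
def jackknife_matrix(n: int) -> np.ndarray:
    """Quadratic-closure matrix mapping a size-``n`` spectrum to size ``n+1``.

    For each target entry the frequency density is approximated by a quadratic
    polynomial fitted to three consecutive size-``n`` entries bracketing the
    target frequency; both source and target entries are exact linear
    functionals of the quadratic's coefficients.
    """
    if n < 2:
        raise ValueError("jackknife closure needs sample size >= 2")
    g_n = bernstein_power_moments(n)
    g_n1 = bernstein_power_moments(n + 1)
    jk = np.zeros((n + 2, n + 1))
    for tgt in range(n + 2):
        xstar = tgt / (n + 1)
        i0 = min(max(int(round(xstar * n)), 1), n - 1)
        src = [i0 - 1, i0, i0 + 1]
        m3 = g_n[src, :]  # (3 sources) x (3 powers)
        weights = np.linalg.solve(m3.T, g_n1[tgt, :])
        jk[tgt, src] = weights
    return jk


@functools.lru_cache(maxsize=None)
def _migration_factors(n_recv: int, n_src: int):
    """Per-axis matrices for the ordered migration pair (receiver, source).

    The generator term M * (y - x) d/dx applied to the Bernstein basis splits
    into a receiver-only part ``x d/dx`` (matrix X) and a cross part built
    from the Bernstein derivative (matrix A on the receiving axis, one sample
    down) and frequency-weighting on the source axis (one sample up, via the
    jackknife).
    """
    nr, ns_ = n_recv, n_src
    # X[i, :]: E[x d/dx b_i] = i*Phi[i] - (i+1)*Phi[i+1]
    x_mat = np.zeros((nr + 1, nr + 1))
    for i in range(nr + 1):
        x_mat[i, i] = i
        if i + 1 <= nr:
            x_mat[i, i + 1] = -(i + 1)
    # E: d/dx b_i = n (b'_{i-1} - b'_i) on the size nr-1 basis
    e_mat = np.zeros((nr + 1, nr))
    for i in range(nr + 1):
        if 0 <= i - 1 <= nr - 1:
            e_mat[i, i - 1] += nr
        if i <= nr - 1:
            e_mat[i, i] -= nr
    proj = hypergeom_projection_matrix(nr, nr - 1)  # (nr, nr+1)
    a_recv = e_mat @ proj  # (nr+1, nr+1)
    # Y: y b_j = (j+1)/(ns+1) b''_{j+1} on the size ns+1 basis
    y_mat = np.zeros((ns_ + 1, ns_ + 2))
    for j in range(ns_ + 1):
        y_mat[j, j + 1] = (j + 1) / (ns_ + 1)
    b_src = y_mat @ jackknife_matrix(ns_)  # (ns+1, ns+1)
    return sp.csr_matrix(a_recv), sp.csr_matrix(b_src), sp.csr_matrix(x_mat)


def _place(shape: tuple[int, ...], ops: dict[int, sp.spmatrix]) -> sp.csr_matrix:
    """Kronecker-embed per-axis operators (identity on unnamed axes), C-order."""
    out = None
    for ax, dim in enumerate(shape):
        mat = ops.get(ax, sp.identity(dim, format="csr"))
        out = mat if out is None else sp.kron(out, mat, format="csr")
    return out


def epoch_operator(
    sample_sizes: tuple[int, ...],
    nus: tuple[float, ...],
    migration: dict[tuple[int, int], float] | None = None,
    theta: float = 1.0,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Constant-coefficient generator ``dPhi/dtau = A Phi + s`` for one epoch.

    ``migration[(a, b)]`` is the scaled rate ``M_ab = 2 N_ref m_ab`` of lineage
    flow into population ``a`` from population ``b`` (forward time). Columns of
    the two absorbing corners are zeroed: fixed/lost sites never feed back into
    segregating entries.
    """
    migration = migration or {}
    shape = tuple(n + 1 for n in sample_sizes)
    size = int(np.prod(shape))
    a_op = sp.csr_matrix((size, size))
    for ax, (n, nu) in enumerate(zip(sample_sizes, nus)):
        if nu <= 0:
            raise ValueError("population size ratios must be positive")
        a_op = a_op + _place(shape, {ax: drift_matrix(n)}) / (2.0 * nu)
    for (a, b), m_ab in migration.items():
        if m_ab < 0:
            raise ValueError("migration rates must be non-negative")
        if m_ab == 0 or a == b:
            continue
        a_recv, b_src, x_recv = _migration_factors(sample_sizes[a], sample_sizes[b])
        a_op = a_op + m_ab * (_place(shape, {a: a_recv, b: b_src}) - _place(shape, {a: x_recv}))
    a_op = a_op.tolil()
    a_op[:, 0] = 0.0
    a_op[:, size - 1] = 0.0
    a_op = a_op.tocsr()
    source = np.zeros(size)
    for ax, n in enumerate(sample_sizes):
        idx = np.ravel_multi_index(
            tuple(1 if k == ax else 0 for k in range(len(shape))), shape
        )
        source[idx] = n * theta / 2.0
    return a_op, source


def integrate_epoch(
    phi: np.ndarray, a_op: sp.csr_matrix, source: np.ndarray, duration: float
) -> np.ndarray:
    """Propagate ``dPhi/dtau = A Phi + s`` for ``duration`` time units.

    Uses the exact matrix exponential of the affine-augmented system, so long
    epochs and stiff drift scales need no step-size control.
    """
    if not math.isfinite(duration) or duration < 0:
        raise ValueError("epoch duration must be finite and >= 0")
    if duration == 0:
        return phi.copy()
    n = a_op.shape[0]
    aug = sp.bmat(
        [
            [a_op * duration, sp.csr_matrix(source[:, None] * duration)],
            [sp.csr_matrix((1, n)), sp.csr_matrix((1, 1))],
        ],
        format="csc",
    )
    norm = float(np.abs(aug).sum(axis=1).max())
    if n <= 1600 and norm > 60.0:
        # dense scaling-and-squaring: cost grows only logarithmically with the
        # operator norm, which matters for stiff epochs (tiny nu, long t)
        z = scipy.linalg.expm(aug.toarray()) @ np.append(phi, 1.0)
    else:
        z = expm_multiply(aug, np.append(phi, 1.0))
    return z[:-1]


def equilibrium_phi(n: int, theta: float = 1.0) -> np.ndarray:
    """Standard neutral single-population equilibrium: Phi(i) = theta / i."""
    phi = np.zeros(n + 1)
    phi[1:n] = theta / np.arange(1, n)
    return phi


@functools.lru_cache(maxsize=None)
def split_matrix(n: int, n1: int, n2: int) -> np.ndarray:
    """Redistribute a size-``n`` spectrum over two daughter samples (n1, n2).

    Both daughters inherit the ancestral frequency x, so
    ``Phi2(i, j) = C(n1,i) C(n2,j) / C(n,i+j) * Phi1(i+j)``.
    Rows are C-order flattened (i, j) cells.
    """
    if n1 + n2 != n:
        raise ValueError("daughter sample sizes must sum to the ancestral size")
    mat = np.zeros(((n1 + 1) * (n2 + 1), n + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            w = math.exp(_log_comb(n1, i) + _log_comb(n2, j) - _log_comb(n, i + j))
            mat[i * (n2 + 1) + j, i + j] = w
    return mat


def split_axis(phi: np.ndarray, axis: int, n1: int, n2: int) -> np.ndarray:
    """Split one axis of a joint spectrum into two populations."""
    n = phi.shape[axis] - 1
    s_mat = split_matrix(n, n1, n2)
    out = np.tensordot(s_mat, phi, axes=(1, axis))  # new flat axis first
    out = np.moveaxis(out, 0, axis)
    new_shape = phi.shape[:axis] + (n1 + 1, n2 + 1) + phi.shape[axis + 1 :]
    return out.reshape(new_shape)
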