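"""Batched spectral solver for symmetrizable birth-death generators.

A tridiagonal generator with strictly positive nearest-neighbour rates obeys
detailed balance and can be symmetrized by the diagonal similarity
D K D^-1 with d_{i+1}/d_i = sqrt(b_i / f_i), giving a symmetric tridiagonal
matrix with off-diagonals sqrt(f_i b_i).  Its eigendecomposition yields
P(t) = D^-1 V exp(L t) V^T D P(0) for all times at once, which is the fast
path used by the experiment forward models (the general propagator in
:mod:`.master_equation` uses the matrix exponential instead).

Because only a handful of linear functionals of P(t) are ever needed
(survival, bound fraction, a single state's occupancy), the eigensolver
accepts a small set of projection rows M and returns M V rather than the
full eigenvector matrix: the QL rotations are accumulated on M directly,
reducing the per-matrix cost from O(n^3) to O(r n^2).

The numba-compiled kernel (a standard implicitly shifted QL iteration for
symmetric tridiagonal matrices) is used when numba imports cleanly; a dense
numpy fallback with identical semantics is kept both as a safety net and as
the independent oracle for the kernel's tests.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["eigh_tridiagonal_projected", "block_response"]

_EPS = np.finfo(np.float64).eps
_BIG = 1e150


def _pythag(a: float, b: float) -> float:
    """sqrt(a^2 + b^2) without overflow for |a|, |b| up to ~1e300."""
    a = abs(a)
    b = abs(b)
    if a < b:
        a, b = b, a
    if a == 0.0:
        return 0.0
    if a < _BIG:
        return math.sqrt(a * a + b * b)
    t = b / a
    return a * math.sqrt(1.0 + t * t)


def _tql2_project_py(d_in, e_in, M, w, P, e):  # numba source; e is workspace
    n = d_in.shape[0]
    r = M.shape[0]
    for i in range(n):
        w[i] = d_in[i]
    for i in range(n - 1):
        e[i] = e_in[i]
    e[n - 1] = 0.0
    for i in range(r):
        for j in range(n):
            P[i, j] = M[i, j]
    for l in range(n):
        it = 0
        while True:
            m = l
            while m < n - 1:
                dd = abs(w[m]) + abs(w[m + 1])
                if abs(e[m]) <= _EPS * dd:
                    break
                m += 1
            if m == l:
                break
            it += 1
            if it > 100:
                for i in range(n):
                    w[i] = np.nan
                return
            g = (w[l + 1] - w[l]) / (2.0 * e[l])
            rr = _pythag(g, 1.0)
            if g >= 0.0:
                g = w[m] - w[l] + e[l] / (g + rr)
            else:
                g = w[m] - w[l] + e[l] / (g - rr)
            s = 1.0
            c = 1.0
            p = 0.0
            broke = False
            for i in range(m - 1, l - 1, -1):
                f = s * e[i]
                b = c * e[i]
                rr = _pythag(f, g)
                e[i + 1] = rr
                if rr == 0.0:
                    w[i + 1] -= p
                    e[m] = 0.0
                    broke = True
                    break
                s = f / rr
                c = g / rr
                g = w[i + 1] - p
                rr = (w[i] - g) * s + 2.0 * c * b
                p = s * rr
                w[i + 1] = g + p
                g = c * rr - b
                for k in range(r):
                    f2 = P[k, i + 1]
                    P[k, i + 1] = s * P[k, i] + c * f2
                    P[k, i] = c * P[k, i] - s * f2
            if broke:
                continue
            w[l] -= p
            e[l] = g
            e[m] = 0.0


def _batch_tql2_py(diag, off, proj, w, MV, work):
    for b in range(diag.shape[0]):
        _tql2_project_py(diag[b], off[b], proj[b], w[b], MV[b], work)


try:  # compiled fast path
    from numba import njit

    _pythag = njit(cache=True, inline='always', fastmath=True)(_pythag)
    _tql2_project_nb = njit(cache=True, fastmath=True)(_tql2_project_py)

    @njit(cache=True)
    def _batch_tql2_nb(diag, off, proj, w, MV, work):
        for b in range(diag.shape[0]):
            _tql2_project_nb(diag[b], off[b], proj[b], w[b], MV[b], work)

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _batch_tql2_inner = None
    _HAVE_NUMBA = False


def _eigh_projected_numpy(diag: np.ndarray, off: np.ndarray,
                          proj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dense-eigh reference with the same (w, M V) interface (batched)."""
    diag = np.asarray(diag, dtype=float)
    off = np.asarray(off, dtype=float)
    proj = np.asarray(proj, dtype=float)
    n = diag.shape[-1]
    A = np.zeros(diag.shape[:-1] + (n, n))
    idx = np.arange(n)
    A[..., idx, idx] = diag
    A[..., idx[:-1], idx[1:]] = off
    A[..., idx[1:], idx[:-1]] = off
    w, V = np.linalg.eigh(A)
    return w, proj @ V


def eigh_tridiagonal_projected(diag: np.ndarray, off: np.ndarray,
                               proj: np.ndarray,
                               use_numba: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues and projected eigenvectors of symmetric tridiagonals.

    Parameters
    ----------
    diag : (..., n) diagonals; off : (..., n-1) off-diagonals;
    proj : (..., r, n) projection rows M.

    Returns
    -------
    w : (..., n) eigenvalues (unordered);  MV : (..., r, n) with column k
    holding M times the k-th (unit-norm) eigenvector.
    """
    if _HAVE_NUMBA and use_numba:
        diag = np.ascontiguousarray(diag, dtype=np.float64)
        off = np.ascontiguousarray(off, dtype=np.float64)
        proj = np.ascontiguousarray(proj, dtype=np.float64)
        n = diag.shape[-1]
        lead = diag.shape[:-1]
        r = proj.shape[-2]
        d2 = diag.reshape(-1, n)
        e2 = off.reshape(-1, n - 1)
        m2 = np.broadcast_to(proj, lead + (r, n)).reshape(-1, r, n)
        m2 = np.ascontiguousarray(m2)
        w = np.empty_like(d2)
        MV = np.empty_like(m2)
        work = np.empty(n)
        _batch_tql2_nb(d2, e2, m2, w, MV, work)
        return w.reshape(lead + (n,)), MV.reshape(lead + (r, n))
    return _eigh_projected_numpy(diag, off, proj)


def block_response(log_fw: np.ndarray, log_bw: np.ndarray, leak: np.ndarray,
                   response_pairs, times: np.ndarray,
                   use_numba: bool = True) -> np.ndarray:
    """Linear responses u^T P(t) of a batch of positive-rate chains.

    Each chain has ``n`` states with forward/backward log-rates between
    neighbours (shapes (..., n-1)) and a non-negative extra diagonal leak
    (shape (..., n)).  ``response_pairs`` is a list of (obs, p0) pairs, each
    an array broadcastable to (..., n): the observable u and the initial
    distribution.  The i-th response is u_i^T exp(K t) p0_i.

    Log-rates keep the symmetrization weights d = exp(cumsum(log_bw -
    log_fw)/2) overflow-safe for steep landscapes.  Returns an array of
    shape (..., n_pairs, n_times).
    """
    log_fw = np.asarray(log_fw, dtype=float)
    log_bw = np.asarray(log_bw, dtype=float)
    leak = np.asarray(leak, dtype=float)
    times = np.asarray(times, dtype=float)
    n = log_fw.shape[-1] + 1

    with np.errstate(over="ignore"):
        fw = np.exp(log_fw)
        bw = np.exp(log_bw)
        diag = -leak.copy()
        diag[..., :-1] -= fw
        diag[..., 1:] -= bw
        off = np.exp(0.5 * (log_fw + log_bw))

        logd = np.zeros(log_fw.shape[:-1] + (n,))
        logd[..., 1:] = 0.5 * np.cumsum(log_bw - log_fw, axis=-1)

        rows = []
        for obs, p0 in response_pairs:
            obs = np.asarray(obs, dtype=float)
            p0 = np.asarray(p0, dtype=float)
            rows.append(obs * np.exp(-logd))  # spectral coefficients of u
            rows.append(p0 * np.exp(logd))    # spectral amplitudes of p0
        rows = np.broadcast_arrays(*rows)
        proj = np.stack(rows, axis=-2)

    if not (np.all(np.isfinite(diag)) and np.all(np.isfinite(off))
            and np.all(np.isfinite(proj))):
        raise FloatingPointError("non-finite rates or projections "
                                 "(landscape too steep for the solver)")

    w, MV = eigh_tridiagonal_projected(diag, off, proj, use_numba=use_numba)
    if np.any(np.isnan(w)):
        raise FloatingPointError("tridiagonal QL iteration failed to converge")

    npairs = len(response_pairs)
    coeff = MV[..., 0:2 * npairs:2, :] * MV[..., 1:2 * npairs:2, :]
    with np.errstate(over="ignore"):
        # (..., npairs, n) @ (n, T) -> (..., npairs, T)
        expwt = np.exp(np.minimum(w[..., :, None] * times, 709.0))
    return coeff @ expwt
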