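"""Time propagation of state probabilities under the targeting generator.

The master equation dP/dt = K P over the 22 states (solution, PAM-bound,
R-loop lengths 1..20) is solved with the matrix exponential
P(t) = exp(K t) P(0).  The generator is tridiagonal and may be stiff (rates
spanning many decades); scaling-and-squaring handles this robustly at the
small fixed dimension used here.  Cleavage is an implicit probability leak
out of state 20 (no explicit absorbed state), so the total probability is
conserved only for dCas9 (k_cat = 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .energy_model import N_STATES, RateGenerator

_NEG_TOL = 1e-10


@dataclass(frozen=True)
class StateDistribution:
    """Probabilities over states -1..20 at one time point (seconds)."""

    p: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_STATES,):
            raise ValueError("distribution must have 22 entries (states -1..20)")
        if np.any(p < -_NEG_TOL):
            raise ValueError(f"negative probabilities: min {p.min():.3e}")
        p = np.clip(p, 0.0, None)
        if p.sum() > 1.0 + 1e-9:
            raise ValueError(f"total probability {p.sum()} exceeds 1")
        object.__setattr__(self, "p", p)


def delta_distribution(state: int) -> StateDistribution:
    """All probability in a single state n (-1..20) at t = 0."""
    p = np.zeros(N_STATES)
    p[state + 1] = 1.0
    return StateDistribution(p=p, time=0.0)


def _jacobi_refine(A_ld: np.ndarray, V0: np.ndarray):
    """Refine an approximate eigenbasis by cyclic Jacobi in long double.

    ``V0`` (float64 eigenvectors) nearly diagonalizes ``A_ld``; a few Jacobi
    sweeps on B = V^T A V remove the residual mixing between close
    eigenvalues to long-double accuracy.  Returns (eigenvalues, vectors).
    """
    V = V0.astype(np.longdouble)
    B = V.T @ A_ld @ V
    n = B.shape[0]
    scale = np.max(np.abs(np.diag(B))) or np.longdouble(1.0)
    for _ in range(8):
        rotated = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                bij = B[i, j]
                if abs(bij) <= 1e-30 * scale:
                    continue
                rotated = True
                theta = (B[j, j] - B[i, i]) / (2.0 * bij)
                t = np.sign(theta) / (abs(theta) + np.sqrt(theta * theta + 1.0)) \
                    if theta != 0 else np.longdouble(1.0)
                c = 1.0 / np.sqrt(t * t + 1.0)
                s = t * c
                for M in (B,):
                    col_i = M[:, i].copy()
                    col_j = M[:, j].copy()
                    M[:, i] = c * col_i - s * col_j
                    M[:, j] = s * col_i + c * col_j
                    row_i = M[i, :].copy()
                    row_j = M[j, :].copy()
                    M[i, :] = c * row_i - s * row_j
                    M[j, :] = s * row_i + c * row_j
                col_i = V[:, i].copy()
                col_j = V[:, j].copy()
                V[:, i] = c * col_i - s * col_j
                V[:, j] = s * col_i + c * col_j
        if not rotated:
            break
    return np.diag(B).copy(), V


def _spectral_segments(gen: RateGenerator):
    """Decompose the chain into independently solvable segments.

    A nearest-neighbour pair is *cut* when both connecting rates vanish and
    *one-way* when exactly one does.  Reversible segments are solved
    spectrally; a one-way pair is supported when its receiving side is an
    isolated single state (the dissociation protocol's absorbing solution
    state), whose occupancy follows from the time-integrated leak flux.
    Returns None when the structure is more exotic.
    """
    f, b = gen.forward, gen.backward
    cuts = []          # pair index i means between states i-1+(-1) i.e. idx i,i+1
    oneway = []        # (pair index, direction) direction: -1 down, +1 up
    for i in range(N_STATES - 1):
        fi, bi = f[i], b[i + 1]
        if fi == 0.0 and bi == 0.0:
            cuts.append(i)
        elif fi == 0.0:
            oneway.append((i, -1))
        elif bi == 0.0:
            oneway.append((i, +1))
    bounds = [0] + [i + 1 for i in cuts + [j for j, _ in oneway]] + [N_STATES]
    bounds = sorted(set(bounds))
    segments = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
    for i, direction in oneway:
        recv = i if direction == -1 else i + 1
        if (recv, recv + 1) not in segments:
            return None  # receiving side is not an isolated single state
        if f[recv] > 0.0 or b[recv] > 0.0:
            return None  # receiving state must be absorbing
    return segments, oneway


def _propagate_spectral(gen: RateGenerator, p: np.ndarray,
                        times: np.ndarray) -> np.ndarray | None:
    """P(t) for all times via symmetrized eigendecompositions, or None."""
    seg = _spectral_segments(gen)
    if seg is None:
        return None
    segments, oneway = seg
    f, b = gen.forward, gen.backward
    out = np.tile(p, (times.size, 1))
    flux_into: dict[int, list] = {}
    for (lo, hi) in segments:
        n = hi - lo
        fw = f[lo:hi - 1]
        bw = b[lo + 1:hi]
        leak = np.zeros(n)
        extra_up = f[hi - 1]  # cleavage leak or upward one-way donor rate
        leak[-1] += extra_up
        extra_down = b[lo] if lo > 0 else 0.0
        leak[0] += extra_down  # downward one-way leak into state lo-1
        logd = np.concatenate([[0.0], 0.5 * np.cumsum(np.log(bw) - np.log(fw))])
        # the similarity transform amplifies roundoff by its condition number
        if n > 1 and logd.max() - logd.min() > 18.0:
            return None
        # Build the symmetrized matrix in extended precision and refine the
        # float64 eigenbasis with a Jacobi pass against it: float64 eigh mixes
        # near-degenerate slow modes (relative gaps ~eps*||A||), which exp(w t)
        # turns into O(1e-8) occupancy and conservation errors at long times.
        fw_ld = fw.astype(np.longdouble)
        bw_ld = bw.astype(np.longdouble)
        diag_ld = -leak.astype(np.longdouble)
        diag_ld[:-1] -= fw_ld
        diag_ld[1:] -= bw_ld
        off_ld = np.sqrt(fw_ld * bw_ld)
        A_ld = np.diag(diag_ld) + np.diag(off_ld, 1) + np.diag(off_ld, -1)
        _, V64 = np.linalg.eigh(A_ld.astype(float))
        w_ld, V_ld = _jacobi_refine(A_ld, V64)
        w = w_ld.astype(float)
        w = np.minimum(w, 0.0)
        if not np.any(leak):
            w[np.argmax(w)] = 0.0  # conservative segment: exact zero mode
        d_ld = np.exp(logd.astype(np.longdouble))
        beta = V_ld.T @ (d_ld * p[lo:hi].astype(np.longdouble))
        amp = ((V_ld / d_ld[:, None]) * beta).astype(float)
        out[:, lo:hi] = (amp @ np.exp(w[:, None] * times[None, :])).T
        with np.errstate(divide="ignore", invalid="ignore"):
            integ = np.where(np.abs(w[:, None]) > 1e-300,
                             (np.exp(w[:, None] * times[None, :]) - 1.0)
                             / w[:, None],
                             times[None, :])
        if extra_down > 0.0:
            # integrated flux b[lo] * int_0^t P_lo(tau) dtau into state lo-1
            flux_into.setdefault(lo - 1, []).append(extra_down * (amp[0] @ integ))
        if hi < N_STATES and extra_up > 0.0:
            flux_into.setdefault(hi, []).append(extra_up * (amp[-1] @ integ))
    for state, fluxes in flux_into.items():
        out[:, state] = p[state] + np.sum(fluxes, axis=0)
    return out


def propagate(gen: RateGenerator, p0: StateDistribution,
              times: Sequence[float]) -> list[StateDistribution]:
    """Evolve ``p0`` to each requested time (seconds, ascending, >= 0).

    Returns one :class:`StateDistribution` per time.  Times are absolute
    (measured from the time of ``p0``, which is reset to 0).  The solver is
    spectral (exact in time) whenever the generator decomposes into
    reversible segments, and falls back to the scaling-and-squaring matrix
    exponential otherwise.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be ascending")
    p = np.array(p0.p, dtype=float)
    sol = _propagate_spectral(gen, p, times)
    if sol is not None:
        return [StateDistribution(p=(p.copy() if t == 0.0
                                     else np.clip(sol[i], 0.0, None)),
                                  time=float(t))
                for i, t in enumerate(times)]
    K = gen.matrix()
    out: list[StateDistribution] = []
    t_prev = 0.0
    for t in times:
        dt = t - t_prev
        if dt > 0:
            p = scipy.linalg.expm(K * dt) @ p
            p = np.clip(p, 0.0, None)
        out.append(StateDistribution(p=p.copy(), time=float(t)))
        t_prev = t
    return out


def uncleaved_fraction(dist: StateDistribution) -> float:
    """Fraction of DNA not yet cleaved: sum of P_n over all 22 states."""
    return float(np.sum(dist.p))


def bound_fraction(dist: StateDistribution) -> float:
    """Fraction of DNA with enzyme bound: sum of P_n over states 0..20."""
    return float(np.sum(dist.p[1:]))


def stationary_distribution(gen: RateGenerator) -> np.ndarray:
    """Stationary distribution of a conservative (dCas9) generator.

    For the reversible birth-death chain this is the Boltzmann distribution
    exp(-F_n)/Z, recovered here directly from the rates through detailed
    balance, so it applies to any conservative generator regardless of how
    it was built.
    """
    f, b = gen.forward, gen.backward
    if f[-1] != 0.0:
        raise ValueError("stationary distribution requires a conservative "
                         "generator (no cleavage leak)")
    logw = np.full(N_STATES, -np.inf)
    logw[0] = 0.0
    for i in range(1, N_STATES):
        if f[i - 1] > 0 and b[i] > 0:
            logw[i] = logw[i - 1] + np.log(f[i - 1]) - np.log(b[i])
        else:
            raise ValueError("generator is not irreducible and reversible; "
                             "no unique Boltzmann stationary distribution")
    w = np.exp(logw - np.max(logw[np.isfinite(logw)]))
    return w / w.sum()


def export_trace(path, gen: RateGenerator, p0: StateDistribution,
                 times: Sequence[float]) -> None:
    """Write a P(t) time series as a tab-separated table (one row per time)."""
    dists = propagate(gen, p0, times)
    header = "time\t" + "\t".join(f"P_{n}" for n in range(-1, 21))
    rows = ["\t".join([f"{d.time:.10g}"] + [f"{x:.10g}" for x in d.p])
            for d in dists]
    with open(path, "w") as fh:
        fh.write(header + "\n" + "\n".join(rows) + "\n")
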