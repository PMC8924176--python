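"""Metastable-state coarse-graining via mean first-passage times.

The fitted on-target landscape has three metastable states: PAM-bound with
a closed R-loop (P, state 0), an intermediate R-loop (I, the free-energy
minimum among hybrid lengths 7-13), and the open R-loop (O, state 20).
Effective rates between them are inverse mean first-passage times of the
microscopic chain truncated between the metastable states, with the
reflecting edge's outward rate zeroed and absorption just past the far
edge: tau = -1^T K_tr^{-1} P(0) (the truncated generator has a negative
spectrum, so the sign makes tau positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .energy_model import (FreeEnergyLandscape, MismatchPattern, ParameterSet,
                           RateGenerator, SATURATING, build_landscape,
                           landscape_to_rates, state_index)
from .master_equation import delta_distribution, propagate

INTERMEDIATE_WINDOW = (7, 13)


@dataclass(frozen=True)
class CoarseRates:
    """Effective rates (s^-1) between the P, I and O metastable states."""

    n_intermediate: int
    k_PI: float
    k_IP: float
    k_IO: float
    k_OI: float
    k_cat: float

    def __post_init__(self) -> None:
        lo, hi = INTERMEDIATE_WINDOW
        if not lo <= self.n_intermediate <= hi:
            raise ValueError(f"intermediate state must lie in [{lo}, {hi}]")
        for name in ("k_PI", "k_IP", "k_IO", "k_OI"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")


def locate_intermediate(landscape: FreeEnergyLandscape) -> int:
    """State of minimum free energy within the hybrid-length window 7..13.

    Ties break toward the smaller hybrid length.  Invariant under adding a
    constant to the landscape.
    """
    lo, hi = INTERMEDIATE_WINDOW
    window = landscape.F[state_index(lo):state_index(hi) + 1]
    return lo + int(np.argmin(window))


def mean_first_passage_rate(gen: RateGenerator, source: int,
                            absorbing_boundary: int,
                            reflecting_boundary: int) -> float:
    """Inverse mean first-passage time from ``source`` to the absorbing state.

    The chain is truncated to the states between ``reflecting_boundary``
    (inclusive) and ``absorbing_boundary`` (exclusive); the reflecting
    edge's outward rate is zeroed and the forward (or backward) rate into
    the absorbing state acts as the absorbing leak.
    """
    if absorbing_boundary == reflecting_boundary:
        raise ValueError("boundary states must be distinct")
    a = state_index(absorbing_boundary)
    r = state_index(reflecting_boundary)
    s = state_index(source)
    if r < a:
        transient = np.arange(r, a)
    else:
        transient = np.arange(a + 1, r + 1)
    if s not in transient:
        raise ValueError("source must lie inside the truncated interval")
    K = gen.matrix()
    K_tr = K[np.ix_(transient, transient)].copy()
    r_local = int(np.where(transient == r)[0][0])
    # undo the reflected outward rate (it sits in the full diagonal)
    outward = gen.backward[r] if r < a else gen.forward[r]
    K_tr[r_local, r_local] += outward
    p0 = np.zeros(transient.size)
    p0[int(np.where(transient == s)[0][0])] = 1.0
    try:
        occupancy = scipy.linalg.solve(K_tr.T, -np.ones(transient.size))
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("truncated generator is singular: no path to "
                         "absorption") from exc
    tau = float(occupancy @ p0)
    if not (np.isfinite(tau) and tau > 0):
        raise ValueError("mean first-passage time is not positive; "
                         "check the truncation")
    return 1.0 / tau


def coarse_rates(params: ParameterSet, pattern: MismatchPattern,
                 concentration=1.0) -> CoarseRates:
    """The four metastable-state rates of one target.

    P->I starts at state 0 with state 0 reflecting (PAM unbinding off, as in
    the first-passage truncation); I->P and I->O start at the intermediate
    state; O->I starts at state 20 with state 20 reflecting, which also
    switches off the cleavage leak during that passage.
    """
    landscape = build_landscape(params, pattern, concentration)
    n_i = locate_intermediate(landscape)
    gen = landscape_to_rates(landscape, params, dead=False)
    return CoarseRates(
        n_intermediate=n_i,
        k_PI=mean_first_passage_rate(gen, 0, n_i, 0),
        k_IP=mean_first_passage_rate(gen, n_i, 0, n_i),
        k_IO=mean_first_passage_rate(gen, n_i, 20, n_i),
        k_OI=mean_first_passage_rate(gen, 20, n_i, 20),
        k_cat=params.kcat,
    )


def basin_edges(landscape: FreeEnergyLandscape) -> tuple[int, int, int]:
    """(left barrier top, intermediate state, right barrier top).

    The intermediate basin consists of the states strictly between the two
    barrier tops flanking the intermediate minimum (ties toward the state
    nearest the PAM).
    """
    n_i = locate_intermediate(landscape)
    F = landscape.F
    left = 1 + int(np.argmax(F[state_index(1):state_index(n_i)]))
    right = n_i + 1 + int(np.argmax(F[state_index(n_i + 1):state_index(20) + 1]))
    return left, n_i, right


def coarse_occupancy(params: ParameterSet, pattern: MismatchPattern, times,
                     concentration=SATURATING) -> dict:
    """Occupancy of {closed, intermediate, open+cleaved} over time.

    The full microscopic model is propagated (from state 0 under the
    default saturating concentration, else from solution) and binned:
    closed = solution..left barrier top, intermediate = states within the
    barrier tops, open+cleaved = the rest plus leaked probability.  The
    three occupancies sum to 1 at every time.
    """
    landscape = build_landscape(params, pattern, concentration)
    left, n_i, right = basin_edges(landscape)
    gen = landscape_to_rates(landscape, params, dead=False)
    p0 = delta_distribution(0 if landscape.saturating else -1)
    dists = propagate(gen, p0, times)
    closed = np.array([d.p[:state_index(left) + 1].sum() for d in dists])
    inter = np.array([d.p[state_index(left) + 1:state_index(right)].sum()
                      for d in dists])
    return {
        "times": np.asarray(times, dtype=float),
        "closed": closed,
        "intermediate": inter,
        "open_cleaved": 1.0 - closed - inter,
        "n_intermediate": n_i,
        "basin": (left, right),
    }


def coarse_occupancy_from_rates(rates: CoarseRates, times) -> dict:
    """Propagate the reduced 3-state model (closed, intermediate, open).

    The open bin includes the cleaved state, so cleavage does not leak out
    of it; used to check that the coarse model reproduces the binned
    microscopic occupancies.
    """
    K = np.array([
        [-rates.k_PI, rates.k_IP, 0.0],
        [rates.k_PI, -(rates.k_IP + rates.k_IO), rates.k_OI],
        [0.0, rates.k_IO, -rates.k_OI],
    ])
    p0 = np.array([1.0, 0.0, 0.0])
    occ = np.array([scipy.linalg.expm(K * t) @ p0 for t in np.asarray(times, float)])
    return {"times": np.asarray(times, dtype=float), "closed": occ[:, 0],
            "intermediate": occ[:, 1], "open_cleaved": occ[:, 2]}
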