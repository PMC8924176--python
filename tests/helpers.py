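"""Independent numerical oracles used across the test suite.

These deliberately avoid the code paths they check: the reference propagator
is a long-double Taylor series with scaling and squaring, first-passage and
occupancy oracles are direct stochastic (Gillespie) simulations, and the
cleavage-vs-unbinding splitting probability is an absorbing-chain linear
solve.
"""

from __future__ import annotations

import numpy as np

from rloopkinetics import RateGenerator


def reference_expm_apply(K: np.ndarray, p0: np.ndarray, t: float) -> np.ndarray:
    """exp(K t) @ p0 by long-double Taylor series with scaling and squaring."""
    A = np.asarray(K, dtype=np.longdouble) * np.longdouble(t)
    norm = float(np.max(np.sum(np.abs(A), axis=0)))
    s = max(0, int(np.ceil(np.log2(max(norm, 1e-300) / 0.25))))
    B = A / np.longdouble(2.0) ** s
    E = np.eye(A.shape[0], dtype=np.longdouble)
    term = np.eye(A.shape[0], dtype=np.longdouble)
    for k in range(1, 60):
        term = term @ B / np.longdouble(k)
        E_next = E + term
        if np.all(E_next == E):
            break
        E = E_next
    for _ in range(s):
        E = E @ E
    return np.asarray(E @ np.asarray(p0, dtype=np.longdouble), dtype=float)


def gillespie_states(forward, backward, state0: int, t_end: float,
                     rng: np.random.Generator):
    """One trajectory of the 22-state chain; returns (times, states).

    ``forward[i]`` leaves array state i upward (for the last state it is the
    cleavage leak, modelled as a jump to the absorbing pseudo-state -99);
    ``backward[i]`` leaves state i downward.
    """
    t = 0.0
    st = state0
    times = [0.0]
    states = [st]
    n = len(forward)
    while True:
        f = forward[st]
        b = backward[st]
        rate = f + b
        if rate == 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        if rng.random() < f / rate:
            st = st + 1 if st < n - 1 else -99  # cleavage leak
        else:
            st = st - 1
        times.append(t)
        states.append(st)
        if st == -99:
            break
    return np.array(times), np.array(states)


def gillespie_occupancy(gen: RateGenerator, state0: int, sample_times,
                        n_traj: int, seed: int):
    """Mean occupancy (n_times, 22) and its standard error via simulation."""
    rng = np.random.default_rng(seed)
    sample_times = np.asarray(sample_times, dtype=float)
    counts = np.zeros((sample_times.size, 22))
    for _ in range(n_traj):
        times, states = gillespie_states(gen.forward, gen.backward, state0,
                                         sample_times[-1] * 1.0000001, rng)
        idx = np.searchsorted(times, sample_times, side="right") - 1
        for i, j in enumerate(idx):
            st = states[j]
            if st >= 0:
                counts[i, st] += 1
    occ = counts / n_traj
    se = np.sqrt(np.clip(occ * (1 - occ), 0.0, None) / n_traj)
    return occ, se


def gillespie_mfpt(forward, backward, source: int, absorbing: int,
                   n_traj: int, seed: int):
    """Mean and standard error of the first-passage time to ``absorbing``.

    ``forward``/``backward`` describe the already-truncated chain (the
    reflecting edge simply has no outward rate); states are array indices.
    """
    rng = np.random.default_rng(seed)
    taus = np.empty(n_traj)
    n = len(forward)
    for k in range(n_traj):
        st = source
        t = 0.0
        while st != absorbing:
            f = forward[st] if st < n else 0.0
            b = backward[st]
            t += rng.exponential(1.0 / (f + b))
            st = st + 1 if rng.random() < f / (f + b) else st - 1
        taus[k] = t
    return taus.mean(), taus.std(ddof=1) / np.sqrt(n_traj)


def splitting_probability_cleave(gen: RateGenerator) -> float:
    """P(cleave before unbinding | PAM bound), by absorbing-chain linear solve.

    Transient states 0..20; unbinding from state 0 (rate k_0^b) absorbs at
    "unbound", the cleavage leak from state 20 (rate k_cat) absorbs at
    "cleaved".  Solves the first-step equations for the hit probability.
    """
    f = gen.forward[1:]    # out of states 0..20 upward (last = k_cat)
    b = gen.backward[1:]   # out of states 0..20 downward (first = k_0^b)
    n = 21
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for i in range(n):
        A[i, i] = f[i] + b[i]
        if i + 1 < n:
            A[i, i + 1] = -f[i]
        else:
            rhs[i] += f[i]  # jump to the cleaved state
        if i - 1 >= 0:
            A[i, i - 1] = -b[i]
        # i == 0: backward jump hits the unbound state (h = 0)
    h = np.linalg.solve(A, rhs)
    return float(h[0])
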