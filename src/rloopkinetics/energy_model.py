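"""Free-energy landscapes of the Cas9/dCas9 targeting reaction and their rates.

The targeting reaction is modelled as a hopping process over 22 states:
solution (n = -1), PAM-bound (n = 0) and R-loop states of hybrid length
n = 1..20.  Hybrid position 1 is PAM-proximal; positions count away from the
PAM.  All free energies are in units of kBT (kBT = 1 internally), rates in
s^-1, and concentrations are dimensionless relative to 1 nM.

The reduced parameterisation has 44 physical parameters: the PAM-bound free
energy at the reference concentration (F0_ref), 20 on-target extension free
energies eps_n, 20 position-dependent mismatch penalties delta_eps_n, and
three forward rates (PAM binding k_on at 1 nM, the internal bond-formation
rate k_f shared by all R-loop extension steps, and the catalytic cleavage
rate k_cat out of state 20).  A mismatched target shifts every landscape
step at a mismatched position by the corresponding penalty; everything else
is inherited from the on-target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("rloopkinetics")

N_POSITIONS = 20
N_STATES = 22  # states -1 .. 20
N_PARAMETERS = 44

#: Largest magnitude allowed for arguments of exp() when converting free-energy
#: steps to rates.  Beyond this the argument is clamped (with a warning); the
#: clamp only matters in physically unreachable regimes.
EXP_CLAMP = 700.0


class _Saturating:
    """Sentinel for a saturating enzyme concentration.

    The saturating limit corresponds to F_0 -> -infinity.  Rather than
    exponentiating a huge energy, saturation is realised kinetically: the
    reaction is started with all probability in the PAM-bound state (n = 0)
    and the PAM-unbinding rate k_0^b is forced to zero, which is the exact
    limit of the finite-concentration model.
    """

    def __repr__(self) -> str:  # pragma: no cover
        return "SATURATING"


SATURATING = _Saturating()


def state_index(n: int) -> int:
    """Array index of state ``n`` (n = -1..20)."""
    if not -1 <= n <= 20:
        raise ValueError(f"state must be in [-1, 20], got {n}")
    return n + 1


@dataclass(frozen=True)
class MismatchPattern:
    """Set of mismatched hybrid positions (1..20) of a target vs the guide.

    The empty pattern is the on-target.  Position 1 is PAM-proximal.
    """

    positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.positions)
        if any(not 1 <= p <= N_POSITIONS for p in pos):
            raise ValueError(f"mismatch positions must be in [1, 20], got {pos}")
        if len(set(pos)) != len(pos):
            raise ValueError(f"duplicate mismatch positions in {pos}")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            pos = tuple(sorted(pos))
        object.__setattr__(self, "positions", pos)

    @classmethod
    def from_string(cls, text: str) -> "MismatchPattern":
        """Parse a comma-joined position list; the empty string is on-target."""
        text = text.strip()
        if not text:
            return cls(())
        return cls(tuple(int(tok) for tok in text.split(",")))

    def to_string(self) -> str:
        return ",".join(str(p) for p in self.positions)

    @property
    def n_mismatches(self) -> int:
        return len(self.positions)

    def mask(self) -> np.ndarray:
        """Boolean array of length 20; entry n-1 is True if position n mismatches."""
        m = np.zeros(N_POSITIONS, dtype=bool)
        for p in self.positions:
            m[p - 1] = True
        return m


ON_TARGET = MismatchPattern(())


@dataclass(frozen=True, eq=False)
class ParameterSet:
    """The 44 physical parameters of the reduced targeting model.

    Attributes
    ----------
    F0_ref
        Free energy of the PAM-bound state at the 1 nM reference
        concentration (kBT), relative to solution (F_-1 = 0).
    eps
        20 on-target free-energy gains eps_1..eps_20 (kBT) for extending the
        hybrid by one base pair; may be negative.
    delta_eps
        20 per-position mismatch penalties (kBT), added to the landscape step
        at a mismatched position.
    log10_kon_ref, log10_kf, log10_kcat
        log10 of the PAM binding rate at 1 nM, of the internal forward
        bond-formation rate, and of the cleavage catalysis rate (all s^-1).
    """

    F0_ref: float
    eps: np.ndarray
    delta_eps: np.ndarray
    log10_kon_ref: float
    log10_kf: float
    log10_kcat: float

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        dep = np.asarray(self.delta_eps, dtype=float)
        if eps.shape != (N_POSITIONS,) or dep.shape != (N_POSITIONS,):
            raise ValueError("eps and delta_eps must each have exactly 20 entries")
        scalars = (self.F0_ref, self.log10_kon_ref, self.log10_kf, self.log10_kcat)
        if not (np.all(np.isfinite(eps)) and np.all(np.isfinite(dep))
                and all(np.isfinite(x) for x in scalars)):
            raise ValueError("all parameters must be finite")
        object.__setattr__(self, "eps", eps)
        object.__setattr__(self, "delta_eps", dep)

    @property
    def kon_ref(self) -> float:
        return 10.0 ** self.log10_kon_ref

    @property
    def kf(self) -> float:
        return 10.0 ** self.log10_kf

    @property
    def kcat(self) -> float:
        return 10.0 ** self.log10_kcat

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical 44-vector used by the optimizer."""
        return np.concatenate([
            [self.F0_ref], self.eps, self.delta_eps,
            [self.log10_kon_ref, self.log10_kf, self.log10_kcat],
        ])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return bool(np.array_equal(self.to_vector(), other.to_vector()))

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "ParameterSet":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_PARAMETERS,):
            raise ValueError(f"parameter vector must have {N_PARAMETERS} entries")
        return cls(F0_ref=float(x[0]), eps=x[1:21].copy(), delta_eps=x[21:41].copy(),
                   log10_kon_ref=float(x[41]), log10_kf=float(x[42]),
                   log10_kcat=float(x[43]))

    def to_dict(self) -> dict:
        return {
            "F0_ref": self.F0_ref,
            "eps": self.eps.tolist(),
            "delta_eps": self.delta_eps.tolist(),
            "log10_kon_ref": self.log10_kon_ref,
            "log10_kf": self.log10_kf,
            "log10_kcat": self.log10_kcat,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        missing = {"F0_ref", "eps", "delta_eps", "log10_kon_ref",
                   "log10_kf", "log10_kcat"} - set(d)
        if missing:
            raise ValueError(f"parameter file missing keys: {sorted(missing)}")
        return cls(F0_ref=float(d["F0_ref"]),
                   eps=np.asarray(d["eps"], dtype=float),
                   delta_eps=np.asarray(d["delta_eps"], dtype=float),
                   log10_kon_ref=float(d["log10_kon_ref"]),
                   log10_kf=float(d["log10_kf"]),
                   log10_kcat=float(d["log10_kcat"]))


@dataclass(frozen=True)
class FreeEnergyLandscape:
    """Free energies F_-1..F_20 (kBT) of one target at one concentration.

    F_-1 = 0 is the solution reference.  For a saturating concentration the
    stored F_0 is the reference-concentration value; the saturation limit is
    applied at the rate level (see :data:`SATURATING`).
    """

    F: np.ndarray
    concentration: float
    saturating: bool = False

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (N_STATES,):
            raise ValueError("landscape must have 22 free energies (states -1..20)")
        if F[0] != 0.0:
            raise ValueError("F_-1 must be exactly 0 (solution reference)")
        if not self.saturating and not self.concentration > 0:
            raise ValueError("concentration must be positive")
        object.__setattr__(self, "F", F)

    def steps(self) -> np.ndarray:
        """Consecutive free-energy differences dF_n = F_n - F_{n-1}, n = 0..20."""
        return np.diff(self.F)


def build_landscape(params: ParameterSet, pattern: MismatchPattern,
                    concentration) -> FreeEnergyLandscape:
    """Free-energy landscape of a (possibly mismatched) target.

    F_-1 = 0; F_0 = F0_ref - ln(c); for n >= 1 each extension step adds eps_n,
    plus delta_eps_n when position n is mismatched (local, additive penalties).
    ``concentration`` is relative to 1 nM, or :data:`SATURATING`.
    """
    sat = concentration is SATURATING
    if not sat and not concentration > 0:
        raise ValueError("concentration must be positive or SATURATING")
    F = np.empty(N_STATES)
    F[0] = 0.0
    F0 = params.F0_ref if sat else params.F0_ref - np.log(concentration)
    steps = params.eps + params.delta_eps * pattern.mask()
    F[1] = F0
    F[2:] = F0 + np.cumsum(steps)
    return FreeEnergyLandscape(F=F, concentration=(1.0 if sat else float(concentration)),
                               saturating=sat)


@dataclass(frozen=True)
class RateGenerator:
    """Transition rates of the tridiagonal master-equation generator.

    ``forward[i]`` is the rate out of state n = i-1 to n = i (for state 20 it
    is the cleavage leak k_cat, which has no destination state); ``backward[i]``
    is the rate from state n = i-1 to n = i-2, with k_-1^b = 0.
    """

    forward: np.ndarray
    backward: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.forward, dtype=float)
        b = np.asarray(self.backward, dtype=float)
        if f.shape != (N_STATES,) or b.shape != (N_STATES,):
            raise ValueError("forward and backward must have 22 entries (states -1..20)")
        if np.any(f < 0) or np.any(b < 0):
            raise ValueError("rates must be non-negative")
        if b[0] != 0.0:
            raise ValueError("k_-1^b must be 0")
        object.__setattr__(self, "forward", f)
        object.__setattr__(self, "backward", b)

    def matrix(self) -> np.ndarray:
        """Dense 22x22 generator K with columns summing to zero except for the
        cleavage leak out of state 20 (column sum -k_cat)."""
        f, b = self.forward, self.backward
        K = np.zeros((N_STATES, N_STATES))
        idx = np.arange(N_STATES)
        K[idx, idx] = -(f + b)
        K[idx[1:], idx[:-1]] = f[:-1]   # n -> n+1
        K[idx[:-1], idx[1:]] = b[1:]    # n -> n-1
        return K


def _safe_exp(x: np.ndarray | float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > EXP_CLAMP):
        warnings.warn(
            f"free-energy step beyond +/-{EXP_CLAMP} kBT clamped in exp()",
            RuntimeWarning, stacklevel=3)
        x = np.clip(x, -EXP_CLAMP, EXP_CLAMP)
    return np.exp(x)


def landscape_to_rates(landscape: FreeEnergyLandscape, params: ParameterSet,
                       dead: bool = False, no_binding: bool = False) -> RateGenerator:
    """Convert a landscape to transition rates (local detailed balance).

    Forward rates: k_-1^f = k_on_ref * c (0 when ``no_binding`` or saturating),
    k_n^f = k_f for n = 0..19, and k_20^f = k_cat (0 for dCas9, ``dead=True``).
    Backward rates: k_0^b = k_on_ref * exp(F0_ref) (0 in the saturating limit),
    k_n^b = k_f * exp(dF_n) for n = 1..20.
    """
    kf = params.kf
    forward = np.empty(N_STATES)
    backward = np.empty(N_STATES)
    steps = landscape.steps()  # dF_0 .. dF_20
    forward[1:21] = kf
    forward[21] = 0.0 if dead else params.kcat
    backward[0] = 0.0
    backward[2:] = kf * _safe_exp(steps[1:])
    if landscape.saturating:
        forward[0] = 0.0
        backward[1] = 0.0
    else:
        forward[0] = 0.0 if no_binding else params.kon_ref * landscape.concentration
        backward[1] = params.kon_ref * _safe_exp(params.F0_ref)
    return RateGenerator(forward=forward, backward=backward)
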