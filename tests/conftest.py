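import numpy as np
import pytest

from rloopkinetics import ParameterSet, generate_parameter_set


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """A fitted-like parameter set with the three-minimum on-target landscape."""
    return generate_parameter_set(7)


@pytest.fixture(scope="session")
def fast_params(params) -> ParameterSet:
    """Same landscape but fast binding/internal rates (near-equilibrium)."""
    return ParameterSet(F0_ref=params.F0_ref, eps=params.eps,
                        delta_eps=params.delta_eps, log10_kon_ref=2.0,
                        log10_kf=6.0, log10_kcat=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_patterns(rng, n, max_mismatches=4):
    """Distinct random mismatch patterns (possibly including the on-target)."""
    from rloopkinetics import MismatchPattern
    seen = set()
    out = []
    while len(out) < n:
        k = int(rng.integers(0, max_mismatches + 1))
        positions = tuple(sorted(rng.choice(np.arange(1, 21), size=k,
                                            replace=False).tolist()))
        if positions not in seen:
            seen.add(positions)
            out.append(MismatchPattern(positions))
    return out
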