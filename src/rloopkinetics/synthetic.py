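"""Synthetic parameter sets, measurement tables, and toy genomes.

The generator emulates the statistical structure of the training data: one
on-target, 20 single-mismatch and 190 double-mismatch patterns per
experiment, with multiplicative (log-normal) measurement noise.  The
template on-target landscape has the three-minimum shape characteristic of
the targeting reaction (closed / intermediate around hybrid length 9-12 /
open), and mismatch penalties are drawn around 5 kBT, so that synthetic
truth is a plausible stand-in for fitted parameters in recovery benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy_model import MismatchPattern, ON_TARGET, ParameterSet
from .experiments import (QuantityKind, predict_ka_eff_batch,
                          predict_kclv_eff_batch)
from .training import RawMeasurement

#: on-target free energies F_0..F_20 (kBT, at 1 nM) of the template
#: landscape.  The PAM-bound state is weakly stable (+3 kBT: PAM sampling is
#: transient, so seed-blocked targets release within the binding assay's 10
#: minutes), the intermediate basin sits at a similar level (making the
#: closed<->intermediate transition reversible), and the open R-loop is the
#: global bound minimum.
_TEMPLATE_F = np.array([
    3.0,                                     # PAM bound
    7.5, 8.5, 8.5, 8.5, 8.0, 8.0, 7.5, 6.0,  # seed barrier (1-8)
    2.8, 2.5, 2.8, 3.2,                      # intermediate basin (9-12)
    6.0, 6.5, 7.0, 7.2, 7.2, 7.0, 6.5,       # distal barrier (13-19)
    -5.0,                                    # open R-loop (20)
])


def all_patterns(max_mismatches: int = 2) -> list[MismatchPattern]:
    """On-target plus all patterns with up to ``max_mismatches`` mismatches."""
    pats = [ON_TARGET]
    if max_mismatches >= 1:
        pats += [MismatchPattern((i,)) for i in range(1, 21)]
    if max_mismatches >= 2:
        pats += [MismatchPattern((i, j))
                 for i in range(1, 21) for j in range(i + 1, 21)]
    if max_mismatches > 2:
        raise ValueError("synthetic tables cover at most 2 mismatches")
    return pats


def generate_parameter_set(seed: int) -> ParameterSet:
    """Draw a plausible 44-parameter truth around the template landscape.

    The on-target extension energies are the template steps plus N(0, 0.3)
    jitter; penalties are N(5, 1) truncated positive; rates are log-jittered
    around k_on = 10^-3.5 s^-1 at 1 nM (3e5 /M/s), k_f = 1e3 s^-1 and
    k_cat = 10^-1.5 s^-1 (slow catalysis: cleavage assays run for hours).
    Together with the weakly stable PAM state this reproduces the structure
    of the real training tables: association constants that drop by orders
    of magnitude for seed mismatches but respond weakly to distal ones, and
    cleavage rates suppressed by mismatches anywhere.  Deterministic per
    seed.
    """
    rng = np.random.default_rng(seed)
    F0 = _TEMPLATE_F[0] + rng.normal(0.0, 0.3)
    eps = np.diff(_TEMPLATE_F) + rng.normal(0.0, 0.3, 20)
    delta = rng.normal(5.0, 1.0, 20)
    while np.any(delta <= 0):  # truncate at positive penalties
        bad = delta <= 0
        delta[bad] = rng.normal(5.0, 1.0, int(bad.sum()))
    return ParameterSet(
        F0_ref=float(F0), eps=eps, delta_eps=delta,
        log10_kon_ref=float(-3.5 + rng.normal(0.0, 0.2)),
        log10_kf=float(3.0 + rng.normal(0.0, 0.2)),
        log10_kcat=float(-1.5 + rng.normal(0.0, 0.2)),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for synthetic measurement tables.

    With ``mismatch_type_replicates`` (the default) each pattern carries one
    row per mismatch-type combination — 1 for the on-target, 3 per single
    mismatch, 9 per double — matching the sequence multiplicity of the real
    libraries, so that mismatch-type averaging shrinks the record errors
    the way it does on real tables.  ``replicates_per_pattern`` multiplies
    the row count further.
    """

    true_params: ParameterSet
    noise_sd: float = 0.1          # additive on log10 values
    replicates_per_pattern: int = 1
    mismatch_type_replicates: bool = True
    max_mismatches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates_per_pattern < 1:
            raise ValueError("replicates_per_pattern must be >= 1")


def generate_measurements(spec: SyntheticSpec):
    """Raw tables for both training experiments from known true parameters.

    Returns (cleavage_rows, association_rows): per pattern and replicate one
    :class:`RawMeasurement` whose log10 value is the noiseless prediction
    plus N(0, noise_sd), with the per-row error set to noise_sd (a small
    floor keeps the error positive in the noiseless case).
    """
    rng = np.random.default_rng(spec.seed)
    pats = all_patterns(spec.max_mismatches)
    err = max(spec.noise_sd, 1e-3)
    tables = []
    for kind, batch in ((QuantityKind.CLEAVAGE_RATE, predict_kclv_eff_batch),
                        (QuantityKind.ASSOCIATION_CONSTANT,
                         predict_ka_eff_batch)):
        log10_true = np.log10(batch(spec.true_params, pats))
        rows = []
        for i, pat in enumerate(pats):
            n_types = 3 ** pat.n_mismatches if spec.mismatch_type_replicates                 else 1
            for rep in range(n_types * spec.replicates_per_pattern):
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
                rows.append(RawMeasurement(
                    sequence_id=f"{kind.value.lower()}:{pat.to_string() or 'on'}"
                                f":rep{rep}",
                    pattern=pat,
                    log10_value=float(log10_true[i] + noise),
                    log10_error=err))
        tables.append(rows)
    return tables[0], tables[1]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _mutate(base: str, rng) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def generate_toy_genome(guide: str, planted, length: int = 10000,
                        seed: int = 0) -> tuple[str, list[tuple[int, str]]]:
    """Random sequence with off-target sites planted at known positions.

    ``planted`` is a list of MismatchPattern; each is embedded as a
    protospacer (the guide mutated at the pattern's positions, position 1
    PAM-proximal) followed by an AGG PAM, at evenly spaced, non-overlapping
    locations.  Returns (sequence, [(start, protospacer+PAM), ...]).
    """
    if len(guide) != 20:
        raise ValueError("guide must be 20 nt")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    spacing = length // (len(planted) + 1)
    sites = []
    for i, pattern in enumerate(planted):
        proto = list(guide)
        for pos in pattern.positions:
            proto[20 - pos] = _mutate(proto[20 - pos], rng)
        site = "".join(proto) + "AGG"
        start = spacing * (i + 1)
        seq[start:start + 23] = list(site)
        sites.append((start, site))
    return "".join(seq), sites
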