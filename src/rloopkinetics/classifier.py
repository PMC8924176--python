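"""Off-target ranking: closed-form cleavage score, PAM scanning, PR curves.

In the low-concentration limit the genomic cleavage rate factorizes into a
target-independent PAM-binding flux times the probability that a PAM-bound
complex cleaves before unbinding.  That splitting probability has a closed
form in the free energies of the target's landscape,

    P(PAM->clv) = k_cat / (k_cat * sum_{n=0..19} e^{F_n} + k_f * e^{F_20}),

(the solution-state reference F_-1 = 0 makes the numerator k_cat), and is
used as a ranking score: target-independent prefactors and the common
concentration shift of F_0 do not change the order.  Genomic candidate
sites are all 20-nt protospacers followed by a canonical NGG PAM on either
strand; classification quality against a truth set is summarized by the
precision-recall curve, its maximum F1, and the area under it (AUPRC).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.special import logsumexp

from .energy_model import MismatchPattern, ParameterSet

PAM_LENGTH = 3
SITE_LENGTH = 23  # 20-nt protospacer + NGG

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class GenomicSite:
    """One candidate site: 23 nt (protospacer + NGG), 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str
    pattern: MismatchPattern
    score: float | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != SITE_LENGTH:
            raise ValueError("a site spans exactly 23 bases")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    def key(self) -> tuple:
        return (self.contig, self.start, self.end, self.strand)

    def display(self) -> str:
        """1-based inclusive coordinate string."""
        return f"{self.contig}:{self.start + 1}-{self.end}:{self.strand}"


def _score_masks(params: ParameterSet, masks: np.ndarray) -> np.ndarray:
    """Vectorized cleavage-probability score for mismatch masks (B, 20)."""
    F0 = params.F0_ref  # reference concentration (1 nM)
    steps = params.eps + params.delta_eps * masks
    F = F0 + np.concatenate([np.zeros((masks.shape[0], 1)),
                             np.cumsum(steps, axis=1)], axis=1)  # F_0..F_20
    ln_kcat = np.log(10.0) * params.log10_kcat
    ln_kf = np.log(10.0) * params.log10_kf
    terms = np.concatenate([ln_kcat + F[:, :20], ln_kf + F[:, 20:21]], axis=1)
    return np.exp(ln_kcat - logsumexp(terms, axis=1))


def cleavage_probability_score(params: ParameterSet,
                               pattern: MismatchPattern) -> float:
    """Probability-like ranking score of one target (log-sum-exp safe)."""
    return float(_score_masks(params, pattern.mask()[None, :])[0])


def find_pam_sites(genome: Mapping[str, str], guide: str,
                   max_mismatches: int | None = None) -> list[GenomicSite]:
    """All NGG-adjacent 20-nt sites on both strands, with mismatch patterns.

    ``genome`` maps contig names to sequences (A/C/G/T/N; case-insensitive);
    sites containing N are skipped.  The minus strand is scanned via the
    reverse complement and reported in plus-strand coordinates.  Position 1
    of a pattern is the base adjacent to the PAM.  ``max_mismatches``
    optionally drops heavily mismatched sites.
    """
    if len(guide) != 20:
        raise ValueError("guide must be exactly 20 nt")
    guide = guide.upper()
    if set(guide) - set("ACGT"):
        raise ValueError("guide must contain only A/C/G/T")
    sites: list[GenomicSite] = []
    for contig, seq in genome.items():
        seq = seq.upper()
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else seq.translate(_COMPLEMENT)[::-1]
            for start, proto in _scan_strand(s, guide):
                positions = tuple(
                    20 - j for j in range(20) if proto[j] != guide[j])
                pattern = MismatchPattern(tuple(sorted(positions)))
                if max_mismatches is not None \
                        and pattern.n_mismatches > max_mismatches:
                    continue
                if strand == "+":
                    g_start = start
                else:
                    g_start = L - (start + SITE_LENGTH)
                sites.append(GenomicSite(contig=contig, start=g_start,
                                         end=g_start + SITE_LENGTH,
                                         strand=strand, pattern=pattern))
    return sites


def _scan_strand(seq: str, guide: str):
    """Yield (start, protospacer) for windows followed by NGG, skipping Ns."""
    if len(seq) < SITE_LENGTH:
        return
    b = np.frombuffer(seq.encode(), dtype="S1")
    gg = (b[21:] == b"G")[:-1] & (b[22:] == b"G")
    valid = b != b"N"
    # window [i, i+23) must be N-free
    ok = np.ones(len(seq) - SITE_LENGTH + 1, dtype=bool)
    bad = np.flatnonzero(~valid)
    for j in bad:
        lo = max(0, j - SITE_LENGTH + 1)
        ok[lo:j + 1] = False
    for i in np.flatnonzero(gg[:len(ok)] & ok):
        yield int(i), seq[i:i + 20]


def scan_genome(genome: Mapping[str, str], guide: str, params: ParameterSet,
                max_mismatches: int | None = None) -> list[GenomicSite]:
    """Find and score all candidate sites, sorted by descending score."""
    sites = find_pam_sites(genome, guide, max_mismatches=max_mismatches)
    if not sites:
        return []
    masks = np.array([s.pattern.mask() for s in sites], dtype=float)
    scores = _score_masks(params, masks)
    scored = [replace(s, score=float(v)) for s, v in zip(sites, scores)]
    scored.sort(key=lambda s: (-s.score, s.key()))
    return scored


@dataclass(frozen=True)
class PRResult:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    max_f1: float
    auprc: float


def pr_evaluate(scored_sites: Iterable[GenomicSite], truth: set) -> PRResult:
    """Precision-recall analysis of a scored site list against a truth set.

    The threshold sweeps the unique score values (all ties cross together);
    AUPRC is the trapezoid over recall with the conventional (recall 0,
    precision 1) anchor.  ``truth`` holds site keys (contig, start, end,
    strand) as returned by :meth:`GenomicSite.key`.
    """
    sites = list(scored_sites)
    if not truth:
        raise ValueError("truth set must not be empty")
    if any(s.score is None or not np.isfinite(s.score) for s in sites):
        raise ValueError("all sites must carry finite scores")
    scores = np.array([s.score for s in sites])
    is_true = np.array([s.key() in truth for s in sites])
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    is_true = is_true[order]
    n_truth = len(truth)
    # indices where a run of tied scores ends
    ends = np.flatnonzero(np.diff(scores) != 0)
    ends = np.concatenate([ends, [len(scores) - 1]])
    tp = np.cumsum(is_true)[ends]
    n_called = ends + 1
    precision = tp / n_called
    recall = tp / n_truth
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(tp > 0, 2 * precision * recall / (precision + recall), 0.0)
    r_anchor = np.concatenate([[0.0], recall])
    p_anchor = np.concatenate([[1.0], precision])
    auprc = float(np.trapezoid(p_anchor, r_anchor))
    return PRResult(thresholds=scores[ends], precision=precision,
                    recall=recall, max_f1=float(f1.max()), auprc=auprc)


def truth_set_from_sites(sites: Iterable[GenomicSite]) -> set:
    return {s.key() for s in sites}


def truth_union(*sets: set) -> set:
    out: set = set()
    for s in sets:
        out |= s
    return out


def truth_intersection(*sets: set) -> set:
    if not sets:
        return set()
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out
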