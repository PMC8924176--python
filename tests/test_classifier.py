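import numpy as np
import pytest

from rloopkinetics import (GenomicSite, MismatchPattern, ON_TARGET,
                           ParameterSet, build_landscape,
                           cleavage_probability_score, find_pam_sites,
                           landscape_to_rates, pr_evaluate, scan_genome,
                           truth_intersection, truth_union)
from rloopkinetics.synthetic import generate_toy_genome, reverse_complement

from conftest import random_patterns
from helpers import splitting_probability_cleave


class TestScore:
    def test_flat_landscape_closed_form(self):
        """With all free energies zero the score is k_cat/(20 k_cat + k_f)."""
        flat = ParameterSet(F0_ref=0.0, eps=np.zeros(20),
                            delta_eps=np.full(20, 5.0), log10_kon_ref=0.0,
                            log10_kf=2.0, log10_kcat=-1.0)
        expected = flat.kcat / (20.0 * flat.kcat + flat.kf)
        assert cleavage_probability_score(flat, ON_TARGET) == \
            pytest.approx(expected, rel=1e-12)

    def test_ranking_matches_splitting_probability(self, params, rng):
        """The closed-form score orders 500 random patterns exactly as the
        cleave-before-unbind probability from an absorbing-chain solve."""
        patterns = random_patterns(rng, 500, max_mismatches=6)
        scores = np.array([cleavage_probability_score(params, p)
                           for p in patterns])
        probs = np.empty(len(patterns))
        for i, p in enumerate(patterns):
            gen = landscape_to_rates(build_landscape(params, p, 1.0), params)
            probs[i] = splitting_probability_cleave(gen)
        assert np.array_equal(np.argsort(scores), np.argsort(probs))

    def test_any_mismatch_lowers_score(self, params, rng):
        for pattern in random_patterns(rng, 10, max_mismatches=3):
            base = cleavage_probability_score(params, pattern)
            free = sorted(set(range(1, 21)) - set(pattern.positions))
            pos = free[int(rng.integers(len(free)))]
            worse = MismatchPattern(tuple(sorted(pattern.positions + (pos,))))
            assert cleavage_probability_score(params, worse) < base

    def test_ranking_invariant_to_pam_energy_shift(self, params, rng):
        """Shifting F_0 (the concentration term) rescales all scores by a
        common factor and leaves the ranking unchanged."""
        shifted = ParameterSet(F0_ref=params.F0_ref - 3.0, eps=params.eps,
                               delta_eps=params.delta_eps,
                               log10_kon_ref=params.log10_kon_ref,
                               log10_kf=params.log10_kf,
                               log10_kcat=params.log10_kcat)
        pats = random_patterns(rng, 20)
        s1 = np.array([cleavage_probability_score(params, p) for p in pats])
        s2 = np.array([cleavage_probability_score(shifted, p) for p in pats])
        np.testing.assert_allclose(s2 / s1, s2[0] / s1[0], rtol=1e-9)


GUIDE = "GACGCATAAAGATGAGACGC"


class TestPamScan:
    def test_single_forward_site(self):
        seq = "TTTT" + GUIDE + "AGG" + "CCT"
        sites = find_pam_sites({"chr": seq}, GUIDE)
        fwd = [s for s in sites if s.strand == "+"]
        assert len(fwd) == 1
        assert (fwd[0].start, fwd[0].end) == (4, 27)
        assert fwd[0].pattern == ON_TARGET

    def test_reverse_complement_reports_minus_strand(self):
        seq = "TTTT" + GUIDE + "AGG" + "CCT"
        rc = reverse_complement(seq)
        sites = find_pam_sites({"chr": rc}, GUIDE)
        minus = [s for s in sites if s.strand == "-"]
        assert len(minus) == 1
        assert minus[0].pattern == ON_TARGET
        assert (minus[0].start, minus[0].end) == (len(seq) - 27, len(seq) - 4)

    def test_mismatch_positions_are_pam_proximal(self):
        proto = list(GUIDE)
        proto[19] = "A" if proto[19] != "A" else "C"  # adjacent to the PAM
        seq = "AA" + "".join(proto) + "TGG"
        sites = find_pam_sites({"c": seq}, GUIDE)
        assert sites[0].pattern == MismatchPattern((1,))

    def test_sites_with_n_skipped(self):
        seq = "TTTT" + GUIDE[:10] + "N" + GUIDE[11:] + "AGG"
        assert all(s.start != 4 for s in find_pam_sites({"c": seq}, GUIDE))

    def test_matches_brute_force_scan(self, rng):
        """Site list on a random 10 kb sequence equals a direct
        window-by-window scan on both strands."""
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        genome = {"chr1": seq}
        sites = {(s.start, s.strand): s.pattern
                 for s in find_pam_sites(genome, GUIDE)}
        expected = {}
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for i in range(len(s) - 22):
                if s[i + 21:i + 23] == "GG":
                    proto = s[i:i + 20]
                    pat = tuple(sorted(20 - j for j in range(20)
                                       if proto[j] != GUIDE[j]))
                    start = i if strand == "+" else len(s) - i - 23
                    expected[(start, strand)] = MismatchPattern(pat)
        assert sites == expected

    def test_bad_guide_rejected(self):
        with pytest.raises(ValueError):
            find_pam_sites({"c": "ACGT"}, "ACGT")
        with pytest.raises(ValueError):
            find_pam_sites({"c": "ACGT"}, "N" * 20)


def make_sites(scores, truth_flags):
    sites, truth = [], set()
    for i, (sc, is_true) in enumerate(zip(scores, truth_flags)):
        s = GenomicSite(contig="c", start=100 * i, end=100 * i + 23,
                        strand="+", pattern=ON_TARGET, score=float(sc))
        sites.append(s)
        if is_true:
            truth.add(s.key())
    return sites, truth


class TestPrecisionRecall:
    def test_perfect_separation(self):
        sites, truth = make_sites([9, 8, 7, 3, 2, 1],
                                  [True, True, True, False, False, False])
        res = pr_evaluate(sites, truth)
        assert res.max_f1 == pytest.approx(1.0)
        assert res.auprc == pytest.approx(1.0)

    def test_constant_scores_collapse_to_prevalence(self):
        sites, truth = make_sites([5, 5, 5, 5], [True, False, False, False])
        res = pr_evaluate(sites, truth)
        assert res.precision.shape == (1,)
        assert res.precision[0] == pytest.approx(0.25)
        assert res.recall[0] == pytest.approx(1.0)

    def test_six_site_hand_enumeration(self):
        """Scores 6..1 with truth at ranks 1, 2 and 4: best F1 is 6/7 at
        the top-4 cutoff."""
        sites, truth = make_sites([6, 5, 4, 3, 2, 1],
                                  [True, True, False, True, False, False])
        res = pr_evaluate(sites, truth)
        np.testing.assert_allclose(res.precision,
                                   [1.0, 1.0, 2 / 3, 3 / 4, 3 / 5, 1 / 2])
        np.testing.assert_allclose(res.recall,
                                   [1 / 3, 2 / 3, 2 / 3, 1.0, 1.0, 1.0])
        assert res.max_f1 == pytest.approx(6 / 7)

    def test_input_order_irrelevant(self, rng):
        scores = rng.uniform(size=30)
        flags = rng.uniform(size=30) < 0.2
        flags[0] = True
        sites, truth = make_sites(scores, flags)
        res1 = pr_evaluate(sites, truth)
        perm = rng.permutation(30)
        res2 = pr_evaluate([sites[i] for i in perm], truth)
        assert res1.max_f1 == res2.max_f1
        assert res1.auprc == res2.auprc

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import auc, precision_recall_curve
        scores = rng.uniform(size=200)
        flags = rng.uniform(size=200) < 0.1
        flags[:2] = True
        sites, truth = make_sites(scores, flags)
        res = pr_evaluate(sites, truth)
        prec, rec, _ = precision_recall_curve(flags, scores)
        f1 = 2 * prec[:-1] * rec[:-1] / np.clip(prec[:-1] + rec[:-1],
                                                1e-300, None)
        assert res.max_f1 == pytest.approx(float(f1.max()), rel=1e-12)
        assert res.auprc == pytest.approx(float(auc(rec, prec)), rel=1e-9)

    def test_empty_truth_rejected(self):
        sites, _ = make_sites([1, 2], [False, False])
        with pytest.raises(ValueError):
            pr_evaluate(sites, set())

    def test_truth_set_algebra(self):
        a, b = {1, 2, 3}, {2, 3, 4}
        assert truth_union(a, b) == {1, 2, 3, 4}
        assert truth_intersection(a, b) == {2, 3}


class TestScanGenome:
    def test_planted_sites_rank_first(self, params):
        planted = [ON_TARGET, MismatchPattern((3,)), MismatchPattern((15,)),
                   MismatchPattern((3, 15))]
        seq, locs = generate_toy_genome(GUIDE, planted, length=8000, seed=4)
        sites = scan_genome({"chr": seq}, GUIDE, params)
        assert {(s.start for s in sites[:1])}  # scored and sorted
        planted_starts = {start for start, _ in locs}
        assert {s.start for s in sites[:len(planted)]} == planted_starts
        low_mm = [s for s in sites if s.pattern.n_mismatches <= 4]
        assert {s.start for s in low_mm} == planted_starts
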