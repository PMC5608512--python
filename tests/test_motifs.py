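"""Log-odds scanning, composite assembly, spacing grammar, KS test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from greekislands.motifs import (
    MotifHit,
    PositionFrequencyMatrix,
    assemble_composite,
    best_match_score,
    build_logodds,
    ks_one_sided,
    min_pair_distance,
    nucleotide_class_matrix,
    pair_distances_by_region,
    scan_sequence,
    score_cdf,
)
from greekislands.simulate import default_ebf_pfm, default_lhx2_pfm

import oracles

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def random_pfm(rng, L, name="m"):
    p = rng.dirichlet(np.ones(4), size=L).T
    return PositionFrequencyMatrix(name, p)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestBuildLogodds:
    def test_uniform_column_scores_zero(self):
        pfm = PositionFrequencyMatrix("u", np.full((4, 3), 0.25))
        lom = build_logodds(pfm, UNIFORM, pseudocount=0.01)
        assert np.allclose(lom.weights, 0.0)

    def test_certain_column_without_pseudocount(self):
        pfm = PositionFrequencyMatrix("c", np.array([[1.0], [0], [0], [0]]))
        lom = build_logodds(pfm, UNIFORM, pseudocount=0.0)
        assert lom.weights[0, 0] == pytest.approx(math.log(4.0))

    def test_zero_background_rejected(self):
        pfm = PositionFrequencyMatrix("u", np.full((4, 2), 0.25))
        with pytest.raises(ValueError):
            build_logodds(pfm, (0.5, 0.5, 0.0, 0.0))

    def test_matches_cellwise_formula(self, rng):
        pfm = random_pfm(rng, 8)
        bg = rng.dirichlet(np.ones(4) * 5)
        lom = build_logodds(pfm, bg, pseudocount=0.01)
        for b in range(4):
            for j in range(8):
                expect = math.log(
                    (pfm.probs[b, j] + 0.01 * bg[b]) / ((1 + 0.01) * bg[b])
                )
                assert lom.weights[b, j] == pytest.approx(expect)


class TestScanSequence:
    def test_consensus_hit_scores_column_maxima(self, rng):
        pfm = random_pfm(rng, 7)
        lom = build_logodds(pfm)
        hits = scan_sequence(pfm.consensus, lom, threshold=-1e9)
        plus = [h for h in hits if h.strand == "+"]
        assert plus[0].offset == 0
        assert plus[0].score == pytest.approx(float(lom.weights.max(axis=0).sum()))

    def test_reverse_complement_hits_minus_strand(self):
        pfm = default_lhx2_pfm()  # non-palindromic consensus
        lom = build_logodds(pfm)
        rc = pfm.consensus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        hits = scan_sequence(rc, lom, threshold=lom.max_score - 1e-9)
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].offset == 0

    def test_sequence_shorter_than_motif_is_empty(self):
        lom = build_logodds(default_ebf_pfm())
        assert scan_sequence("ACGT", lom) == []

    def test_matches_bruteforce_scanner(self, rng):
        lom = build_logodds(random_pfm(rng, 6))
        for _ in range(20):
            seq = random_seq(rng, 120)
            if rng.random() < 0.3:  # sprinkle Ns
                pos = rng.integers(0, 120, size=3)
                seq = "".join("N" if i in pos else b for i, b in enumerate(seq))
            got = [(h.offset, h.strand, h.score) for h in scan_sequence(seq, lom, 0.5)]
            exp = oracles.scan_bruteforce(seq, lom.weights, 0.5)
            assert [(o, s) for o, s, _ in exp] == [(o, s) for o, s, _ in got]
            assert np.allclose([s for *_, s in got], [s for *_, s in exp])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=9, max_size=80), st.integers(0, 2**31 - 1))
    def test_strand_symmetry_property(self, seq, pfm_seed):
        """A motif scores a sequence and its reverse complement identically."""
        lom = build_logodds(random_pfm(np.random.default_rng(pfm_seed), 9))
        rc_tab = str.maketrans("ACGTN", "TGCAN")
        fwd = best_match_score(seq, lom)
        rev = best_match_score(seq.translate(rc_tab)[::-1], lom)
        assert fwd == pytest.approx(rev) or (np.isinf(fwd) and np.isinf(rev))


class TestBestMatchScore:
    def test_all_n_sequence_has_no_site(self):
        lom = build_logodds(default_lhx2_pfm())
        assert best_match_score("N" * 50, lom) == -math.inf

    def test_equals_max_over_unthresholded_scan(self, rng):
        lom = build_logodds(random_pfm(rng, 5))
        seq = random_seq(rng, 60)
        hits = scan_sequence(seq, lom, threshold=-math.inf)
        assert best_match_score(seq, lom) == pytest.approx(max(h.score for h in hits))

    def test_monotone_under_extension(self, rng):
        lom = build_logodds(random_pfm(rng, 6))
        seq = random_seq(rng, 40)
        s0 = best_match_score(seq, lom)
        assert best_match_score(seq + random_seq(rng, 20), lom) >= s0

    def test_planted_consensus_recovered(self, rng):
        pfm = default_lhx2_pfm()
        lom = build_logodds(pfm)
        seq = random_seq(rng, 37) + pfm.consensus + random_seq(rng, 30)
        assert best_match_score(seq, lom) >= float(
            sum(lom.weights[:, j].max() for j in range(lom.length))
        ) - 1e-9


class TestAssembleComposite:
    def test_lengths_add(self):
        comp = assemble_composite(default_lhx2_pfm(), default_ebf_pfm(), spacer_bp=2)
        assert comp.length == 6 + 2 + 10

    def test_spacer_contributes_nothing(self, rng):
        a, b = default_lhx2_pfm(), default_ebf_pfm()
        comp = assemble_composite(a, b, spacer_bp=2)
        lom = build_logodds(comp)
        lom_a, lom_b = build_logodds(a), build_logodds(b)
        seq = a.consensus + random_seq(rng, 2) + b.consensus
        hits = [h for h in scan_sequence(seq, lom, -1e9) if h.offset == 0 and h.strand == "+"]
        expect = float(lom_a.weights.max(axis=0).sum() + lom_b.weights.max(axis=0).sum())
        assert hits[0].score == pytest.approx(expect)

    def test_insertion_between_half_sites_breaks_stringent_match(self, rng):
        # spacing grammar: 2 extra bp between the half-sites of a 0-spacer
        # composite drops the best score below the stringent threshold
        a, b = default_lhx2_pfm(), default_ebf_pfm()
        lom = build_logodds(assemble_composite(a, b, spacer_bp=0))
        intact = random_seq(rng, 50) + a.consensus + b.consensus + random_seq(rng, 50)
        spaced = random_seq(rng, 50) + a.consensus + "CA" + b.consensus + random_seq(rng, 50)
        assert best_match_score(intact, lom) > 10.0
        assert best_match_score(spaced, lom) < 10.0


def hit(offset, length, rid="r"):
    return MotifHit(rid, offset, "+", 1.0, "m", length)


class TestMinPairDistance:
    def test_edge_gap(self):
        assert min_pair_distance([hit(10, 10)], [hit(30, 10)]) == 10

    def test_overlap_is_zero(self):
        assert min_pair_distance([hit(10, 10)], [hit(15, 10)]) == 0

    def test_region_without_ebf_hit_excluded(self):
        dists = pair_distances_by_region([], [hit(5, 6, "r1")])
        assert dists == {}

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(30):
            ha = [hit(int(o), int(rng.integers(4, 12))) for o in rng.integers(0, 200, 5)]
            hb = [hit(int(o), int(rng.integers(4, 12))) for o in rng.integers(0, 200, 7)]
            assert min_pair_distance(ha, hb) == oracles.min_pair_bruteforce(ha, hb)


class TestKsOneSided:
    def test_identical_samples(self):
        d, p = ks_one_sided([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_one_sided([], [1.0])

    def test_exact_enumeration_matches_scipy_small_samples(self, rng):
        # tie-free samples: scipy's exact two-sample tail is a valid
        # independent oracle only without ties
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=5)
            d, p = ks_one_sided(a, b, "smaller")
            ref = stats.ks_2samp(a, b, alternative="greater", method="exact")
            assert d == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_shifted_sample_detected(self, rng):
        base = rng.normal(size=400)
        d, p = ks_one_sided(base - 1.0, base, "smaller")
        assert d > 0.3 and p < 1e-10

    def test_greater_alternative_swaps_roles(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=60)
        assert ks_one_sided(a, b, "smaller") == ks_one_sided(b, a, "greater")


class TestScoreCdf:
    def test_steps_and_strict_threshold(self):
        cdf, above = score_cdf([5.0, 10.0, 15.0], thresholds=(10.0, 5.0))
        assert list(cdf.score) == [5.0, 10.0, 15.0]
        assert above[10.0] == pytest.approx(1 / 3)  # score == 10 does not count
        assert above[5.0] == pytest.approx(2 / 3)

    def test_all_failed_scans_never_exceed(self):
        _, above = score_cdf([-math.inf] * 4)
        assert above[10.0] == 0.0 and above[5.0] == 0.0

    def test_matches_sorted_rank_oracle(self, rng):
        scores = rng.normal(size=200) * 5
        cdf, above = score_cdf(scores, thresholds=(3.0,))
        assert above[3.0] == pytest.approx(np.mean(scores > 3.0))
        srt = np.sort(scores)
        assert np.allclose(cdf.score, srt)
        assert np.allclose(cdf.cum_fraction, np.arange(1, 201) / 200)


class TestNucleotideClassMatrix:
    def test_purine_pyrimidine_rows(self):
        mat, freqs = nucleotide_class_matrix(["AG", "CT"])
        assert mat[0].tolist() == ["R", "R"]
        assert mat[1].tolist() == ["Y", "Y"]
        assert freqs.purine.tolist() == [0.5, 0.5]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_class_matrix(["AAA", "AA"])

    def test_column_frequencies_match_tally(self, rng):
        seqs = ["".join("ACGTN"[i] for i in rng.integers(0, 5, 12)) for _ in range(30)]
        _, freqs = nucleotide_class_matrix(seqs)
        for j in range(12):
            col = [s[j] for s in seqs]
            n_r = sum(b in "AG" for b in col)
            n_y = sum(b in "CT" for b in col)
            if n_r + n_y:
                assert freqs.purine[j] == pytest.approx(n_r / (n_r + n_y))
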