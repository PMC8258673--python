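import itertools
from collections import Counter

import numpy as np
import pytest

from trfclash import (
    PairRecord,
    PWMMotif,
    TargetSet,
    Thresholds,
    assemble_target_set,
    combine_orientations,
    compare_motifs,
    dinucleotide_shuffle,
    discover_motif,
    match_to_trf,
    pwm_match_pvalue,
    pwm_score_distribution,
    rank_motifs,
    reverse_complement,
    upstream_downstream_test,
)
from trfclash.motifs import (
    InsufficientTargetsError,
    MotifComparison,
    _column_correlation,
    _log_odds,
    best_pwm_site,
)
from trfclash.simulate import plant_motif_targets, planted_matrix

from conftest import random_seq


def _pairs(trf, targets, orientation="forward", support=1):
    return [
        PairRecord(
            trf_name=trf, transcript_id="tx", target_interval=(1, len(t)),
            orientation=orientation, read_support=support, target_sequence=t,
        )
        for t in targets
    ]


class TestTargetSets:
    def test_polyt_targets_removed_and_duplicates_collapsed(self, thresholds):
        rng = np.random.default_rng(0)
        clean = [random_seq(rng, 30) for _ in range(27)]
        polyt = ["ACG" + "T" * 6 + random_seq(rng, 20) for _ in range(3)]
        pairs = _pairs("t", clean + polyt) + _pairs("t", clean[:5])  # dups
        ts = assemble_target_set("t", pairs, thresholds)
        assert len(ts) == 27
        assert ts.n_removed_polyt == 3
        assert ts.total_read_support == 32  # 27 singles + 5 duplicates

    def test_too_few_targets_raise(self, thresholds):
        rng = np.random.default_rng(1)
        pairs = _pairs("t", [random_seq(rng, 30) for _ in range(5)])
        with pytest.raises(InsufficientTargetsError):
            assemble_target_set("t", pairs, thresholds)


class TestShuffle:
    def test_dinucleotide_counts_preserved(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            seq = random_seq(rng, int(rng.integers(10, 80)))
            sh = dinucleotide_shuffle(seq, rng)
            assert Counter(zip(sh, sh[1:])) == Counter(zip(seq, seq[1:]))
            assert sh[0] == seq[0] and sh[-1] == seq[-1]


class TestDiscovery:
    def test_planted_motif_recovered_with_high_column_correlation(self):
        rng = np.random.default_rng(100)
        cons = "ACGTACGT"
        seqs = plant_motif_targets(cons, 50, 40, 0.9, rng)
        ts = TargetSet("t", "forward", seqs, [1.0] * 50)
        m = discover_motif(ts, widths=[8], seed=3)
        assert m is not None
        assert _column_correlation(m.matrix, planted_matrix(cons, 0.9)) >= 0.9

    def test_identical_sequences_give_degenerate_high_information_motif(self):
        seqs = ["ACGTACGTACGTACGTACGT"] * 12
        ts = TargetSet("t", "forward", seqs, [1.0] * 12)
        m = discover_motif(ts, widths=[8], seed=0, return_all=True)
        assert m is not None
        assert m.information_content.mean() > 1.5

    def test_recovery_rate_monotone_in_site_frequency(self):
        """More frequent planted sites are recovered at least as often."""
        cons = "GATTACAG"
        rates = []
        for freq in (0.3, 0.6, 0.9):
            hits = 0
            for s in range(6):
                rng = np.random.default_rng(1000 + s)
                seqs = plant_motif_targets(cons, 50, 40, 0.95, rng, site_frequency=freq)
                ts = TargetSet("t", "forward", seqs, [1.0] * 50)
                m = discover_motif(ts, widths=[8], seed=s)
                if m is not None and _column_correlation(
                    m.matrix, planted_matrix(cons, 0.95)
                ) >= 0.8:
                    hits += 1
            rates.append(hits)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 5

    def test_polyt_decoys_mask_motif_unless_filtered(self, thresholds):
        """With 30% T-run decoys the unfiltered top motif is T-rich; after the
        polyT partition the planted motif is found."""
        rng = np.random.default_rng(55)
        cons = "GACGATCG"
        clean = plant_motif_targets(cons, 35, 30, 0.95, rng)
        decoys = [random_seq(rng, 10) + "T" * 12 + random_seq(rng, 8) for _ in range(15)]
        pairs = _pairs("t", clean + decoys)
        unfiltered = TargetSet("t", "forward", clean + decoys, [1.0] * 50)
        m_raw = discover_motif(unfiltered, widths=[8], seed=2, return_all=True)
        t_mass = m_raw.matrix[:, 3].mean()
        assert t_mass > 0.7
        ts = assemble_target_set("t", pairs, thresholds)
        assert ts.n_removed_polyt >= 15  # all decoys (plus chance T-runs) gone
        assert len(ts) >= 30
        m = discover_motif(ts, widths=[8], seed=2)
        assert m is not None
        assert _column_correlation(m.matrix, planted_matrix(cons, 0.95)) >= 0.8

    def test_pooling_orientations_rescues_small_sets(self, thresholds):
        rng = np.random.default_rng(66)
        cons = "TTAGGCAT"
        fwd = plant_motif_targets(cons, 8, 30, 0.95, rng)
        rev = plant_motif_targets(cons, 8, 30, 0.95, rng)
        pairs = _pairs("t", fwd, "forward") + _pairs("t", rev, "reverse")
        with pytest.raises(InsufficientTargetsError):
            assemble_target_set("t", pairs, thresholds, "forward")
        fs = rs = None
        mc = combine_orientations(
            TargetSet("t", "forward", fwd, [1.0] * 8),
            TargetSet("t", "reverse", rev, [1.0] * 8),
            thresholds, seed=1, widths=[8],
        )
        assert mc is not None and mc.orientation == "combined"

    def test_one_empty_orientation_equals_single_set_result(self, thresholds):
        rng = np.random.default_rng(67)
        seqs = plant_motif_targets("CCATGAGA", 20, 30, 0.95, rng)
        ts = TargetSet("t", "forward", seqs, [1.0] * 20)
        mc = combine_orientations(ts, None, thresholds, seed=4, widths=[8])
        ms = discover_motif(
            TargetSet("t", "combined", ts.sequences, ts.weights),
            widths=[8], seed=4, thresholds=thresholds,
        )
        assert mc is not None and ms is not None
        assert np.allclose(mc.matrix, ms.matrix)

    def test_higher_support_motif_wins_in_pooled_set(self, thresholds):
        rng = np.random.default_rng(68)
        major = plant_motif_targets("GGATCCAA", 30, 30, 0.95, rng)
        minor = plant_motif_targets("CATCATGT", 10, 30, 0.95, rng)
        ts = TargetSet("t", "combined", major + minor, [1.0] * 40)
        m = discover_motif(ts, widths=[8], seed=5)
        assert m is not None
        assert _column_correlation(m.matrix, planted_matrix("GGATCCAA", 0.95)) >= 0.8


class TestExactPValue:
    def test_width5_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        matrix = rng.dirichlet(np.ones(4), size=5)
        bg = np.array([0.3, 0.2, 0.3, 0.2])
        lods = _log_odds(matrix, bg)
        vals, tail = pwm_score_distribution(lods, bg)
        words = list(itertools.product(range(4), repeat=5))
        scores = []
        probs = []
        for w in words:
            s, p = 0.0, 1.0
            for k in range(5):
                s += lods[k, w[k]]
                p *= bg[w[k]]
            scores.append(s)
            probs.append(p)
        scores, probs = np.array(scores), np.array(probs)
        for threshold in rng.choice(scores, size=50, replace=False):
            p_bf = probs[scores >= threshold - 1e-12].sum()
            idx = np.searchsorted(vals, threshold - 1e-12, side="left")
            p_dp = tail[idx] if idx < len(vals) else 0.0
            assert abs(p_bf - p_dp) <= 1e-9

    def test_tail_is_monotone_in_score(self):
        rng = np.random.default_rng(7)
        matrix = rng.dirichlet(np.ones(4), size=6)
        vals, tail = pwm_score_distribution(_log_odds(matrix, np.full(4, 0.25)), np.full(4, 0.25))
        assert np.all(np.diff(tail) <= 1e-15)

    def test_single_word_pwm_tail_is_quarter_power_width(self):
        cons = "CCCCCC"
        matrix = planted_matrix(cons, 1 - 3e-9)  # effectively all mass on one word
        trf = "AAA" + reverse_complement(cons) + "AAA"
        interval, _score, p = pwm_match_pvalue(matrix, trf)
        assert p == pytest.approx(0.25 ** 6, rel=1e-6)
        assert interval == (4, 9)

    def test_scrambled_trf_rarely_matches(self, thresholds):
        rng = np.random.default_rng(8)
        matrix = planted_matrix("GATCGTCA", 0.9)
        trf = random_seq(rng, 20)
        n_sig = 0
        for _ in range(100):
            scr = "".join(rng.permutation(list(trf)))
            _, _, p = pwm_match_pvalue(matrix, scr)
            if p <= thresholds.matchback_pvalue_max:
                n_sig += 1
        assert n_sig <= 5

    def test_width_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            pwm_match_pvalue(planted_matrix("ACGTACGT", 0.9), "ACGTA")

    def test_match_back_finds_planted_complement(self, thresholds):
        trf = "ACGTACGTACGTACGTACGT"
        cons = reverse_complement(trf[2:10])
        m = PWMMotif("t", "forward", 8, planted_matrix(cons, 0.95), 1e-5, 10)
        assert match_to_trf(m, trf, thresholds)
        assert m.trf_interval == (3, 10)

    def test_best_site_locates_planted_occurrence(self):
        rng = np.random.default_rng(9)
        cons = "GGATACCA"
        seq = random_seq(rng, 12) + cons + random_seq(rng, 10)
        assert best_pwm_site(planted_matrix(cons, 0.95), seq) == 12


class TestComparison:
    def _motif(self, interval, matrix=None, width=8):
        m = PWMMotif(
            "t", "forward", width,
            matrix if matrix is not None else planted_matrix("ACGTACGT", 0.9),
            1e-4, 10,
        )
        m.trf_interval = interval
        return m

    def test_equal_intervals_and_matrices_are_identical(self):
        a, b = self._motif((2, 9)), self._motif((2, 9))
        c = compare_motifs(a, b)
        assert c.cls == "identical" and c.overlap_nt == 8

    def test_partial_overlap_classes(self):
        assert compare_motifs(self._motif((2, 9)), self._motif((5, 12))).cls == "overlap_ge4"
        assert compare_motifs(self._motif((1, 8)), self._motif((13, 20))).cls == "disjoint"
        assert compare_motifs(self._motif((1, 8)), self._motif((7, 14))).cls == "minimal_overlap"

    def test_missing_motif_flagged(self):
        c = compare_motifs(self._motif((2, 9)), None)
        assert c.cls == "one_missing"

    def test_overlap_invariant(self):
        for c in [
            compare_motifs(self._motif((2, 9)), self._motif((5, 12))),
            compare_motifs(self._motif((2, 9)), self._motif((2, 9))),
            compare_motifs(self._motif((1, 8)), self._motif((13, 20))),
        ]:
            assert (c.overlap_nt >= 4) == (c.cls in ("identical", "overlap_ge4"))


class TestUpstreamDownstream:
    def test_reproduces_printed_worked_examples(self):
        comps = [
            MotifComparison("x", "overlap_ge4", 5, 1, 5) for _ in range(60)
        ] + [MotifComparison("x", "overlap_ge4", 5, 5, 1) for _ in range(25)]
        n_f, n_r, p = upstream_downstream_test(comps)
        assert (n_f, n_r) == (60, 25)
        assert p == pytest.approx(1.87e-4, rel=0.05)
        comps = [
            MotifComparison("x", "overlap_ge4", 5, 1, 5) for _ in range(53)
        ] + [MotifComparison("x", "overlap_ge4", 5, 5, 1) for _ in range(20)]
        assert upstream_downstream_test(comps)[2] == pytest.approx(1.42e-4, rel=0.05)

    def test_symmetric_split_is_uninformative(self):
        comps = [MotifComparison("x", "overlap_ge4", 5, 1, 5),
                 MotifComparison("x", "overlap_ge4", 5, 5, 1)]
        assert upstream_downstream_test(comps)[2] == 1.0

    def test_two_sided_symmetry(self):
        from trfclash.stats import binomial_two_sided
        for n in (10, 37, 85):
            for k in range(n + 1):
                assert binomial_two_sided(k, n) == pytest.approx(
                    binomial_two_sided(n - k, n), abs=1e-12
                )

    def test_ties_and_missing_excluded(self):
        comps = [MotifComparison("x", "identical", 8, 3, 3),
                 MotifComparison("x", "one_missing", 0, 3, None)]
        with pytest.raises(ValueError):
            upstream_downstream_test(comps)


class TestRanking:
    def _cohort(self, values):
        out = []
        for i, v in enumerate(values):
            m = PWMMotif("t%d" % i, "forward", 8, planted_matrix("ACGTACGT", 0.9),
                         e_value=1.0 / (v + 1), n_sites=v)
            m.read_support = float(v)
            m.matchback_pvalue = 1.0 / (v + 2)
            out.append(m)
        return out

    def test_nine_distinct_values_flag_exactly_three(self):
        ranked = rank_motifs(self._cohort(list(range(9))))
        for param in ("n_targets", "read_support", "e_value", "matchback_pvalue"):
            assert sum(r.top_tercile[param] for r in ranked) == 3

    def test_all_ties_share_top_tercile(self):
        ranked = rank_motifs(self._cohort([5] * 6))
        assert all(r.high_confidence for r in ranked)

    def test_flags_match_sort_based_oracle(self):
        rng = np.random.default_rng(15)
        values = [int(v) for v in rng.integers(0, 50, 20)]
        ranked = rank_motifs(self._cohort(values))
        import math
        cutoff = math.ceil(len(values) / 3)
        for r in ranked:
            better = sum(1 for v in values if v > r.n_targets)
            assert r.top_tercile["n_targets"] == (better < cutoff)


class TestMatrixIO:
    def test_round_trip(self, tmp_path):
        from trfclash.motifs import read_motif_matrix, write_motif_matrix

        m = PWMMotif("t", "forward", 8, planted_matrix("ACGTACGT", 0.9), 1e-5, 10)
        write_motif_matrix(m, tmp_path / "m.txt")
        back = read_motif_matrix(tmp_path / "m.txt", "t")
        assert back.width == 8
        assert np.allclose(back.matrix, m.matrix, atol=1e-6)
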