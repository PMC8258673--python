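import numpy as np
import pytest

from trfclash import (
    GeneIndex,
    Rejection,
    TranscriptIndex,
    TranscriptModel,
    TRNAGeneModel,
    annotate_target,
    detect_trf_trf,
    find_trf_arm,
    split_read,
    tally_pairs,
)
from trfclash.simulate import SimulationConfig, make_references, simulate_clash_reads
from trfclash.chimera import split_read as _split

from conftest import random_seq


def brute_force_arm(read, genes, orientation, min_len):
    """Exhaustive scan over all anchored read prefixes/suffixes."""
    spaces = []
    for g in genes:
        spaces.append(g.sequence)
        if g.cca_added:
            spaces.append(g.body_cca)
        if g.trailer:
            spaces.append(g.body_trailer)
    best = 0
    for k in range(min_len, len(read) + 1):
        probe = read[:k] if orientation == "forward" else read[len(read) - k :]
        if any(probe in s for s in spaces):
            best = k
    return best


class TestFindArm:
    def test_forward_arm_is_anchored_prefix(self, small_reference, small_indexes):
        genes, _ = small_reference
        gi, _ = small_indexes
        g = genes[0]
        arm = g.body_cca[-18:]  # gene 3' end with CCA
        read = arm + random_seq(np.random.default_rng(1), 22)
        res = find_trf_arm(read, gi, "forward")
        assert res is not None
        (s, e), hits = res
        assert (s, e) == (1, 18)
        assert hits[0][0] == g.gene_id

    def test_reverse_arm_is_anchored_suffix(self, small_reference, small_indexes):
        genes, _ = small_reference
        gi, _ = small_indexes
        g = genes[1]
        read = random_seq(np.random.default_rng(2), 20) + g.sequence[-18:]
        res = find_trf_arm(read, gi, "reverse")
        assert res is not None
        (s, e), _hits = res
        assert (s, e) == (21, 38)

    def test_no_anchored_match_returns_none(self, small_indexes):
        gi, _ = small_indexes
        assert find_trf_arm("ACGT" * 10, gi, "forward") is None

    def test_empty_read_rejected(self, small_indexes):
        gi, _ = small_indexes
        with pytest.raises(ValueError):
            find_trf_arm("", gi, "forward")

    @pytest.mark.parametrize("orientation", ["forward", "reverse"])
    def test_matches_exhaustive_oracle(self, orientation):
        """Anchored-arm search equals brute force on small random instances."""
        rng = np.random.default_rng(31)
        for trial in range(30):
            genes = [
                TRNAGeneModel(
                    gene_id=f"G{trial}-{i:03d}",
                    origin="N",
                    sequence=random_seq(rng, int(rng.integers(60, 101))),
                    anticodon_loop=(30, 36),
                    trailer=random_seq(rng, 10),
                )
                for i in range(int(rng.integers(1, 6)))
            ]
            gi = GeneIndex(genes)
            g = genes[int(rng.integers(len(genes)))]
            start = int(rng.integers(0, g.length - 20))
            piece = g.sequence[start : start + int(rng.integers(16, 21))]
            noise = random_seq(rng, int(rng.integers(10, 30)))
            read = piece + noise if orientation == "forward" else noise + piece
            expected = brute_force_arm(read, genes, orientation, 16)
            res = find_trf_arm(read, gi, orientation)
            got = 0 if res is None else res[0][1] - res[0][0] + 1
            assert got == expected


class TestSplitRead:
    def test_read_inside_trna_is_dominated(self, small_reference, small_indexes):
        genes, _ = small_reference
        gi, ti = small_indexes
        r = split_read("r1", genes[0].sequence[:40], gi, ti, "forward")
        assert isinstance(r, Rejection) and r.reason == "trna_dominated"

    def test_arm_fraction_at_eighty_percent_is_rejected(self, small_reference, small_indexes):
        genes, _ = small_reference
        gi, ti = small_indexes
        read = genes[0].sequence[:36] + "ACGT"  # 36/40 = 0.9 >= 0.8
        r = split_read("r1", read, gi, ti, "forward")
        assert isinstance(r, Rejection) and r.reason == "trna_dominated"

    def test_valid_forward_chimera_decomposed(self, small_reference, small_indexes):
        genes, transcripts = small_reference
        gi, ti = small_indexes
        tx = transcripts[0]
        read = genes[0].sequence[:18] + tx.sequence[99:121]
        d = split_read("r1", read, gi, ti, "forward")
        assert not isinstance(d, Rejection)
        assert d.orientation == "forward"
        assert d.target_annotation[0] == "tx-mrna-1"
        assert d.target_annotation[1] == "mRNA"
        assert d.trf_read_interval == (1, 18)
        assert d.target_read_interval == (19, 40)

    def test_short_target_rejected(self, small_reference, small_indexes):
        genes, transcripts = small_reference
        gi, ti = small_indexes
        stub = "G" if genes[0].sequence[18] != "G" else "C"  # no arm extension
        read = genes[0].sequence[:18] + stub * 5
        r = split_read("r1", read, gi, ti, "forward")
        assert isinstance(r, Rejection) and r.reason == "target_too_short"

    def test_unmappable_target_rejected(self, small_reference, small_indexes):
        genes, _ = small_reference
        gi, ti = small_indexes
        read = genes[0].sequence[:18] + "T" * 20
        r = split_read("r1", read, gi, ti, "forward")
        assert isinstance(r, Rejection) and r.reason == "target_unannotated"


class TestTrfTrf:
    def test_two_genes_on_both_ends(self, small_reference, small_indexes):
        genes, _ = small_reference
        gi, _ = small_indexes
        read = genes[0].sequence[:18] + genes[1].sequence[-18:]
        assert detect_trf_trf(read, gi) == "different_gene_pair"

    def test_disjoint_fragments_of_one_gene(self, small_reference, small_indexes):
        genes, _ = small_reference
        gi, _ = small_indexes
        g = genes[2]
        read = g.sequence[:18] + g.sequence[g.length - 18 :]
        assert detect_trf_trf(read, gi) == "same_gene_disjoint"

    def test_trf_target_read_is_not_trf_trf(self, small_reference, small_indexes):
        genes, transcripts = small_reference
        gi, _ = small_indexes
        read = genes[0].sequence[:18] + transcripts[0].sequence[50:75]
        assert detect_trf_trf(read, gi) == "not_trf_trf"


class TestAnnotateTarget:
    def test_utr3_segment_labelled(self, small_reference, small_indexes):
        _, transcripts = small_reference
        _, ti = small_indexes
        seg = transcripts[0].sequence[259:280]  # fully inside the 3'UTR
        tid, cat, region, start = annotate_target(seg, ti)
        assert (tid, cat, region, start) == ("tx-mrna-1", "mRNA", "3UTR", 260)

    def test_rrna_segment_has_no_region(self, small_reference, small_indexes):
        _, transcripts = small_reference
        _, ti = small_indexes
        seg = transcripts[1].sequence[10:35]
        tid, cat, region, _ = annotate_target(seg, ti)
        assert (tid, cat, region) == ("tx-rrna-1", "rRNA", None)

    def test_boundary_segment_gets_majority_region(self, small_reference, small_indexes):
        _, transcripts = small_reference
        _, ti = small_indexes
        # 15 nt of CDS (226..240) + 5 nt of 3'UTR (241..245): majority CDS
        seg = transcripts[0].sequence[225:245]
        _, _, region, _ = annotate_target(seg, ti)
        assert region == "CDS"

    def test_exact_tie_uses_precedence(self):
        rng = np.random.default_rng(5)
        tx = TranscriptModel(
            "tie-tx", "mRNA", random_seq(rng, 100),
            regions=[("CDS", (1, 50)), ("3UTR", (51, 100))],
        )
        ti = TranscriptIndex([tx])
        seg = tx.sequence[40:60]  # 10 nt CDS + 10 nt 3UTR
        _, _, region, _ = annotate_target(seg, ti)
        assert region == "3UTR"


class TestTally:
    def test_supports_and_two_read_flags(self, small_reference, small_indexes):
        genes, transcripts = small_reference
        gi, ti = small_indexes
        read_a = genes[0].sequence[:18] + transcripts[0].sequence[99:121]
        read_b = genes[0].sequence[:18] + transcripts[0].sequence[149:171]
        decomps = [
            _split(f"r{i}", read_a, gi, ti, "forward") for i in range(3)
        ] + [_split("r9", read_b, gi, ti, "forward")]
        pairs, summary = tally_pairs(decomps)
        assert sorted(p.read_support for p in pairs) == [1, 3]
        assert {p.read_support: p.two_read_supported for p in pairs} == {3: True, 1: False}
        assert summary["reads"].sum() == 4
        assert summary["reads_ge2"].sum() == 3

    def test_empty_input_gives_empty_table(self):
        pairs, summary = tally_pairs([])
        assert pairs == [] and summary.empty


class TestGeneratorRecovery:
    def test_noise_free_reads_fully_recovered(self):
        """Every simulated guide+target read decomposes to its truth record."""
        from trfclash import GeneIndex, TranscriptIndex

        cfg = SimulationConfig(seed=5, n_genes=6, n_clash_reads=500)
        refs = make_references(cfg)
        reads, truth = simulate_clash_reads(cfg, refs)
        gi, ti = GeneIndex(refs.genes), TranscriptIndex(refs.transcripts)
        truth_by_id = {r["read_id"]: r for r in truth.reads.to_dict("records")}
        n_pairs = 0
        for rid, seq in reads:
            row = truth_by_id[rid]
            if row["kind"] != "pair":
                continue
            n_pairs += 1
            d = split_read(rid, seq, gi, ti, row["orientation"])
            assert not isinstance(d, Rejection), (rid, d)
            assert d.trf.name == row["trf_name"]
            assert d.target_annotation[0] == row["transcript_id"]
            assert d.orientation == row["orientation"]
            # the two arms partition the read exactly
            ti_, tt = d.trf_read_interval, d.target_read_interval
            covered = (ti_[1] - ti_[0] + 1) + (tt[1] - tt[0] + 1)
            assert covered == len(seq)
            assert (ti_[1] - ti_[0] + 1) / len(seq) < 0.8
        assert n_pairs > 300

    def test_summary_marginals_conserve_accepted_reads(self):
        from trfclash import GeneIndex, TranscriptIndex, parse_reads

        cfg = SimulationConfig(seed=6, n_genes=6, n_clash_reads=400)
        refs = make_references(cfg)
        reads, truth = simulate_clash_reads(cfg, refs)
        gi, ti = GeneIndex(refs.genes), TranscriptIndex(refs.transcripts)
        fwd_ids = set(truth.reads.query("orientation == 'forward'")["read_id"])
        fwd, counts_f = parse_reads(
            [(r, s) for r, s in reads if r in fwd_ids], gi, ti, "forward"
        )
        _pairs, summary = tally_pairs(fwd)
        assert summary["reads"].sum() == counts_f["accepted"] == len(fwd)
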