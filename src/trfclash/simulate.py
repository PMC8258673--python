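"""Synthetic workspace generator with planted ground truth.

Everything the pipeline consumes can be emulated here: tRNA gene models,
a transcript reference, chimeric guide-target reads in both orientations,
PAR-CLIP-style reads with T->C conversions, and a per-nucleotide reactivity
track.  The generator plants a known tRF per gene (with the field's
characteristic length modes: 18 nt for tRF-3p, 33-36 nt for tRF-5i halves),
a complementary binding motif on each tRF, a crosslinking hotspot inside
the 8-12 nt region, orientation-biased chimera formation, polyT tail
artifacts restricted to forward targets, and a double-/single-stranded
reactivity contrast at target sites — and records every planted fact in a
truth table so each analysis stage can be scored against it.

Chimera orientation follows a two-parameter generative mechanism: each tRF
binds its targets on one side of the crosslinking hotspot (upstream with
probability ``beta``); upstream binding leaves the tRF 3' end free and
favours forward ligation with probability ``p_forward_upstream``, downstream
binding the opposite.  tRF-5i guides carry a 2',3'-cyclic-phosphate-like
forward-ligation penalty: a forward ligation attempt simply fails with
probability ``gamma`` and the read is never formed, thinning 5i forward
pairs by the factor (1 - gamma) without inflating the reverse set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import reverse_complement
from .reference import TranscriptModel, TRNAGeneModel
from .taxonomy import TRFRecord, make_trf_record

__all__ = [
    "SimulationConfig",
    "PlantedTRF",
    "References",
    "ClashTruth",
    "generate_workspace",
    "make_references",
    "simulate_clash_reads",
    "simulate_parclip_reads",
    "simulate_reactivity",
    "plant_motif_targets",
    "planted_matrix",
]

_BASES = "ACGT"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    out = []
    for c in seq:
        if rng.random() < identity:
            out.append(c)
        else:
            out.append(_BASES[(_BASES.index(c) + 1 + rng.integers(3)) % 4])
    return "".join(out)


def planted_matrix(consensus: str, identity: float) -> np.ndarray:
    """The PWM a consensus planted at a given per-position identity implies."""
    w = len(consensus)
    m = np.full((w, 4), (1 - identity) / 3)
    for i, c in enumerate(consensus):
        m[i, _BASES.index(c)] = identity
    return m


def plant_motif_targets(
    consensus: str,
    n: int,
    length: int,
    identity: float,
    rng: np.random.Generator,
    site_frequency: float = 1.0,
) -> list[str]:
    """Random sequences with the consensus planted at ``identity`` per base.

    A site is embedded (at a random position) in each sequence with
    probability ``site_frequency``; used for motif parameter-recovery and
    null-calibration experiments.
    """
    w = len(consensus)
    if length < w:
        raise ValueError("sequences shorter than the motif")
    out = []
    for _ in range(n):
        s = list(_random_seq(rng, length))
        if rng.random() < site_frequency:
            pos = int(rng.integers(0, length - w + 1))
            s[pos : pos + w] = _mutate(consensus, identity, rng)
        out.append("".join(s))
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    seed: int = 0
    # references
    n_genes: int = 12
    gene_length_range: tuple[int, int] = (70, 90)
    anticodon_loop: tuple[int, int] = (32, 38)
    trailer_length: int = 15
    n_mrna: int = 40
    n_rrna: int = 2
    n_mirna: int = 3
    n_other: int = 3
    mrna_length: int = 450
    # planted tRFs and motifs
    motif_width: int = 8
    site_identity: float = 0.9
    n_slots_per_trf: int = 30
    hotspot_position: int = 10  # tRF coordinate, inside the 8-12 nt region
    # orientation model
    beta: float = 0.8  # P(binding upstream of the hotspot)
    p_forward_upstream: float = 0.8
    gamma: float = 0.9  # 5i forward-ligation failure probability
    # chimeric reads
    n_clash_reads: int = 2000
    target_flank_left: int = 10
    target_flank_right: int = 10
    polyt_rate: float = 0.1
    polyt_run_range: tuple[int, int] = (5, 9)
    trf_trf_fraction: float = 0.02
    pure_trna_fraction: float = 0.02
    # PAR-CLIP reads
    n_parclip_reads: int = 10000
    n_parclip_samples: int = 3
    conversion_rate: float = 0.3
    background_conversion_rate: float = 0.01
    short_read_fraction: float = 0.1
    short_read_length: int = 14
    # reactivity
    p_ds: float = 0.983
    reactivity_delta: float = 0.3

    def replace(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class PlantedTRF:
    record: TRFRecord
    space: str
    motif_interval: tuple[int, int]  # on the tRF, 1-based
    site_consensus: str  # target-strand consensus (revcomp of the tRF window)
    hotspot: int  # tRF coordinate of the planted conversion site
    binding_side: str  # upstream | downstream
    clean_slots: list[tuple[str, int]] = field(default_factory=list)
    polyt_slots: list[tuple[str, int]] = field(default_factory=list)

    @property
    def name(self) -> str:
        return self.record.name


@dataclass
class References:
    genes: list[TRNAGeneModel]
    transcripts: list[TranscriptModel]
    planted: list[PlantedTRF]

    def gene(self, gene_id: str) -> TRNAGeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


_TYPE_CYCLE = ("3p", "5i", "5p", "3t", "i", "3i")


def _plan_interval(
    trf_type: str, L: int, loop: tuple[int, int], rng: np.random.Generator
) -> tuple[int, int, str]:
    """(start, end, space) of a planted fragment of the requested type."""
    ls, le = loop
    if trf_type == "3p":  # 18 nt ending at the CCA end: the modal tRF-3p
        return L + 3 - 17, L + 3, "body+CCA"
    if trf_type == "5i":  # 33-36 nt halves ending in the anticodon loop
        end = int(rng.integers(max(33, ls), min(36, le) + 1))
        return 1, end, "body"
    if trf_type == "5p":
        return 1, 20, "body"
    if trf_type == "3t":  # straddles the gene 3' border into the trailer
        return L - 10, L + 10, "body+trailer"
    if trf_type == "i":
        return 8, 27, "body"
    if trf_type == "3i":  # starts in the loop, runs to the CCA end
        return int(rng.integers(ls, le + 1)), L + 3, "body+CCA"
    raise ValueError(trf_type)


def make_references(config: SimulationConfig) -> References:
    """Deterministically build gene models, transcripts, and planted truth.

    One tRF is planted per gene, cycling through the six types; the gene
    sequence is edited so the planted crosslinking hotspot falls on a T and
    the planted binding motif sits entirely on the chosen side of it.
    Target-site "slots" (the motif's reverse-complement consensus, mutated
    per slot at the configured identity, plus safe junction bases) are
    written into the transcript sequences so every emitted target arm is an
    exact transcript substring.
    """
    rng = np.random.default_rng([config.seed, 101])
    genes: list[TRNAGeneModel] = []
    planted: list[PlantedTRF] = []
    w = config.motif_width
    h = config.hotspot_position

    specs = []
    for i in range(config.n_genes):
        L = int(rng.integers(*config.gene_length_range, endpoint=True))
        seq = list(_random_seq(rng, L))
        trf_type = _TYPE_CYCLE[i % len(_TYPE_CYCLE)]
        start, end, space = _plan_interval(trf_type, L, config.anticodon_loop, rng)
        side = "upstream" if rng.random() < config.beta else "downstream"
        # hotspot must be a T of the gene body
        hot_gene_pos = start + h - 1
        if hot_gene_pos > L:  # inside CCA/trailer: shift the hotspot left onto the body
            hot_gene_pos = min(L, hot_gene_pos)
        seq[hot_gene_pos - 1] = "T"
        gene_id = f"Gene{chr(65 + i // 10)}{i % 10:02d}-{i + 1:03d}"
        trailer = _random_seq(rng, config.trailer_length)
        if trailer.startswith("CC"):
            # keep CCA- and trailer-extended products distinguishable
            trailer = "GA" + trailer[2:]
        genes.append(
            TRNAGeneModel(
                gene_id=gene_id,
                origin="N",
                sequence="".join(seq),
                anticodon_loop=config.anticodon_loop,
                trailer=trailer,
                cca_added=True,
            )
        )
        specs.append((gene_id, trf_type, start, end, space, side, hot_gene_pos))

    # transcripts
    rrna_len = 500
    mirna_len = 70
    other_len = 200
    transcripts: list[TranscriptModel] = []
    tx_seqs: dict[str, list[str]] = {}
    tx_meta: list[tuple[str, str, list]] = []
    ml = config.mrna_length
    for i in range(config.n_mrna):
        tid = f"mRNA{i + 1:03d}"
        tx_seqs[tid] = list(_random_seq(rng, ml))
        u5 = ml // 5
        cds = ml * 3 // 5
        regions = [
            ("5UTR", (1, u5)),
            ("CDS", (u5 + 1, u5 + cds)),
            ("3UTR", (u5 + cds + 1, ml)),
        ]
        tx_meta.append((tid, "mRNA", regions))
    for i in range(config.n_rrna):
        tid = f"rRNA{i + 1:02d}"
        tx_seqs[tid] = list(_random_seq(rng, rrna_len))
        tx_meta.append((tid, "rRNA", []))
    for i in range(config.n_mirna):
        tid = f"miRNA{i + 1:02d}"
        tx_seqs[tid] = list(_random_seq(rng, mirna_len))
        tx_meta.append((tid, "miRNA", []))
    for i in range(config.n_other):
        tid = f"ncRNA{i + 1:02d}"
        tx_seqs[tid] = list(_random_seq(rng, other_len))
        tx_meta.append((tid, "other_ncRNA", []))

    # site slots: disjoint windows per planted interaction, written in place
    window = config.target_flank_left + w + config.target_flank_right
    cursors = {tid: 5 for tid in tx_seqs}
    mrna_ids = [t for t, c, _ in tx_meta if c == "mRNA"]

    for gene_model, (gene_id, trf_type, start, end, space, side, hot_gene_pos) in zip(
        genes, specs
    ):
        rec = make_trf_record(gene_model, start, end, space=space)
        hotspot = hot_gene_pos - start + 1
        if side == "upstream":
            m_start = max(1, hotspot - 1 - w)
        else:
            m_start = hotspot + 1
        m_end = m_start + w - 1
        if m_end > rec.length:  # fragment too short downstream: fall back upstream
            m_start = max(1, hotspot - 1 - w)
            m_end = m_start + w - 1
            side = "upstream"
        trf_window = rec.sequence[m_start - 1 : m_end]
        site_consensus = reverse_complement(trf_window)
        p = PlantedTRF(
            record=rec,
            space=space,
            motif_interval=(m_start, m_end),
            site_consensus=site_consensus,
            hotspot=hotspot,
            binding_side=side,
        )

        n_polyt = max(1, int(round(config.polyt_rate * config.n_slots_per_trf)))
        for s in range(config.n_slots_per_trf):
            tid = mrna_ids[int(rng.integers(len(mrna_ids)))]
            seq = tx_seqs[tid]
            pos = cursors[tid]
            if pos + window + 2 >= len(seq):
                # fall back to the least-used transcript
                tid = min(mrna_ids, key=lambda t: (cursors[t], t))
                seq = tx_seqs[tid]
                pos = cursors[tid]
                if pos + window + 2 >= len(seq):
                    raise ValueError("transcriptome too small for requested slots")
            cursors[tid] = pos + window + 2  # leave a spacer between slots
            site = _mutate(site_consensus, config.site_identity, rng)
            seq[pos + config.target_flank_left : pos + config.target_flank_left + w] = list(site)
            is_polyt = s < n_polyt
            if is_polyt:
                run = int(rng.integers(*config.polyt_run_range, endpoint=True))
                seq[pos + window - run : pos + window] = ["T"] * run
            # junction safety: the window must not extend the tRF arm match
            nxt = _gene_next_base(gene_model, rec, space)
            if nxt is not None and seq[pos] == nxt:
                seq[pos] = _BASES[(_BASES.index(nxt) + 1) % 4]
            prv = _gene_prev_base(gene_model, rec)
            if prv is not None and seq[pos + window - 1] == prv:
                if not is_polyt:  # keep planted polyT tails intact
                    seq[pos + window - 1] = _BASES[(_BASES.index(prv) + 1) % 4]
            slot = (tid, pos + 1)  # 1-based window start
            (p.polyt_slots if is_polyt else p.clean_slots).append(slot)
        planted.append(p)

    for tid, category, regions in tx_meta:
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                category=category,
                sequence="".join(tx_seqs[tid]),
                regions=regions,
            )
        )
    return References(genes=genes, transcripts=transcripts, planted=planted)


def _gene_next_base(model: TRNAGeneModel, rec: TRFRecord, space: str) -> str | None:
    ext = model.extended_sequence(space)
    return ext[rec.end] if rec.end < len(ext) else None


def _gene_prev_base(model: TRNAGeneModel, rec: TRFRecord) -> str | None:
    return model.sequence[rec.start - 2] if rec.start > 1 else None


@dataclass
class ClashTruth:
    reads: pd.DataFrame  # per-read truth records
    planted: list[PlantedTRF]


def simulate_clash_reads(
    config: SimulationConfig, references: References
) -> tuple[list[tuple[str, str]], ClashTruth]:
    """Emit chimeric reads as (id, sequence) with a per-read truth table.

    Orientation follows the upstream/downstream binding mechanism described
    in the module docstring; polyT artifact slots are used only by forward
    reads; tRF-tRF chimeras and pure-tRNA reads are injected as negative
    controls at the configured fractions.
    """
    rng = np.random.default_rng([config.seed, 202])
    planted = references.planted
    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    window = config.target_flank_left + config.motif_width + config.target_flank_right
    tx_by_id = {t.transcript_id: t for t in references.transcripts}

    n = config.n_clash_reads
    for i in range(n):
        rid = f"read{i:06d}"
        u = rng.random()
        if u < config.trf_trf_fraction:
            seq, kind = _make_trf_trf(config, references, rng)
            reads.append((rid, seq))
            rows.append({"read_id": rid, "kind": kind, "trf_name": "", "transcript_id": "",
                         "target_start": 0, "orientation": "", "polyt": False})
            continue
        if u < config.trf_trf_fraction + config.pure_trna_fraction:
            g = references.genes[int(rng.integers(len(references.genes)))]
            L = min(40, g.length)
            s = int(rng.integers(0, g.length - L + 1))
            reads.append((rid, g.sequence[s : s + L]))
            rows.append({"read_id": rid, "kind": "pure_trna", "trf_name": "", "transcript_id": "",
                         "target_start": 0, "orientation": "", "polyt": False})
            continue
        # guide-target chimera; 5i forward ligation may fail (cyclic phosphate)
        while True:
            p = planted[int(rng.integers(len(planted)))]
            p_fwd = (
                config.p_forward_upstream
                if p.binding_side == "upstream"
                else 1 - config.p_forward_upstream
            )
            forward = rng.random() < p_fwd
            if forward and p.record.type == "5i" and rng.random() < config.gamma:
                continue  # ligation failed; no read formed
            break
        use_polyt = forward and p.polyt_slots and rng.random() < config.polyt_rate
        slots = p.polyt_slots if use_polyt else p.clean_slots
        tid, start = slots[int(rng.integers(len(slots)))]
        target = tx_by_id[tid].sequence[start - 1 : start - 1 + window]
        seq = p.record.sequence + target if forward else target + p.record.sequence
        reads.append((rid, seq))
        rows.append(
            {
                "read_id": rid,
                "kind": "pair",
                "trf_name": p.name,
                "transcript_id": tid,
                "target_start": start,
                "orientation": "forward" if forward else "reverse",
                "polyt": bool(use_polyt),
            }
        )
    truth = ClashTruth(reads=pd.DataFrame(rows), planted=planted)
    return reads, truth


def _make_trf_trf(
    config: SimulationConfig, references: References, rng: np.random.Generator
) -> tuple[str, str]:
    genes = references.genes
    if rng.random() < 0.5 and len(genes) >= 2:
        ga, gb = rng.choice(len(genes), size=2, replace=False)
        a = genes[int(ga)].sequence[:18]
        b = genes[int(gb)].sequence[-18:]
        return a + b, "trf_trf_different"
    g = genes[int(rng.integers(len(genes)))]
    a = g.sequence[:18]
    b = g.sequence[g.length - 18 :]
    return a + b, "trf_trf_same_disjoint"


def simulate_parclip_reads(
    config: SimulationConfig, references: References
) -> tuple[list[tuple[str, str, int]], list[int], pd.DataFrame]:
    """Emit PAR-CLIP-style reads as (id, sequence, sample index).

    Reads copy planted tRF sequences with T->C conversion at the hotspot at
    ``conversion_rate`` and at other T positions at the background rate; a
    configured fraction is truncated below the 16 nt inclusion filter.
    Returns (reads, per-sample emitted totals, per-read truth).
    """
    rng = np.random.default_rng([config.seed, 303])
    planted = references.planted
    for p in planted:
        if p.record.sequence[p.hotspot - 1] != "T":
            raise ValueError(f"{p.name}: planted hotspot is not a T")
    reads: list[tuple[str, str, int]] = []
    rows: list[dict] = []
    totals = [0] * config.n_parclip_samples
    for i in range(config.n_parclip_reads):
        p = planted[int(rng.integers(len(planted)))]
        sample = int(rng.integers(config.n_parclip_samples))
        seq = list(p.record.sequence)
        converted: list[int] = []
        for j, c in enumerate(seq):
            if c != "T":
                continue
            rate = (
                config.conversion_rate
                if j + 1 == p.hotspot
                else config.background_conversion_rate
            )
            if rng.random() < rate:
                seq[j] = "C"
                converted.append(j + 1)
        if len(converted) > 1:  # the aligner accepts at most one conversion
            keep = converted[int(rng.integers(len(converted)))]
            for pos in converted:
                if pos != keep:
                    seq[pos - 1] = "T"
            converted = [keep]
        short = rng.random() < config.short_read_fraction
        out = "".join(seq[: config.short_read_length]) if short else "".join(seq)
        rid = f"pc{i:06d}"
        reads.append((rid, out, sample))
        totals[sample] += 1
        rows.append(
            {
                "read_id": rid,
                "trf_name": p.name,
                "sample": sample,
                "conversion_pos": converted[0] if converted else 0,
                "short": short,
            }
        )
    return reads, totals, pd.DataFrame(rows)


def simulate_reactivity(
    config: SimulationConfig,
    references: References,
    truth: ClashTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-nucleotide reactivity scores for mRNA transcripts.

    Background positions draw i.i.d. uniform scores; each planted target
    site is double-stranded with probability ``p_ds`` (its motif-region
    scores shifted down by delta) else single-stranded (shifted up), always
    clipped to [0, 1].  Returns (track, per-site truth) where track has
    columns transcript_id / position / score.
    """
    rng = np.random.default_rng([config.seed, 404])
    scores: dict[str, np.ndarray] = {}
    for t in references.transcripts:
        if t.category == "mRNA":
            scores[t.transcript_id] = rng.uniform(0, 1, size=t.length)
    site_rows: list[dict] = []
    w = config.motif_width
    for p in references.planted:
        for tid, start in p.clean_slots + p.polyt_slots:
            if tid not in scores:
                continue
            m0 = start - 1 + config.target_flank_left  # 0-based motif start
            ds = rng.random() < config.p_ds
            shift = -config.reactivity_delta if ds else config.reactivity_delta
            scores[tid][m0 : m0 + w] = np.clip(scores[tid][m0 : m0 + w] + shift, 0, 1)
            site_rows.append(
                {
                    "trf_name": p.name,
                    "transcript_id": tid,
                    "motif_start": m0 + 1,
                    "motif_end": m0 + w,
                    "ds": ds,
                }
            )
    rows = []
    for tid in sorted(scores):
        for pos, s in enumerate(scores[tid], start=1):
            rows.append((tid, pos, round(float(s), 4)))
    track = pd.DataFrame(rows, columns=["transcript_id", "position", "score"])
    return track, pd.DataFrame(site_rows)


def generate_workspace(config: SimulationConfig):
    """References plus all three simulated inputs, in one call."""
    refs = make_references(config)
    clash_reads, clash_truth = simulate_clash_reads(config, refs)
    parclip_reads, totals, parclip_truth = simulate_parclip_reads(config, refs)
    track, site_truth = simulate_reactivity(config, refs, clash_truth)
    return {
        "references": refs,
        "clash_reads": clash_reads,
        "clash_truth": clash_truth,
        "parclip_reads": parclip_reads,
        "parclip_totals": totals,
        "parclip_truth": parclip_truth,
        "reactivity": track,
        "site_truth": site_truth,
    }
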