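"""Decomposition of chimeric guide-target reads into tRF arm + target arm.

A chimeric read carries a tRF ligated to its bound target in one of two
orientations: *forward* (tRF on the 5' end of the read, target on the 3'
end) or *reverse* (target first, tRF anchored at the last nucleotide).  The
tRF arm is the longest exact match to any tRNA gene (body, CCA-extended or
trailer-extended sequence) anchored at the corresponding read end; matching
is exact by construction — only fragments perfectly mapping to tRNAs are
accepted.  Reads with >= 80% of their length inside a tRNA are excluded, as
are reads whose remaining target arm is too short or cannot be placed on any
reference transcript.  Reads carrying tRNA matches on both ends (tRF-tRF
chimeras) are classified separately and removed from the tRF-target stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .reference import Thresholds, TranscriptModel, TRNAGeneModel, normalize_sequence
from .taxonomy import TRFRecord, make_trf_record

__all__ = [
    "GeneIndex",
    "TranscriptIndex",
    "ChimeraDecomposition",
    "Rejection",
    "PairRecord",
    "find_trf_arm",
    "split_read",
    "detect_trf_trf",
    "annotate_target",
    "tally_pairs",
    "parse_reads",
    "read_sequences",
]

_SPACE_ORDER = ("body", "body+CCA", "body+trailer")

# region-label precedence for boundary-spanning target segments
_REGION_PRECEDENCE = {"3UTR": 0, "CDS": 1, "5UTR": 2, "intron": 3}


class GeneIndex:
    """Exact-substring queries over all tRNA gene extended sequences."""

    def __init__(self, models: Iterable[TRNAGeneModel]):
        self.models = sorted(models, key=lambda m: m.gene_id)
        if not self.models:
            raise ValueError("gene index needs at least one gene model")
        self.by_id = {m.gene_id: m for m in self.models}
        self._spaces: list[tuple[str, str, str]] = []  # (gene_id, space, seq)
        for m in self.models:
            self._spaces.append((m.gene_id, "body", m.sequence))
            if m.cca_added:
                self._spaces.append((m.gene_id, "body+CCA", m.body_cca))
            if m.trailer:
                self._spaces.append((m.gene_id, "body+trailer", m.body_trailer))

    def longest_anchored_match(
        self, read: str, orientation: str, min_len: int
    ) -> tuple[int, list[tuple[str, str, int]]]:
        """Longest read prefix (forward) / suffix (reverse) found in any gene.

        Returns (match length, [(gene_id, space, 1-based start in space)]);
        length 0 when nothing of at least ``min_len`` matches.  Within one
        gene space the 5'-most occurrence is reported.
        """
        if orientation not in ("forward", "reverse"):
            raise ValueError(f"unknown orientation {orientation!r}")
        n = len(read)

        def probe(k: int) -> str:
            return read[:k] if orientation == "forward" else read[n - k :]

        best = 0
        per_space: list[tuple[int, str, str, int]] = []
        for gene_id, space, seq in self._spaces:
            # monotone in k, so binary search the longest anchored match
            lo, hi = 0, min(n, len(seq))
            if hi < min_len or probe(min_len) not in seq:
                continue
            lo = min_len
            while lo < hi:
                mid = (lo + hi + 1) // 2
                if probe(mid) in seq:
                    lo = mid
                else:
                    hi = mid - 1
            pos = seq.find(probe(lo)) + 1
            per_space.append((lo, gene_id, space, pos))
            best = max(best, lo)
        if best < min_len:
            return 0, []
        hits = [(g, sp, pos) for k, g, sp, pos in per_space if k == best]
        # deterministic: gene_id, then body < body+CCA < body+trailer
        hits.sort(key=lambda h: (h[0], _SPACE_ORDER.index(h[1])))
        return best, hits


class TranscriptIndex:
    """Exact-substring queries over reference transcripts (tRNAs excluded)."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts = sorted(
            (t for t in transcripts if t.category != "tRNA"),
            key=lambda t: t.transcript_id,
        )
        self.by_id = {t.transcript_id: t for t in self.transcripts}

    def find(self, segment: str) -> list[tuple[TranscriptModel, int]]:
        """All transcripts containing ``segment``; 1-based start, 5'-most hit."""
        hits = []
        for t in self.transcripts:
            pos = t.sequence.find(segment)
            if pos >= 0:
                hits.append((t, pos + 1))
        return hits


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # no_trf_arm | trna_dominated | target_too_short | target_unannotated


@dataclass
class ChimeraDecomposition:
    """A read split into a tRF arm and a target arm."""

    read_id: str
    orientation: str
    trf: TRFRecord
    trf_read_interval: tuple[int, int]
    target_sequence: str
    target_read_interval: tuple[int, int]
    target_annotation: tuple[str, str, str | None]  # transcript, category, region
    target_position: int  # 1-based start of the target segment on the transcript
    ambiguity: list[str] = field(default_factory=list)


@dataclass
class PairRecord:
    trf_name: str
    transcript_id: str
    target_interval: tuple[int, int]
    orientation: str
    read_support: int
    trf_type: str = "i"
    target_category: str = "mRNA"
    target_sequence: str = ""

    @property
    def two_read_supported(self) -> bool:
        return self.read_support >= 2


def find_trf_arm(
    read_sequence: str,
    gene_index: GeneIndex,
    orientation: str,
    thresholds: Thresholds = Thresholds(),
) -> tuple[tuple[int, int], list[tuple[str, str, int]]] | None:
    """Locate the anchored tRF arm of a read.

    Returns the 1-based read interval of the arm plus the list of equally
    long gene matches (gene_id, space, start-in-space), or None when no
    anchored match of at least ``min_trf_arm`` nt exists.
    """
    if not read_sequence:
        raise ValueError("empty read")
    read = normalize_sequence(read_sequence)
    k, hits = gene_index.longest_anchored_match(
        read, orientation, thresholds.min_trf_arm
    )
    if k == 0:
        return None
    if orientation == "forward":
        interval = (1, k)
    else:
        interval = (len(read) - k + 1, len(read))
    return interval, hits


def _trf_from_hits(
    gene_index: GeneIndex, hits: list[tuple[str, str, int]], arm_len: int
) -> tuple[TRFRecord, list[str]]:
    """Canonical record from the lexicographically smallest matching gene."""
    gene_id, space, start = hits[0]
    model = gene_index.by_id[gene_id]
    rec = make_trf_record(model, start, start + arm_len - 1, space=space)
    ambiguity = sorted({g for g, _, _ in hits[1:] if g != gene_id})
    return rec, ambiguity


def annotate_target(
    target_sequence: str, transcript_index: TranscriptIndex
) -> tuple[str, str, str | None, int] | None:
    """Place a target arm on the reference by exact substring match.

    Multi-transcript hits resolve to the lexicographically smallest
    transcript id.  For mRNA the region label is assigned by majority
    overlap with the transcript's region map; ties break by the precedence
    3UTR > CDS > 5UTR > intron.  Returns (transcript_id, category,
    region_label or None, 1-based start) or None when unplaceable.
    """
    hits = transcript_index.find(target_sequence)
    if not hits:
        return None
    tx, start = hits[0]  # index is sorted by transcript_id
    end = start + len(target_sequence) - 1
    region: str | None = None
    if tx.category == "mRNA" and tx.regions:
        overlaps = tx.region_overlaps(start, end)
        if overlaps:
            region = min(
                overlaps.items(), key=lambda kv: (-kv[1], _REGION_PRECEDENCE[kv[0]])
            )[0]
    return tx.transcript_id, tx.category, region, start


def split_read(
    read_id: str,
    read_sequence: str,
    gene_index: GeneIndex,
    transcript_index: TranscriptIndex,
    orientation: str,
    thresholds: Thresholds = Thresholds(),
) -> ChimeraDecomposition | Rejection:
    """Decompose one read into tRF arm + target arm, or reject it.

    Rejection reasons: ``no_trf_arm`` (no anchored tRNA match),
    ``trna_dominated`` (arm covers >= 80% of the read), ``target_too_short``
    and ``target_unannotated``.
    """
    read = normalize_sequence(read_sequence)
    arm = find_trf_arm(read, gene_index, orientation, thresholds)
    if arm is None:
        return Rejection(read_id, "no_trf_arm")
    (a_start, a_end), hits = arm
    arm_len = a_end - a_start + 1
    if arm_len / len(read) >= thresholds.trna_fraction_max:
        return Rejection(read_id, "trna_dominated")
    if orientation == "forward":
        t_interval = (a_end + 1, len(read))
    else:
        t_interval = (1, a_start - 1)
    target_seq = read[t_interval[0] - 1 : t_interval[1]]
    if len(target_seq) < thresholds.min_target_arm:
        return Rejection(read_id, "target_too_short")
    annotation = annotate_target(target_seq, transcript_index)
    if annotation is None:
        return Rejection(read_id, "target_unannotated")
    tx_id, category, region, tx_start = annotation
    trf, ambiguity = _trf_from_hits(gene_index, hits, arm_len)
    return ChimeraDecomposition(
        read_id=read_id,
        orientation=orientation,
        trf=trf,
        trf_read_interval=(a_start, a_end),
        target_sequence=target_seq,
        target_read_interval=t_interval,
        target_annotation=(tx_id, category, region),
        target_position=tx_start,
        ambiguity=ambiguity,
    )


def detect_trf_trf(
    read_sequence: str,
    gene_index: GeneIndex,
    thresholds: Thresholds = Thresholds(),
) -> str:
    """Classify a read carrying tRNA matches on both ends.

    ``different_gene_pair`` — 5'- and 3'-anchored arms jointly cover the read
    and can only come from two distinct genes; ``same_gene_disjoint`` — some
    gene hosts both arms at non-overlapping gene intervals; ``not_trf_trf``
    otherwise.  Same-gene disjoint placement takes precedence when both
    readings exist.
    """
    read = normalize_sequence(read_sequence)
    k5, hits5 = gene_index.longest_anchored_match(
        read, "forward", thresholds.min_trf_arm
    )
    k3, hits3 = gene_index.longest_anchored_match(
        read, "reverse", thresholds.min_trf_arm
    )
    if k5 == 0 or k3 == 0 or k5 + k3 < len(read):
        return "not_trf_trf"
    if k5 >= len(read) or k3 >= len(read):
        # whole read inside one gene: not a chimera of two fragments
        return "not_trf_trf"
    for g5, _, s5 in hits5:
        for g3, _, s3 in hits3:
            if g5 == g3:
                iv5 = (s5, s5 + k5 - 1)
                iv3 = (s3, s3 + k3 - 1)
                if iv5[1] < iv3[0] or iv3[1] < iv5[0]:
                    return "same_gene_disjoint"
    genes5 = {g for g, _, _ in hits5}
    genes3 = {g for g, _, _ in hits3}
    if genes5 != genes3 or len(genes5) > 1 or len(genes3) > 1:
        return "different_gene_pair"
    return "not_trf_trf"


def tally_pairs(
    decompositions: Iterable[ChimeraDecomposition],
) -> tuple[list[PairRecord], pd.DataFrame]:
    """Collapse decompositions into pair records and a summary table.

    The summary mirrors the layout of a per-orientation count table: one row
    per (orientation, tRF type, target category) with the total supporting
    reads and, in a separate column, the subtotal from pairs supported by at
    least two reads.
    """
    pairs: dict[tuple, PairRecord] = {}
    for d in decompositions:
        tx_id, category, _region = d.target_annotation
        t_iv = (d.target_position, d.target_position + len(d.target_sequence) - 1)
        key = (d.trf.name, tx_id, t_iv, d.orientation)
        if key in pairs:
            pairs[key].read_support += 1
        else:
            pairs[key] = PairRecord(
                trf_name=d.trf.name,
                transcript_id=tx_id,
                target_interval=t_iv,
                orientation=d.orientation,
                read_support=1,
                trf_type=d.trf.type,
                target_category=category,
                target_sequence=d.target_sequence,
            )
    records = sorted(
        pairs.values(),
        key=lambda p: (p.orientation, p.trf_name, p.transcript_id, p.target_interval),
    )
    cells: dict[tuple[str, str, str], list[int]] = {}
    for p in records:
        cell = cells.setdefault((p.orientation, p.trf_type, p.target_category), [0, 0])
        cell[0] += p.read_support
        if p.two_read_supported:
            cell[1] += p.read_support
    summary = pd.DataFrame(
        [
            (o, t, c, tot, two)
            for (o, t, c), (tot, two) in sorted(cells.items())
        ],
        columns=["orientation", "trf_type", "target_category", "reads", "reads_ge2"],
    )
    return records, summary


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ (qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq)


def parse_reads(
    reads: Iterable[tuple[str, str]],
    gene_index: GeneIndex,
    transcript_index: TranscriptIndex,
    orientation: str,
    thresholds: Thresholds = Thresholds(),
) -> tuple[list[ChimeraDecomposition], dict[str, int]]:
    """Run the full per-read decomposition over a read stream.

    tRF-tRF chimeras are classified first and removed from the tRF-target
    stream; the returned counter reports every rejection reason plus the
    tRF-tRF classes and the number of accepted reads.
    """
    accepted: list[ChimeraDecomposition] = []
    counts: dict[str, int] = {}

    def bump(reason: str) -> None:
        counts[reason] = counts.get(reason, 0) + 1

    for read_id, seq in reads:
        tt = detect_trf_trf(seq, gene_index, thresholds)
        if tt != "not_trf_trf":
            bump(f"trf_trf:{tt}")
            continue
        result = split_read(
            read_id, seq, gene_index, transcript_index, orientation, thresholds
        )
        if isinstance(result, Rejection):
            bump(result.reason)
        else:
            accepted.append(result)
            bump("accepted")
    return accepted, counts
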