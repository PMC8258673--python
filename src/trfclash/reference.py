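"""Domain types and readers/writers shared by every pipeline stage.

The pipeline consumes a self-contained reference workspace: a tRNA gene-model
file (FASTA plus a per-gene annotation TSV giving the anticodon-loop interval,
introns, 3' trailer and nuclear/mitochondrial origin) and a transcript
reference (FASTA plus a region-annotation TSV).  All coordinates are 1-based
closed intervals on the gene body (introns included); tRF fragments may extend
past the gene body into either the post-transcriptionally appended CCA or the
genomic 3' trailer, never both at once.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Thresholds",
    "TRNAGeneModel",
    "TranscriptModel",
    "normalize_sequence",
    "load_gene_models",
    "write_gene_models",
    "load_transcripts",
    "write_transcripts",
]

_ORIGINS = ("N", "M", "NM")
_CATEGORIES = ("mRNA", "rRNA", "miRNA", "other_ncRNA", "tRNA")
_REGION_LABELS = ("5UTR", "CDS", "3UTR", "intron")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to DNA T; reject anything outside ACGTN."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class Thresholds:
    """All tunable cutoffs of the pipeline, in one place.

    Defaults are the constants the analysis is defined by: the >=80% tRNA
    content exclusion for chimeric reads, the >=5 nt polyT artifact run, the
    motif E-value < 0.01 and match-back p-value < 0.001 significance levels,
    the 0.5 reactivity boundary between single- and double-stranded calls,
    the random 12-mer null width, and the 16 nt minimum PAR-CLIP read length.
    """

    trna_fraction_max: float = 0.80
    min_trf_arm: int = 16
    min_target_arm: int = 10
    polyt_min_run: int = 5
    polyt_tail_window: int = 10
    motif_evalue_max: float = 0.01
    matchback_pvalue_max: float = 0.001
    reactivity_ss_cutoff: float = 0.5
    random_kmer_width: int = 12
    min_parclip_read: int = 16
    min_motif_targets: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.trna_fraction_max < 1.0):
            raise ValueError("trna_fraction_max must lie in (0, 1)")
        for name in (
            "min_trf_arm",
            "min_target_arm",
            "polyt_min_run",
            "polyt_tail_window",
            "motif_evalue_max",
            "matchback_pvalue_max",
            "reactivity_ss_cutoff",
            "random_kmer_width",
            "min_parclip_read",
            "min_motif_targets",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


@dataclass
class TRNAGeneModel:
    """A tRNA gene: body sequence (introns included) plus 3' extensions.

    ``anticodon_loop`` and ``introns`` are 1-based closed intervals on the
    gene body.  The extended coordinate space appends either CCA (positions
    L+1..L+3 of the mature, CCA-added product) or the genomic trailer
    (positions L+1..L+len(trailer)); the two extensions are alternatives,
    matching the convention that CCA is assumed added to tRF-3p while the
    trailer is added to tRF-3t.
    """

    gene_id: str
    origin: str
    sequence: str
    anticodon_loop: tuple[int, int]
    introns: list[tuple[int, int]] = field(default_factory=list)
    trailer: str = ""
    cca_added: bool = True

    def __post_init__(self) -> None:
        if self.origin not in _ORIGINS:
            raise ValueError(f"{self.gene_id}: origin must be one of {_ORIGINS}")
        self.sequence = normalize_sequence(self.sequence)
        self.trailer = normalize_sequence(self.trailer) if self.trailer else ""
        ls, le = self.anticodon_loop
        L = len(self.sequence)
        if not (1 <= ls <= le <= L):
            raise ValueError(
                f"{self.gene_id}: anticodon loop [{ls},{le}] out of bounds for length {L}"
            )
        prev_end = 0
        for s, e in self.introns:
            if not (1 <= s <= e <= L):
                raise ValueError(f"{self.gene_id}: intron [{s},{e}] out of bounds")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: introns must be sorted and disjoint")
            prev_end = e

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def body_cca(self) -> str:
        """Mature-like sequence with the appended CCA."""
        return self.sequence + "CCA"

    @property
    def body_trailer(self) -> str:
        """Gene body read through into the genomic 3' trailer."""
        return self.sequence + self.trailer

    def extended_coordinates(self, product_kind: str) -> tuple[int, int]:
        """1-based coordinate range for one of the three product spaces.

        ``body`` -> [1, L]; ``body+CCA`` -> [1, L+3]; ``body+trailer`` ->
        [1, L+len(trailer)] (error when the trailer is empty).
        """
        L = self.length
        if product_kind == "body":
            return (1, L)
        if product_kind == "body+CCA":
            return (1, L + 3)
        if product_kind == "body+trailer":
            if not self.trailer:
                raise ValueError(f"{self.gene_id}: no trailer annotated")
            return (1, L + len(self.trailer))
        raise ValueError(f"unknown product kind {product_kind!r}")

    def extended_sequence(self, product_kind: str) -> str:
        if product_kind == "body":
            return self.sequence
        if product_kind == "body+CCA":
            return self.body_cca
        if product_kind == "body+trailer":
            if not self.trailer:
                raise ValueError(f"{self.gene_id}: no trailer annotated")
            return self.body_trailer
        raise ValueError(f"unknown product kind {product_kind!r}")


@dataclass
class TranscriptModel:
    """A reference transcript with an optional mRNA region map.

    ``regions`` is a list of (label, (start, end)) with label one of 5UTR /
    CDS / 3UTR / intron; non-mRNA categories carry no regions.
    """

    transcript_id: str
    category: str
    sequence: str
    regions: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(
                f"{self.transcript_id}: category must be one of {_CATEGORIES}"
            )
        self.sequence = normalize_sequence(self.sequence)
        if self.category != "mRNA" and self.regions:
            raise ValueError(
                f"{self.transcript_id}: only mRNA transcripts carry region maps"
            )
        L = len(self.sequence)
        for label, (s, e) in self.regions:
            if label not in _REGION_LABELS:
                raise ValueError(f"{self.transcript_id}: unknown region label {label}")
            if not (1 <= s <= e <= L):
                raise ValueError(
                    f"{self.transcript_id}: region {label} [{s},{e}] out of bounds"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def region_overlaps(self, start: int, end: int) -> dict[str, int]:
        """nt of overlap between [start, end] and each annotated region."""
        out: dict[str, int] = {}
        for label, (s, e) in self.regions:
            ov = min(end, e) - max(start, s) + 1
            if ov > 0:
                out[label] = out.get(label, 0) + ov
        return out


# ---------------------------------------------------------------------------
# serialization

_GENE_COLUMNS = [
    "gene_id",
    "origin",
    "loop_start",
    "loop_end",
    "introns",
    "trailer",
    "cca_added",
]
_TX_COLUMNS = ["transcript_id", "category", "regions"]


def _format_intervals(intervals: Iterable[tuple[int, int]]) -> str:
    parts = [f"{s}-{e}" for s, e in intervals]
    return ",".join(parts) if parts else "."


def _parse_intervals(text: str, context: str) -> list[tuple[int, int]]:
    text = text.strip()
    if text in (".", ""):
        return []
    out = []
    for part in text.split(","):
        try:
            s, e = part.split("-")
            out.append((int(s), int(e)))
        except ValueError as exc:
            raise ValueError(f"{context}: malformed interval {part!r}") from exc
    return out


def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _write_fasta(path: str | Path, items: Iterable[tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


def load_gene_models(annotation_table: str | Path, fasta: str | Path) -> list[TRNAGeneModel]:
    """Read tRNA gene models from an annotation TSV plus a FASTA.

    The TSV has a header line and one row per gene: gene_id, origin (N/M/NM),
    loop_start, loop_end, introns ("." or comma list of s-e), trailer ("." or
    sequence), cca_added (0/1).  Every annotated gene must have a FASTA
    sequence; duplicate gene ids are rejected.
    """
    seqs = _read_fasta(fasta)
    models: list[TRNAGeneModel] = []
    seen: set[str] = set()
    with open(annotation_table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLUMNS:
            raise ValueError(f"unexpected gene annotation columns: {header}")
        for line in fh:
            if not line.strip():
                continue
            gid, origin, ls, le, introns, trailer, cca = line.rstrip("\n").split("\t")
            if gid in seen:
                raise ValueError(f"duplicate gene_id {gid}")
            seen.add(gid)
            if gid not in seqs:
                raise ValueError(f"{gid}: annotated but missing from FASTA")
            models.append(
                TRNAGeneModel(
                    gene_id=gid,
                    origin=origin,
                    sequence=seqs[gid],
                    anticodon_loop=(int(ls), int(le)),
                    introns=_parse_intervals(introns, gid),
                    trailer="" if trailer == "." else trailer,
                    cca_added=bool(int(cca)),
                )
            )
    return models


def write_gene_models(
    models: Iterable[TRNAGeneModel], annotation_table: str | Path, fasta: str | Path
) -> None:
    models = list(models)
    with open(annotation_table, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.gene_id,
                        m.origin,
                        str(m.anticodon_loop[0]),
                        str(m.anticodon_loop[1]),
                        _format_intervals(m.introns),
                        m.trailer or ".",
                        str(int(m.cca_added)),
                    ]
                )
                + "\n"
            )
    _write_fasta(fasta, [(m.gene_id, m.sequence) for m in models])


def load_transcripts(annotation_table: str | Path, fasta: str | Path) -> list[TranscriptModel]:
    """Read transcript models: TSV (transcript_id, category, regions) + FASTA.

    Regions are "." for non-mRNA or a comma list of label:start-end entries.
    """
    seqs = _read_fasta(fasta)
    out: list[TranscriptModel] = []
    seen: set[str] = set()
    with open(annotation_table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TX_COLUMNS:
            raise ValueError(f"unexpected transcript annotation columns: {header}")
        for line in fh:
            if not line.strip():
                continue
            tid, category, regions_txt = line.rstrip("\n").split("\t")
            if tid in seen:
                raise ValueError(f"duplicate transcript_id {tid}")
            seen.add(tid)
            if tid not in seqs:
                raise ValueError(f"{tid}: annotated but missing from FASTA")
            regions: list[tuple[str, tuple[int, int]]] = []
            if regions_txt.strip() not in (".", ""):
                for part in regions_txt.split(","):
                    label, iv = part.split(":")
                    (interval,) = _parse_intervals(iv, tid)
                    regions.append((label, interval))
            out.append(
                TranscriptModel(
                    transcript_id=tid,
                    category=category,
                    sequence=seqs[tid],
                    regions=regions,
                )
            )
    return out


def write_transcripts(
    transcripts: Iterable[TranscriptModel], annotation_table: str | Path, fasta: str | Path
) -> None:
    transcripts = list(transcripts)
    with open(annotation_table, "w") as fh:
        fh.write("\t".join(_TX_COLUMNS) + "\n")
        for t in transcripts:
            if t.regions:
                regions = ",".join(f"{lab}:{s}-{e}" for lab, (s, e) in t.regions)
            else:
                regions = "."
            fh.write("\t".join([t.transcript_id, t.category, regions]) + "\n")
    _write_fasta(fasta, [(t.transcript_id, t.sequence) for t in transcripts])
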