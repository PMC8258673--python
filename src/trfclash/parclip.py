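"""PAR-CLIP alignment to tRNAs and T->C conversion-site profiling.

Crosslinked 4-thiouridines read out as T->C conversions, so reads are
aligned end-to-end to the tRNA reference allowing either a perfect match or
exactly one mismatch whose reference base is T and read base is C; perfect
placements always take precedence, reads under 16 nt are excluded, and
every other mismatch pattern is rejected.  Conversion events are normalized
to reads per million within each sample and combined across samples into
per-position frequency profiles whose maxima are the inferred Argonaute
crosslinking sites.  The cumulative-bitscore analysis places each tRF's
motif information content at offsets relative to its top conversion site
and tests the upstream/downstream mass asymmetry with an exact binomial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chimera import GeneIndex
from .motifs import PWMMotif
from .reference import Thresholds, TRNAGeneModel
from .stats import binomial_two_sided

__all__ = [
    "ParclipAlignment",
    "ConversionProfile",
    "BitscoreHistogram",
    "align_parclip_read",
    "conversion_profile",
    "map_cross_species",
    "bitscore_histogram",
    "side_bias_test",
]

_SPACE_ORDER = {"body": 0, "body+CCA": 1, "body+trailer": 2}


@dataclass(frozen=True)
class ParclipAlignment:
    gene_id: str
    space: str
    start: int  # 1-based start of the read on the extended gene sequence
    read_length: int
    mismatches: int  # 0 or 1
    conversion_position: int | None  # gene-space coordinate of the T->C, if any


def _scan_gene(read_arr: np.ndarray, gene_arr: np.ndarray) -> tuple[int, int] | None:
    """Best end-to-end placement: (0-based offset, mismatch count) or None.

    Only placements with <= 1 mismatch are considered; fewer mismatches win,
    ties go to the 5'-most offset.
    """
    r = len(read_arr)
    if r > len(gene_arr):
        return None
    windows = np.lib.stride_tricks.sliding_window_view(gene_arr, r)
    mism = (windows != read_arr[None, :]).sum(axis=1)
    best = int(mism.min())
    if best > 1:
        return None
    return int(np.argmax(mism == best)), best


def align_parclip_read(
    read: str,
    gene_index: GeneIndex,
    thresholds: Thresholds = Thresholds(),
) -> ParclipAlignment | None:
    """End-to-end alignment with at most one T->C conversion.

    Perfect matches take precedence over one-mismatch placements anywhere in
    the index; a single mismatch is accepted only where the reference base
    is T and the read base is C.  Ambiguous hits resolve to the
    lexicographically smallest gene (then body < CCA < trailer space, then
    the 5'-most offset).  Reads shorter than ``min_parclip_read`` return
    None.
    """
    if len(read) < thresholds.min_parclip_read:
        return None
    read = read.upper().replace("U", "T")
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    candidates: list[tuple[int, str, int, int, str, int | None]] = []
    for gene_id, space, seq in gene_index._spaces:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        hit = _scan_gene(read_arr, arr)
        if hit is None:
            continue
        offset, mm = hit
        conv = None
        if mm == 1:
            pos = int(np.argmax(arr[offset : offset + len(read)] != read_arr))
            ref_b, read_b = chr(arr[offset + pos]), read[pos]
            if not (ref_b == "T" and read_b == "C"):
                continue  # only T->C single mismatches are admissible
            conv = offset + pos + 1
        candidates.append((mm, gene_id, _SPACE_ORDER[space], offset, space, conv))
    if not candidates:
        return None
    mm, gene_id, _sp, offset, space, conv = min(candidates)
    return ParclipAlignment(
        gene_id=gene_id,
        space=space,
        start=offset + 1,
        read_length=len(read),
        mismatches=mm,
        conversion_position=conv,
    )


@dataclass
class ConversionProfile:
    gene_id: str
    rpm: np.ndarray  # per-position T->C frequency, reads-per-million units
    depth: np.ndarray  # raw read coverage per position
    top_site: int | None  # 1-based position of maximal frequency
    top_site_tied: bool = False

    @property
    def total_rpm(self) -> float:
        return float(self.rpm.sum())


def conversion_profile(
    per_sample_alignments: Sequence[Sequence[ParclipAlignment]],
    sample_totals: Sequence[int],
    gene_id: str,
    length: int,
) -> ConversionProfile:
    """Combine per-sample conversion events into one RPM-normalized profile.

    Each conversion event contributes 1e6 / (its sample's total aligned
    reads); samples are then summed.  The top site is the position of
    maximal frequency, ties resolved to the 5'-most position and flagged.
    """
    if len(per_sample_alignments) != len(sample_totals):
        raise ValueError("one total per sample required")
    rpm = np.zeros(length)
    depth = np.zeros(length, dtype=int)
    for alignments, total in zip(per_sample_alignments, sample_totals):
        if total <= 0:
            raise ValueError("sample total must be positive")
        scale = 1e6 / total
        for a in alignments:
            if a.gene_id != gene_id:
                continue
            end = min(length, a.start - 1 + a.read_length)
            depth[a.start - 1 : end] += 1
            if a.conversion_position is not None and 1 <= a.conversion_position <= length:
                rpm[a.conversion_position - 1] += scale
    if rpm.max() > 0:
        top = int(np.argmax(rpm)) + 1
        tied = int((rpm == rpm.max()).sum()) > 1
    else:
        top, tied = None, False
    return ConversionProfile(
        gene_id=gene_id, rpm=rpm, depth=depth, top_site=top, top_site_tied=tied
    )


def map_cross_species(
    other_species_trfs: Iterable[tuple[str, str, Sequence[int]]],
    reference_genes: Iterable[TRNAGeneModel],
    include_extensions: bool = True,
) -> tuple[list[tuple[str, str, list[int]]], int]:
    """Translate conversion sites from another species' tRFs onto this one.

    Input records are (trf_id, sequence, tRF-relative conversion positions).
    A tRF maps only when its full sequence matches a reference gene exactly
    (body, CCA- or trailer-extended); position p then maps to gene position
    offset + p.  Returns (mapped records as (trf_id, gene_id, gene
    positions), number of dropped tRFs).
    """
    genes = sorted(reference_genes, key=lambda g: g.gene_id)
    spaces: list[tuple[str, str]] = []
    for g in genes:
        spaces.append((g.gene_id, g.sequence))
        if include_extensions:
            if g.cca_added:
                spaces.append((g.gene_id, g.body_cca))
            if g.trailer:
                spaces.append((g.gene_id, g.body_trailer))
    mapped: list[tuple[str, str, list[int]]] = []
    dropped = 0
    for trf_id, seq, sites in other_species_trfs:
        seq = seq.upper().replace("U", "T")
        hit = None
        for gene_id, gseq in spaces:
            pos = gseq.find(seq)
            if pos >= 0:
                hit = (gene_id, pos)
                break
        if hit is None:
            dropped += 1
            continue
        gene_id, offset = hit
        mapped.append((trf_id, gene_id, [offset + p for p in sites]))
    return mapped, dropped


@dataclass
class BitscoreHistogram:
    offsets: np.ndarray  # relative to the conversion site (negative = 5')
    cumulative: np.ndarray  # summed per-column bitscores at each offset
    n_contributing: np.ndarray  # tRFs contributing at each offset
    n_skipped: int = 0

    def mass(self, side: str) -> float:
        if side == "upstream":
            return float(self.cumulative[self.offsets < 0].sum())
        if side == "downstream":
            return float(self.cumulative[self.offsets > 0].sum())
        raise ValueError(side)


def bitscore_histogram(
    motifs: Iterable[PWMMotif],
    top_sites: Mapping[str, int | None],
    orientation: str | None = None,
) -> BitscoreHistogram:
    """Cumulative motif information content around the crosslinking site.

    Every motif column's bitscore (2 + sum f log2 f) is placed at the offset
    of its tRF position from that tRF's top conversion site (offset 0 = the
    site itself, negative = 5' of it) and summed across tRFs.  Motifs
    without a match-back interval or whose tRF lacks a top site are skipped
    and counted.
    """
    acc: dict[int, float] = {}
    ncontrib: dict[int, int] = {}
    skipped = 0
    for m in motifs:
        if orientation is not None and m.orientation != orientation:
            continue
        site = top_sites.get(m.trf_name)
        if site is None or m.trf_interval is None:
            skipped += 1
            continue
        ic = m.information_content
        a, _b = m.trf_interval
        seen_offsets = set()
        for t in range(m.width):
            off = (a + t) - site
            acc[off] = acc.get(off, 0.0) + float(ic[t])
            seen_offsets.add(off)
        for off in seen_offsets:
            ncontrib[off] = ncontrib.get(off, 0) + 1
    if not acc:
        return BitscoreHistogram(
            offsets=np.array([], dtype=int),
            cumulative=np.array([]),
            n_contributing=np.array([], dtype=int),
            n_skipped=skipped,
        )
    offs = np.array(sorted(acc), dtype=int)
    return BitscoreHistogram(
        offsets=offs,
        cumulative=np.array([acc[o] for o in offs]),
        n_contributing=np.array([ncontrib[o] for o in offs], dtype=int),
        n_skipped=skipped,
    )


def side_bias_test(
    motifs: Iterable[PWMMotif],
    top_sites: Mapping[str, int | None],
) -> tuple[int, int, float]:
    """Binomial test of per-tRF motif mass upstream vs downstream of the site.

    For each motif-bearing tRF with a known top conversion site, the motif's
    total bitscore strictly 5' of the site is compared with the mass
    strictly 3' of it; the majority side is the tRF's vote, exact ties are
    excluded, and the vote split is tested against 0.5 with an exact
    two-sided binomial test.
    """
    n_up = n_down = 0
    for m in motifs:
        site = top_sites.get(m.trf_name)
        if site is None or m.trf_interval is None:
            continue
        ic = m.information_content
        a, _b = m.trf_interval
        up = down = 0.0
        for t in range(m.width):
            off = (a + t) - site
            if off < 0:
                up += float(ic[t])
            elif off > 0:
                down += float(ic[t])
        if up > down:
            n_up += 1
        elif down > up:
            n_down += 1
    n = n_up + n_down
    if n == 0:
        raise ValueError("no tRFs with an untied motif-mass side")
    return n_up, n_down, binomial_two_sided(n_up, n)
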