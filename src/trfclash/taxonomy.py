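"""Classification of tRF gene intervals into the six canonical types.

A fragment interval [start, end] on a tRNA gene (1-based, inclusive; introns
included in the coordinates) is typed relative to the gene ends and the
anticodon loop [ls, le], with L the gene-body length:

* ``3t`` — ends at least 3 nt downstream of the gene (into the genomic
  trailer), or starts after the gene end (the fragments traditionally
  called tRF-1 are folded into this type);
* ``5p`` — starts in the first 5 nt and ends before the anticodon loop;
* ``5i`` — starts in the first 5 nt and ends inside the anticodon loop
  (the ~33-36 nt "tRNA halves" / 5' tiRNAs);
* ``3p`` — ends in the last 5 nt of the CCA-extended gene and starts after
  the loop;
* ``3i`` — ends in the last 5 nt of the CCA-extended gene and starts inside
  the loop;
* ``i``  — anything internal that fits none of the anchored rules.

Rules are applied in the precedence 3t, 5p/5i, 3p/3i, i so the classifier is
total and deterministic even for intervals that would satisfy several rules.
Canonical names follow ``host_gene-ORIGIN-type-start-end``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .reference import TRNAGeneModel

__all__ = [
    "TRFRecord",
    "classify_trf",
    "make_trf_record",
    "trf_name",
    "parse_trf_name",
    "length_distribution",
    "compare_orientations",
    "isodecoder_family",
]

TRF_TYPES = ("5p", "5i", "3p", "3i", "3t", "i")


@dataclass(frozen=True)
class TRFRecord:
    """A classified tRNA fragment with canonical name."""

    gene_id: str
    origin: str
    type: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match interval "
                f"[{self.start},{self.end}]"
            )

    @property
    def name(self) -> str:
        return trf_name(self)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def classify_trf(
    start: int,
    end: int,
    model: TRNAGeneModel,
    space: str | None = None,
) -> str:
    """Assign one of the six tRF types to the interval [start, end].

    ``space`` names the coordinate space the interval lives in (``body``,
    ``body+CCA`` or ``body+trailer``); when omitted it is inferred: intervals
    within the gene body need no extension, intervals past the body default
    to the CCA space when the gene is CCA-added, else to the trailer space.
    """
    L = model.length
    ls, le = model.anticodon_loop
    if space is None:
        if end <= L:
            space = "body"
        elif model.cca_added:
            space = "body+CCA"
        else:
            space = "body+trailer"
    lo, hi = model.extended_coordinates(space)
    if not (lo <= start <= end <= hi):
        raise ValueError(
            f"interval [{start},{end}] outside {space} space [{lo},{hi}] "
            f"of {model.gene_id}"
        )
    # trailer-derived fragments, including tRF-1 (start past the gene end)
    if space == "body+trailer" and end >= L + 3:
        return "3t"
    if start > L:
        return "3t"
    if start <= 5 and end < ls:
        return "5p"
    if start <= 5 and ls <= end <= le:
        return "5i"
    # "last 5 nt with CCA": end within the final 5 positions of the
    # CCA-extended sequence, i.e. end >= (L+3)-4 = L-1
    if end >= L - 1 and start > le:
        return "3p"
    if end >= L - 1 and ls <= start <= le:
        return "3i"
    return "i"


def make_trf_record(
    model: TRNAGeneModel, start: int, end: int, space: str | None = None
) -> TRFRecord:
    """Build a classified record, pulling the sequence from the right space."""
    trf_type = classify_trf(start, end, model, space=space)
    if space is None:
        if end <= model.length:
            space = "body"
        elif model.cca_added and trf_type != "3t":
            space = "body+CCA"
        else:
            space = "body+trailer"
    seq = model.extended_sequence(space)[start - 1 : end]
    return TRFRecord(
        gene_id=model.gene_id,
        origin=model.origin,
        type=trf_type,
        start=start,
        end=end,
        sequence=seq,
    )


def trf_name(record: TRFRecord) -> str:
    """Canonical name ``host_gene-ORIGIN-type-start-end``."""
    return f"{record.gene_id}-{record.origin}-{record.type}-{record.start}-{record.end}"


_NAME_RE = re.compile(
    r"^(?P<gene>.+)-(?P<origin>NM|N|M)-(?P<type>5p|5i|3p|3i|3t|i)-(?P<start>\d+)-(?P<end>\d+)$"
)


def parse_trf_name(name: str) -> dict:
    """Invert :func:`trf_name`; returns gene_id/origin/type/start/end."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"not a canonical tRF name: {name!r}")
    return {
        "gene_id": m.group("gene"),
        "origin": m.group("origin"),
        "type": m.group("type"),
        "start": int(m.group("start")),
        "end": int(m.group("end")),
    }


def isodecoder_family(gene_id: str) -> str:
    """Parent isodecoder family, e.g. ``CysGCA-002`` -> ``CysGCA``."""
    return re.sub(r"-\d+$", "", gene_id)


def length_distribution(
    records: Iterable[TRFRecord], orientation: str | None = None
) -> pd.DataFrame:
    """Long-format histogram of fragment lengths per tRF type."""
    rows: dict[tuple[str, int], int] = {}
    for r in records:
        key = (r.type, r.length)
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [(t, l, c) for (t, l), c in sorted(rows.items())],
        columns=["type", "length", "count"],
    )
    df["orientation"] = orientation if orientation is not None else "all"
    return df


def compare_orientations(
    forward_counts: Mapping[str, int],
    reverse_counts: Mapping[str, int],
    level: str = "isoform",
) -> tuple[pd.DataFrame, float]:
    """Compare tRF abundance between chimera orientations.

    Counts are keyed by canonical tRF name; at ``level="isodecoder"`` they
    are pooled over the parent isodecoder family first.  Relative
    frequencies are computed within each orientation, the Pearson R between
    the two frequency vectors is reported, and per-item fold changes
    (forward/reverse) replace a zero count by 0.5 so orientation-exclusive
    items stay finite.
    """
    if not forward_counts and not reverse_counts:
        raise ValueError("both orientations are empty")
    if level not in ("isoform", "isodecoder"):
        raise ValueError(f"unknown level {level!r}")

    def pool(counts: Mapping[str, int]) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, c in counts.items():
            key = name
            if level == "isodecoder":
                key = isodecoder_family(parse_trf_name(name)["gene_id"])
            out[key] = out.get(key, 0) + c
        return out

    fwd = pool(forward_counts)
    rev = pool(reverse_counts)
    keys = sorted(set(fwd) | set(rev))
    fc = np.array([fwd.get(k, 0) for k in keys], dtype=float)
    rc = np.array([rev.get(k, 0) for k in keys], dtype=float)
    tot_f, tot_r = fc.sum(), rc.sum()
    if tot_f == 0 or tot_r == 0:
        raise ValueError("one orientation has no counts")
    freq_f = fc / tot_f
    freq_r = rc / tot_r
    # zero counts take a +0.5 pseudocount so exclusive items stay finite
    f_adj = np.where(fc == 0, 0.5, fc) / tot_f
    r_adj = np.where(rc == 0, 0.5, rc) / tot_r
    fold = f_adj / r_adj
    if len(keys) < 2 or np.ptp(freq_f) == 0 or np.ptp(freq_r) == 0:
        r_val = 1.0 if np.allclose(freq_f, freq_r) else float("nan")
    else:
        r_val = float(stats.pearsonr(freq_f, freq_r)[0])
    table = pd.DataFrame(
        {
            "item": keys,
            "count_fwd": fc.astype(int),
            "count_rev": rc.astype(int),
            "freq_fwd": freq_f,
            "freq_rev": freq_r,
            "fold_change": fold,
        }
    )
    return table, r_val
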