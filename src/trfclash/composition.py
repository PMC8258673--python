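"""Dinucleotide-composition PCA and polyT artifact detection.

Target arms of forward chimeras are enriched for runs of consecutive Ts — a
library-preparation artifact that separates from genuine targets in the
space of overlapping-dinucleotide frequencies and that masks motif discovery
when left in.  This module computes the 16-dimensional dinucleotide vectors,
projects them with a deterministic PCA, and flags/partitions sequences by
their longest T run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .chimera import PairRecord
from .reference import Thresholds

__all__ = [
    "DINUCLEOTIDES",
    "PolyTReport",
    "PCAResult",
    "dinucleotide_vector",
    "dinucleotide_table",
    "pca_project",
    "polyt_report",
    "partition_by_polyt",
]

_BASES = "ACGT"
DINUCLEOTIDES = [a + b for a in _BASES for b in _BASES]
_DINUC_IDX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


def dinucleotide_vector(sequence: str) -> np.ndarray:
    """Frequencies of all overlapping dinucleotides, indexed AA..TT.

    The denominator is length-1 (every overlapping window); windows touching
    an ambiguity character (N) are not counted.  Sequences shorter than 2 nt
    yield the all-zero vector.
    """
    seq = sequence.upper().replace("U", "T")
    v = np.zeros(16)
    if len(seq) < 2:
        return v
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        if d in _DINUC_IDX:
            v[_DINUC_IDX[d]] += 1
    denom = len(seq) - 1
    return v / denom


def dinucleotide_table(items: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Vectors for (id, sequence) pairs as a DataFrame indexed by id."""
    ids, rows = [], []
    for sid, seq in items:
        ids.append(sid)
        rows.append(dinucleotide_vector(seq))
    return pd.DataFrame(rows, index=ids, columns=DINUCLEOTIDES)


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, k)
    explained_variance_ratio: np.ndarray  # (k,)
    components: np.ndarray  # (k, 16)
    mean: np.ndarray  # (16,)

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.components + self.mean


def pca_project(vectors: np.ndarray | pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Column-centered PCA with a deterministic sign convention.

    Components are ordered by decreasing explained variance; each component
    is flipped so its largest-magnitude loading is positive, making scores
    reproducible across runs and row orders.  Zero-variance columns simply
    receive zero loadings.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 vectors")
    k = min(n_components, X.shape[1], X.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for j in range(k):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] = -comps[j]
            scores[:, j] = -scores[:, j]
    return PCAResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        components=comps,
        mean=pca.mean_.copy(),
    )


@dataclass(frozen=True)
class PolyTReport:
    sequence_id: str
    longest_t_run: int
    has_long_run: bool  # a run of >= polyt_min_run consecutive Ts exists
    long_run_in_tail_window: bool  # such a run touches the last tail-window nt
    fraction_T: float


def polyt_report(
    sequence: str, thresholds: Thresholds = Thresholds(), sequence_id: str = ""
) -> PolyTReport:
    """Longest T-run statistics of a sequence.

    Ambiguity characters break runs and count toward length.  The tail flag
    is true iff a run of at least ``polyt_min_run`` Ts intersects the last
    ``polyt_tail_window`` nucleotides.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    longest = 0
    in_tail = False
    run_start = None
    for i in range(n + 1):
        if i < n and seq[i] == "T":
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                run_len = i - run_start
                longest = max(longest, run_len)
                if run_len >= thresholds.polyt_min_run and i - 1 >= n - thresholds.polyt_tail_window:
                    in_tail = True
                run_start = None
    frac = seq.count("T") / n if n else 0.0
    return PolyTReport(
        sequence_id=sequence_id,
        longest_t_run=longest,
        has_long_run=longest >= thresholds.polyt_min_run,
        long_run_in_tail_window=in_tail,
        fraction_T=frac,
    )


def partition_by_polyt(
    pairs: Sequence[PairRecord], thresholds: Thresholds = Thresholds()
) -> tuple[list[PairRecord], list[PairRecord], dict[str, float]]:
    """Split pairs into a clean set and a polyT-artifact set.

    A pair is flagged when its target carries a run of at least
    ``polyt_min_run`` consecutive Ts.  The contrast reports the mean
    T fraction of target sequences in each set.
    """
    clean: list[PairRecord] = []
    polyt: list[PairRecord] = []
    for p in pairs:
        rep = polyt_report(p.target_sequence, thresholds, sequence_id=p.trf_name)
        (polyt if rep.has_long_run else clean).append(p)

    def mean_frac(group: list[PairRecord]) -> float:
        if not group:
            return float("nan")
        return float(
            np.mean([polyt_report(p.target_sequence, thresholds).fraction_T for p in group])
        )

    contrast = {
        "fraction_T_polyt": mean_frac(polyt),
        "fraction_T_clean": mean_frac(clean),
        "n_polyt": float(len(polyt)),
        "n_clean": float(len(clean)),
    }
    return clean, polyt, contrast
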