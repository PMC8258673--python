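"""Target-motif discovery per tRF, match-back, comparison and ranking.

For every tRF, the unique target arms of its chimeras (polyT artifacts
removed, read support kept as weights) are searched for a shared sequence
motif with a self-contained ZOOPS (zero-or-one occurrence per sequence)
expectation-maximization finder over a range of widths.  Significance is
empirical: the same finder is run on dinucleotide-shuffled decoy target
sets and the observed score is referred to a Gumbel extreme-value tail
fitted to the decoy best scores, Bonferroni-scaled by the number of widths
tested.  A discovered motif is matched back onto the tRF by scanning the
tRF's reverse complement with the motif log-odds and computing the exact
p-value of the best hit from the full PWM score distribution (value-indexed
convolution of per-column score distributions — no discretization).

Forward- and reverse-orientation motifs of the same tRF are compared on the
tRF coordinate system (identical / overlapping >= 4 nt / marginal overlap /
disjoint), orientations can be pooled for a combined search, motif cohorts
are ranked by multiple parameters with top-tercile flags, and the
upstream-downstream asymmetry of paired motif starts is assessed with an
exact two-sided binomial test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chimera import PairRecord
from .composition import polyt_report
from .reference import Thresholds
from .stats import binomial_two_sided

__all__ = [
    "PWMMotif",
    "MotifComparison",
    "RankedMotif",
    "TargetSet",
    "InsufficientTargetsError",
    "assemble_target_set",
    "discover_motif",
    "combine_orientations",
    "pwm_score_distribution",
    "pwm_match_pvalue",
    "match_to_trf",
    "compare_motifs",
    "upstream_downstream_test",
    "rank_motifs",
    "dinucleotide_shuffle",
    "reverse_complement",
    "write_motif_matrix",
    "read_motif_matrix",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_WIDTHS = tuple(range(6, 13))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX.get(c, -1) for c in seq.upper()], dtype=np.int64)


# ---------------------------------------------------------------------------
# target sets


class InsufficientTargetsError(ValueError):
    """Raised when a tRF has too few distinct targets for motif inference."""


@dataclass
class TargetSet:
    trf_name: str
    orientation: str
    sequences: list[str]
    weights: list[float]
    n_removed_polyt: int = 0

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def total_read_support(self) -> float:
        return float(sum(self.weights))


def assemble_target_set(
    trf_name: str,
    pair_records: Iterable[PairRecord],
    thresholds: Thresholds = Thresholds(),
    orientation: str | None = None,
) -> TargetSet:
    """Unique, polyT-filtered target sequences of one tRF with read weights.

    Duplicate target sequences collapse into one entry whose weight is the
    summed read support.  Raises :class:`InsufficientTargetsError` below
    ``min_motif_targets`` unique sequences.
    """
    weights: dict[str, float] = {}
    n_polyt = 0
    for p in pair_records:
        if p.trf_name != trf_name:
            continue
        if orientation is not None and p.orientation != orientation:
            continue
        if polyt_report(p.target_sequence, thresholds).has_long_run:
            n_polyt += 1
            continue
        weights[p.target_sequence] = weights.get(p.target_sequence, 0.0) + p.read_support
    seqs = sorted(weights)
    ts = TargetSet(
        trf_name=trf_name,
        orientation=orientation or "pooled",
        sequences=seqs,
        weights=[weights[s] for s in seqs],
        n_removed_polyt=n_polyt,
    )
    if len(ts) < thresholds.min_motif_targets:
        raise InsufficientTargetsError(
            f"{trf_name}: {len(ts)} unique targets < {thresholds.min_motif_targets}"
        )
    return ts


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Euler-path construction)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Builds the multigraph whose edges are the observed dinucleotide
    transitions and emits a uniform random Eulerian walk from the original
    start vertex: a random terminal edge is fixed per vertex so the terminal
    edges form a tree into the final vertex, the remaining edge lists are
    permuted, and the walk is read off.
    """
    if len(seq) < 3:
        return seq
    s = seq.upper()
    verts = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in verts}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]

    non_final = [v for v in verts if v != last and edges[v]]
    for _ in range(10_000):
        tail = {v: edges[v][rng.integers(len(edges[v]))] for v in non_final}
        # every non-final vertex must reach the final vertex via tail edges
        ok = True
        for v in non_final:
            seen = {v}
            cur = v
            while cur != last:
                cur = tail.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - graph of a real sequence is always connected
        return s

    pools: dict[str, list[str]] = {}
    for v in verts:
        pool = list(edges[v])
        if v in tail:
            pool.remove(tail[v])
        rng.shuffle(pool)
        if v in tail:
            pool.append(tail[v])
        pools[v] = pool

    out = [s[0]]
    cur = s[0]
    idx = {v: 0 for v in verts}
    for _ in range(len(s) - 1):
        nxt = pools[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# ZOOPS expectation-maximization


@dataclass
class PWMMotif:
    """A discovered position weight matrix and its tRF match-back."""

    trf_name: str
    orientation: str  # forward | reverse | combined
    width: int
    matrix: np.ndarray  # (width, 4) per-position probabilities over ACGT
    e_value: float
    n_sites: int
    score: float = 0.0  # ZOOPS log-likelihood ratio over background
    read_support: float = 0.0
    converged: bool = True
    trf_interval: tuple[int, int] | None = None
    matchback_pvalue: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.width, 4):
            raise ValueError("matrix must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("matrix rows must each sum to 1")

    @property
    def information_content(self) -> np.ndarray:
        """Per-column bitscore 2 + sum_b f_b log2 f_b (logo letter heights)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(self.matrix > 0, self.matrix * np.log2(self.matrix), 0.0)
        return 2.0 + h.sum(axis=1)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


def _background_from(seqs: Sequence[str]) -> np.ndarray:
    counts = np.ones(4)  # +1 pseudocount keeps log-odds finite
    for s in seqs:
        enc = _encode(s)
        for b in range(4):
            counts[b] += int((enc == b).sum())
    return counts / counts.sum()


def _zoops_em(
    encoded: list[np.ndarray],
    weights: np.ndarray,
    width: int,
    background: np.ndarray,
    rng: np.random.Generator,
    n_starts: int = 2,
    max_iter: int = 40,
    tol: float = 1e-5,
) -> tuple[np.ndarray, float, float, np.ndarray, bool]:
    """Best ZOOPS fit over random k-mer starts, vectorized across sequences.

    Returns (matrix, gamma, weighted log-likelihood-ratio score, per-sequence
    site posterior, converged flag).  Sequences shorter than the width carry
    no site and contribute nothing.
    """
    keep = [i for i, e in enumerate(encoded) if len(e) >= width]
    if not keep:
        raise ValueError("no sequence long enough for this width")
    n_all = len(encoded)
    n = len(keep)
    L = max(len(encoded[i]) for i in keep)
    X = np.full((n, L), -1, dtype=np.int64)
    for r, i in enumerate(keep):
        X[r, : len(encoded[i])] = encoded[i]
    w_vec = weights[keep].astype(float)
    m = L - width + 1
    Xc = np.clip(X, 0, 3)
    # valid windows: fully inside the sequence with no ambiguity codes
    ok = (X >= 0).astype(np.int64)
    csum = np.concatenate([np.zeros((n, 1), dtype=np.int64), np.cumsum(ok, axis=1)], axis=1)
    valid = (csum[:, width:] - csum[:, :-width]) == width  # (n, m)
    mvec = valid.sum(axis=1)
    if (mvec == 0).all():
        raise ValueError("no unambiguous windows available")
    live = mvec > 0
    onehot = np.zeros((n, L, 4))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], Xc] = ok

    # seeds: the most heavily covered distinct k-mers, plus one random window
    seed_rows, seed_cols = np.nonzero(valid)
    kmer_weight: dict[tuple, float] = {}
    for r, c in zip(seed_rows, seed_cols):
        key = tuple(Xc[r, c : c + width])
        kmer_weight[key] = kmer_weight.get(key, 0.0) + w_vec[r]
    top_kmers = sorted(kmer_weight.items(), key=lambda kv: (-kv[1], kv[0]))
    seeds = [np.array(k) for k, _ in top_kmers[: max(1, n_starts - 1)]]
    pick = int(rng.integers(len(seed_rows)))
    seeds.append(Xc[seed_rows[pick], seed_cols[pick] : seed_cols[pick] + width])
    log_bg = np.log(background)
    best: tuple | None = None
    for seed_kmer in seeds[:n_starts]:
        theta = np.full((width, 4), 0.1)
        theta[np.arange(width), seed_kmer] = 0.7
        gamma = 0.5
        prev_ll = -np.inf
        converged = False
        for _it in range(max_iter):
            lods = np.log(theta) - log_bg[None, :]
            S = np.zeros((n, m))
            for k in range(width):
                S += lods[k, Xc[:, k : k + m]]
            S = np.where(valid, S, -np.inf)
            with np.errstate(divide="ignore"):
                prior_site = np.where(
                    live, math.log(max(gamma, 1e-12)) - np.log(np.maximum(mvec, 1)), -np.inf
                )
            A = S + prior_site[:, None]  # (n, m) log site terms
            no_site = math.log(max(1 - gamma, 1e-12))
            mx = np.maximum(A.max(axis=1, initial=-np.inf), no_site)
            expA = np.exp(A - mx[:, None])
            exp0 = np.exp(no_site - mx)
            denom = exp0 + expA.sum(axis=1)
            Z = expA / denom[:, None]  # (n, m) site posteriors
            ll = float(np.sum(w_vec * (mx + np.log(denom))))
            post_site = Z.sum(axis=1)
            gamma = float(
                np.clip((w_vec * post_site).sum() / w_vec.sum(), 1e-3, 1 - 1e-3)
            )
            Zw = Z * w_vec[:, None]
            counts = np.empty((width, 4))
            for k in range(width):
                counts[k] = np.einsum("nm,nmb->b", Zw, onehot[:, k : k + m, :])
            theta = (counts + 0.25) / (counts.sum(axis=1, keepdims=True) + 1.0)
            if abs(ll - prev_ll) < tol * (1 + abs(ll)):
                converged = True
                break
            prev_ll = ll
        if best is None or ll > best[2]:
            full_post = np.zeros(n_all)
            full_post[keep] = post_site
            best = (theta, gamma, ll, full_post, converged)
    theta, gamma, ll, post_site, converged = best
    return theta, gamma, float(ll), post_site, converged


_EULER_GAMMA = 0.5772156649015329


def _gumbel_sf(x: float, samples: np.ndarray) -> float:
    """Upper tail of a Gumbel fitted by moments to decoy maxima."""
    mean = float(samples.mean())
    sd = float(samples.std(ddof=1)) if len(samples) > 1 else 0.0
    if sd < 1e-12:
        return 1.0 if x <= mean + 1e-12 else 1e-300
    beta = sd * math.sqrt(6.0) / math.pi
    mu = mean - _EULER_GAMMA * beta
    z = (x - mu) / beta
    # sf = 1 - exp(-exp(-z)), computed stably for large z
    t = math.exp(-z) if z < 700 else 0.0
    return float(min(1.0, max(-math.expm1(-t), 1e-300)))


def discover_motif(
    target_set: TargetSet,
    widths: Sequence[int] = DEFAULT_WIDTHS,
    seed: int | np.random.Generator = 0,
    thresholds: Thresholds = Thresholds(),
    n_decoys: int = 20,
    return_all: bool = False,
) -> PWMMotif | None:
    """Discover the best-supported motif in a target set, or None.

    For each candidate width the ZOOPS EM score on the real targets is
    referred to the Gumbel tail of the same statistic on ``n_decoys``
    dinucleotide-shuffled copies of the target set; the per-width tail
    probability is Bonferroni-scaled by the number of widths tested.  The
    motif with the smallest E-value is returned when it clears
    ``motif_evalue_max`` (with ``return_all=True`` it is returned
    regardless, for diagnostics).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs = target_set.sequences
    weights = np.asarray(target_set.weights, dtype=float)
    encoded = [_encode(s) for s in seqs]
    background = _background_from(seqs)
    n_widths = len(widths)

    best_motif: PWMMotif | None = None
    for width in widths:
        if max(len(s) for s in seqs) < width:
            continue
        try:
            theta, _gamma, score, post, converged = _zoops_em(
                encoded, weights, width, background, rng
            )
        except ValueError:
            continue
        decoy_scores = []
        for _d in range(n_decoys):
            shuffled = [dinucleotide_shuffle(s, rng) for s in seqs]
            d_enc = [_encode(s) for s in shuffled]
            try:
                _, _, d_score, _, _ = _zoops_em(
                    d_enc, weights, width, background, rng
                )
            except ValueError:
                continue
            decoy_scores.append(d_score)
        if not decoy_scores:
            continue
        e_value = min(1e6, n_widths * _gumbel_sf(score, np.array(decoy_scores)))
        motif = PWMMotif(
            trf_name=target_set.trf_name,
            orientation=target_set.orientation,
            width=width,
            matrix=theta,
            e_value=e_value,
            n_sites=int((post > 0.5).sum()),
            score=score,
            read_support=target_set.total_read_support,
            converged=converged,
        )
        if best_motif is None or motif.e_value < best_motif.e_value:
            best_motif = motif
    if best_motif is None:
        return None
    if best_motif.e_value < thresholds.motif_evalue_max or return_all:
        return best_motif
    return None


def combine_orientations(
    fwd_targets: TargetSet | None,
    rev_targets: TargetSet | None,
    thresholds: Thresholds = Thresholds(),
    seed: int | np.random.Generator = 0,
    widths: Sequence[int] = DEFAULT_WIDTHS,
) -> PWMMotif | None:
    """Pool forward and reverse target sets and rerun motif discovery."""
    if fwd_targets is None and rev_targets is None:
        raise ValueError("both orientations empty")
    weights: dict[str, float] = {}
    name = None
    for ts in (fwd_targets, rev_targets):
        if ts is None:
            continue
        name = ts.trf_name
        for s, w in zip(ts.sequences, ts.weights):
            weights[s] = weights.get(s, 0.0) + w
    if len(weights) < thresholds.min_motif_targets:
        raise InsufficientTargetsError(
            f"{name}: pooled set has {len(weights)} unique targets"
        )
    seqs = sorted(weights)
    pooled = TargetSet(
        trf_name=name,
        orientation="combined",
        sequences=seqs,
        weights=[weights[s] for s in seqs],
    )
    return discover_motif(pooled, widths=widths, seed=seed, thresholds=thresholds)


# ---------------------------------------------------------------------------
# exact PWM match p-value


def pwm_score_distribution(
    log_odds: np.ndarray,
    background: np.ndarray,
    max_values: int = 1 << 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the PWM score of a random background width-mer.

    Column score distributions are convolved on their value set: partial
    sums accumulate left to right and exactly equal values merge, so while
    the working set stays below ``max_values`` the result coincides with
    full enumeration of all 4^width words to machine precision (all widths
    <= 10 fit).  Beyond the cap, values collapse onto a fine lattice
    (range / 2^21 steps), bounding the score error by width x step / 2.
    Returns (sorted score values, tail probability P(score >= value)).
    """
    lods = np.asarray(log_odds, dtype=float)
    bg = np.asarray(background, dtype=float)
    vals = np.zeros(1)
    probs = np.ones(1)
    for k in range(lods.shape[0]):
        vals = (vals[:, None] + lods[k][None, :]).ravel()
        probs = (probs[:, None] * bg[None, :]).ravel()
        if len(vals) > max_values:
            step = np.ptp(vals) / (1 << 21)
            if step > 0:
                vals = np.round(vals / step) * step
        uniq, inv = np.unique(vals, return_inverse=True)
        probs = np.bincount(inv, weights=probs)
        vals = uniq
    tail = np.cumsum(probs[::-1])[::-1]
    return vals, tail


def _log_odds(matrix: np.ndarray, background: np.ndarray) -> np.ndarray:
    m = np.maximum(np.asarray(matrix, dtype=float), 1e-9)
    return np.log2(m) - np.log2(background)[None, :]


def pwm_match_pvalue(
    matrix: np.ndarray,
    trf_sequence: str,
    background: np.ndarray | None = None,
) -> tuple[tuple[int, int], float, float]:
    """Best complementary match of a target motif on a tRF, with exact p-value.

    The motif describes the *target* strand; the scan therefore runs the
    log-odds matrix over the reverse complement of the tRF.  Returns the
    matched interval in 1-based tRF coordinates (5'->3'), the best log-odds
    score, and the exact probability that a random background width-mer
    scores at least as high.  Ties go to the 5'-most tRF position.
    """
    matrix = np.asarray(matrix, dtype=float)
    width = matrix.shape[0]
    L = len(trf_sequence)
    if width > L:
        raise ValueError(f"motif width {width} exceeds tRF length {L}")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    lods = _log_odds(matrix, bg)
    rc = _encode(reverse_complement(trf_sequence))
    best_score = -np.inf
    best_j = 0
    for j in range(L - width + 1):
        win = rc[j : j + width]
        if (win < 0).any():
            continue
        s = 0.0
        for k in range(width):  # left-to-right, matching the distribution
            s += lods[k, win[k]]
        # prefer the 5'-most tRF position: larger j on the rc scan
        if s > best_score + 1e-12 or (abs(s - best_score) <= 1e-12 and j > best_j):
            best_score = s
            best_j = j
    if not np.isfinite(best_score):
        raise ValueError("no unambiguous window on the tRF")
    vals, tail = pwm_score_distribution(lods, bg)
    idx = np.searchsorted(vals, best_score - 1e-12, side="left")
    pvalue = float(tail[idx]) if idx < len(vals) else 0.0
    trf_start = L - (best_j + width) + 1
    return (trf_start, trf_start + width - 1), float(best_score), pvalue


def best_pwm_site(
    matrix: np.ndarray,
    sequence: str,
    background: np.ndarray | None = None,
) -> int | None:
    """0-based offset of the best-scoring motif window on a target sequence.

    Plain-strand scan (the motif describes the target itself); returns None
    when the sequence is shorter than the motif or has no unambiguous
    window.  Ties go to the 5'-most offset.
    """
    matrix = np.asarray(matrix, dtype=float)
    width = matrix.shape[0]
    if len(sequence) < width:
        return None
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    lods = _log_odds(matrix, bg)
    enc = _encode(sequence)
    best_score, best_j = -np.inf, None
    for j in range(len(enc) - width + 1):
        win = enc[j : j + width]
        if (win < 0).any():
            continue
        s = float(lods[np.arange(width), win].sum())
        if s > best_score:
            best_score, best_j = s, j
    return best_j


def match_to_trf(
    motif: PWMMotif,
    trf_sequence: str,
    thresholds: Thresholds = Thresholds(),
    background: np.ndarray | None = None,
) -> bool:
    """Fill the motif's tRF interval and match-back p-value in place.

    Returns True when the match clears ``matchback_pvalue_max``.
    """
    interval, _score, pvalue = pwm_match_pvalue(motif.matrix, trf_sequence, background)
    motif.trf_interval = interval
    motif.matchback_pvalue = pvalue
    return pvalue < thresholds.matchback_pvalue_max


# ---------------------------------------------------------------------------
# comparison, combination, ranking, asymmetry tests


@dataclass(frozen=True)
class MotifComparison:
    trf_name: str
    cls: str  # identical | overlap_ge4 | minimal_overlap | disjoint | one_missing
    overlap_nt: int
    fwd_start: int | None
    rev_start: int | None


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Mean per-column Pearson correlation of two equal-width matrices."""
    cors = []
    for ca, cb in zip(a, b):
        if np.ptp(ca) == 0 or np.ptp(cb) == 0:
            cors.append(1.0 if np.allclose(ca, cb) else 0.0)
        else:
            cors.append(float(np.corrcoef(ca, cb)[0, 1]))
    return float(np.mean(cors))


def compare_motifs(fwd: PWMMotif | None, rev: PWMMotif | None) -> MotifComparison:
    """Compare the tRF footprints of a forward and a reverse motif.

    ``identical`` requires equal intervals and mean per-column matrix
    correlation >= 0.95; overlaps of >= 4 nt are ``overlap_ge4``, shorter
    non-empty overlaps ``minimal_overlap``; non-overlapping footprints are
    ``disjoint``.
    """
    name = (fwd or rev).trf_name if (fwd or rev) else ""
    if fwd is None or rev is None or fwd.trf_interval is None or rev.trf_interval is None:
        f_start = fwd.trf_interval[0] if fwd is not None and fwd.trf_interval else None
        r_start = rev.trf_interval[0] if rev is not None and rev.trf_interval else None
        return MotifComparison(name, "one_missing", 0, f_start, r_start)
    f0, f1 = fwd.trf_interval
    r0, r1 = rev.trf_interval
    overlap = max(0, min(f1, r1) - max(f0, r0) + 1)
    if (f0, f1) == (r0, r1) and fwd.width == rev.width and _column_correlation(
        fwd.matrix, rev.matrix
    ) >= 0.95:
        cls = "identical"
    elif overlap >= 4:
        cls = "overlap_ge4"
    elif overlap >= 1:
        cls = "minimal_overlap"
    else:
        cls = "disjoint"
    return MotifComparison(name, cls, overlap, f0, r0)


def upstream_downstream_test(
    comparisons: Iterable[MotifComparison],
) -> tuple[int, int, float]:
    """Asymmetry of forward vs reverse motif start positions on the tRF.

    Counts tRFs whose forward motif starts strictly upstream (5') of the
    reverse motif and vice versa (ties and missing motifs excluded) and
    tests the split against 0.5 with an exact two-sided binomial test.
    """
    n_fwd = n_rev = 0
    for c in comparisons:
        if c.fwd_start is None or c.rev_start is None:
            continue
        if c.fwd_start < c.rev_start:
            n_fwd += 1
        elif c.rev_start < c.fwd_start:
            n_rev += 1
    n = n_fwd + n_rev
    if n == 0:
        raise ValueError("no comparisons with distinct motif starts")
    return n_fwd, n_rev, binomial_two_sided(n_fwd, n)


@dataclass
class RankedMotif:
    motif: PWMMotif
    n_targets: int
    read_support: float
    e_value: float
    matchback_pvalue: float
    top_tercile: dict[str, bool] = field(default_factory=dict)

    @property
    def high_confidence(self) -> bool:
        return bool(self.top_tercile) and all(self.top_tercile.values())


def rank_motifs(motifs: Sequence[PWMMotif]) -> list[RankedMotif]:
    """Flag, per parameter, the motifs in the top third of the cohort.

    Parameters: number of unique contributing targets (higher is better),
    total read support (higher), motif E-value (lower) and match-back
    p-value (lower).  A motif is top-tercile for a parameter when fewer than
    ceil(n/3) cohort members are strictly better, so ties share rank.
    """
    if len(motifs) < 3:
        raise ValueError("ranking needs a cohort of at least 3 motifs")
    ranked = [
        RankedMotif(
            motif=m,
            n_targets=m.n_sites,
            read_support=m.read_support,
            e_value=m.e_value,
            matchback_pvalue=m.matchback_pvalue if m.matchback_pvalue is not None else 1.0,
        )
        for m in motifs
    ]
    n = len(ranked)
    cutoff = math.ceil(n / 3)
    params: Mapping[str, tuple] = {
        "n_targets": (lambda r: r.n_targets, True),
        "read_support": (lambda r: r.read_support, True),
        "e_value": (lambda r: r.e_value, False),
        "matchback_pvalue": (lambda r: r.matchback_pvalue, False),
    }
    for pname, (get, higher_better) in params.items():
        values = [get(r) for r in ranked]
        for r in ranked:
            v = get(r)
            better = sum(
                1 for u in values if (u > v if higher_better else u < v)
            )
            r.top_tercile[pname] = better < cutoff
    return ranked


# ---------------------------------------------------------------------------
# minimal motif-matrix text interchange format


def write_motif_matrix(motif: PWMMotif, path) -> None:
    """Alphabet line followed by width rows of 4 probabilities."""
    with open(path, "w") as fh:
        fh.write("ACGT\n")
        for row in motif.matrix:
            fh.write("\t".join(f"{p:.6f}" for p in row) + "\n")


def read_motif_matrix(path, trf_name: str = "", orientation: str = "forward") -> PWMMotif:
    with open(path) as fh:
        alphabet = fh.readline().strip()
        if alphabet != "ACGT":
            raise ValueError(f"unsupported alphabet {alphabet!r}")
        rows = [[float(x) for x in line.split()] for line in fh if line.strip()]
    matrix = np.array(rows)
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    return PWMMotif(
        trf_name=trf_name,
        orientation=orientation,
        width=matrix.shape[0],
        matrix=matrix,
        e_value=float("nan"),
        n_sites=0,
    )
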