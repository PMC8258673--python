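# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `trfclash`, in the order the pipeline runs.

## Coordinate model and fragment taxonomy

All coordinates are 1-based closed intervals on the tRNA gene body with
introns included; this is the only convention under which the canonical
fragment names (`host_gene-[N|M|NM]-type-start-end`, e.g. a 5′ half named
`...-5i-1-33`) are reproducible. A fragment may extend past the gene body
into exactly one of two 3′ extensions: the post-transcriptionally appended
CCA (positions L+1..L+3) or the genomic trailer. The six types are decided
in the precedence 3t → 5p/5i → 3p/3i → i:

- **3t**: ends ≥3 nt into the trailer, or starts after the gene end
  (fragments traditionally called tRF-1 are folded in here);
- **5p / 5i**: starts in the first 5 nt and ends before / inside the
  annotated anticodon loop;
- **3p / 3i**: ends within the last 5 positions of the CCA-extended gene
  (end ≥ L−1, since CCA occupies the last 3 of those 5) and starts after /
  inside the loop;
- **i**: everything else.

The precedence makes the classifier total: intervals satisfying several
anchored rules (possible only for near-full-length fragments, which the
80% rule removes upstream) are still assigned exactly one type. How the
anticodon-loop boundary was derived (loop only vs. loop plus flanking stem
nucleotides) is deliberately externalized to the annotation file; the
classifier only consumes the annotated interval.

## Chimera decomposition

The tRF arm is the longest *exact* substring match to any gene extended
sequence anchored at the read's 5′ end (forward) or 3′ end (reverse).
Exactness is a modelling decision, not a shortcut: the analysis is defined
on fragments that map perfectly to tRNAs, and sequencing-error tolerance
is explicitly out of scope. Anchored matching is monotone in length, so
each gene space is searched by bisection.

Thresholds (all in one `Thresholds` record; every stage reads only from
it): arm/read ≥ 0.80 rejects the read as tRNA-dominated; minimum tRF arm
16 nt (stated for PAR-CLIP inclusion, adopted for chimera arms for
consistency); minimum target arm 10 nt (unstated upstream; shorter arms
cannot be placed reliably). Ambiguous gene hits are all recorded, with the
lexicographically smallest gene id canonical for naming and tallies.
Target arms are placed on transcripts by exact substring match; the
region label of a boundary-spanning segment is the majority-overlap label
with ties broken 3UTR > CDS > 5UTR > intron. Reads with anchored tRNA
matches on both ends that jointly cover the read are classified tRF–tRF
(same-gene disjoint placement takes precedence over the different-gene
reading) and removed from the tRF–target stream.

## polyT artifact handling

A target is flagged when it carries a run of ≥5 consecutive Ts; a separate
flag records whether such a run touches the last 10 nt of the target.
Ambiguity characters break runs and contribute to no dinucleotide count.
The dinucleotide PCA (16 overlapping-dinucleotide frequencies, denominator
length−1) is column-centered, fitted jointly over both orientations, and
sign-fixed so each component's largest-magnitude loading is positive —
scores are therefore reproducible across runs and row orders. The
operator-drawn boundary used in exploratory plots is replaced by the
explicit run flags; the PCA only *visualizes* how flagged points
distribute.

## Motif discovery

Per tRF and orientation, unique polyT-filtered target sequences (read
support kept as weights, minimum 10 unique sequences — an EM-stability
choice) are searched with a ZOOPS EM finder over widths 6–12: each
sequence carries at most one motif occurrence; the E-step computes
per-position site posteriors against a 0-order background estimated from
the target set; the M-step re-estimates the PWM with +0.25 pseudocounts
and the site prior γ. Starts are seeded from the most heavily covered
distinct k-mers plus one random window; iteration stops when the
log-likelihood changes by <1e-5 (relative), capped at 40 iterations.

Significance is empirical. For each width, the same finder (identical
settings) runs on 20 decoy sets made by dinucleotide-preserving shuffles
(random Eulerian walks on the transition multigraph) of every target; the
real log-likelihood-ratio score is referred to a Gumbel tail fitted to the
decoy scores by moments, and the tail probability is Bonferroni-scaled by
the number of widths tested. The Gumbel family is the natural model for
best-of-many EM scores, and a parametric tail is required for E-values
below 1/(1+#decoys); with a rank-based formula, 20 decoys could never
certify E < 0.01. Calibration is checked empirically: on uniform-random
target sets the finder reports a motif in ≤5% of seeds.

Match-back scans the motif log-odds over the *reverse complement* of the
tRF (guide–target base pairing), uniform background by default. The
p-value of the best hit is computed from the full score distribution,
obtained by convolving per-column score distributions on their exact value
set (partial sums accumulate left to right; exactly equal values merge).
Below a working-set cap of 2^20 values — which covers every width ≤ 10 —
this equals full 4^w enumeration to machine precision; beyond the cap,
values collapse onto a range/2^21 lattice, bounding the score error by
w·step/2. Ties in the scan resolve to the 5′-most tRF position.

Forward/reverse motif pairs are compared on tRF coordinates: *identical*
requires equal intervals and mean per-column Pearson correlation ≥ 0.95
(the notion of "identical" motifs is not operationally defined upstream;
this criterion is the package's own and is flagged as such), overlaps ≥4 nt
and 1–3 nt are separate classes, and the upstream–downstream asymmetry of
start positions is tested with an exact two-sided binomial (doubled
smaller tail — at p₀ = 0.5 the distribution is symmetric, so this equals
the minimum-likelihood construction and reproduces both printed worked
examples). Motif cohorts are ranked on four parameters (unique targets,
read support, E-value, match-back p); a motif is top-tercile for a
parameter when fewer than ⌈n/3⌉ cohort members are strictly better, so
ties share rank and a fully tied cohort is entirely top-tercile.

## PAR-CLIP conversion profiling

Reads ≥16 nt are aligned end-to-end against all gene extended sequences;
a perfect placement anywhere always beats a one-mismatch placement, and a
single mismatch is accepted only as reference-T → read-C. Ambiguous hits
resolve to the lexicographically smallest gene, matching the chimera
convention, so multi-gene reads are counted once. Each conversion event
contributes 1e6 / (total aligned reads in its sample) and samples are
summed; the RPM denominator is all aligned reads per sample (whether the
upstream analyses normalized by all or by tRNA-aligned reads is unstated;
this default is configurable). The profile maximum is the top conversion
site, ties resolved to the 5′-most position and flagged.

Cross-species mapping requires a full-length exact sequence match of the
other species' tRF to a reference gene; positions translate through the
match offset, non-matching tRFs are dropped and counted.

Bitscores are raw per-column information contents, 2 + Σ f·log₂f (logo
letter heights without small-sample correction — the correction choice is
unstated upstream, so the simplest definition is used). Each motif column
is placed at its tRF position minus the tRF's top conversion site and
summed across tRFs. The side-bias test gives each tRF one vote (more motif
bitscore strictly 5′ vs strictly 3′ of the site, ties excluded) and uses
the same exact binomial as the upstream–downstream test.

## Reactivity structure analysis

Scores live in [0,1]; a site's class is decided solely by the mean of
valid scores over the motif interval (≥0.5 single-stranded, else
double-stranded; no valid score → excluded, never imputed). Flanks default
to 20 nt per side (the flank length is unstated upstream). Aligned
profiles average per offset from the motif start, ignoring missing values
and reporting per-offset n.

The significance test statistic is mean(motif scores) − mean(flank
scores) per site. Because sites are *split into classes by their own motif
mean*, comparing a class against an unconditional null is biased by
selection — even null sites would look significant. The null is therefore
class-conditioned: random 12-mers drawn uniformly from the same
transcripts are classified by the same rule, and each class is referred to
its class-matched null via z = (mean_group − mean_null)/(sd_null/√n).
This choice makes the test calibrated on null data (checked: ~5% of null
p-values fall below 0.05) while remaining extremely sensitive to the
planted effect. The per-offset variant of the same z-test is reported as
a table rather than a single number.

## Synthetic data

The generator emulates all five pipeline inputs with planted truth.
Defaults are the study conditions: one tRF per gene cycling the six types
with the characteristic length modes (18 nt for 3p, 33–36 nt halves ending
in the anticodon loop for 5i); an 8-nt binding motif per tRF at 90%
per-position site identity; a conversion hotspot at tRF position 10
(inside the 8–12 region, enforced to be a T by construction) converting at
rate 0.3 vs 0.01 background; 10% of reads truncated below the 16 nt
filter; a polyT artifact rate of 0.1 restricted to forward targets with
run lengths 5–9; DS probability 0.983 and reactivity shift Δ = 0.3;
uniform background composition (a skewed option stress-tests discovery).

Orientation follows a two-parameter mechanism: each tRF binds its targets
upstream of the hotspot with probability β = 0.8 (the motif is planted on
that side); upstream binding frees the tRF 3′ end and yields forward
ligation with probability 0.8, downstream binding the mirror image. 5i
guides model the 2′,3′-cyclic-phosphate effect as a forward-ligation
*failure* with probability γ = 0.9 — the read is simply not formed, so 5i
forward pairs are thinned by (1−γ) without inflating the reverse set.
The quantitative link from binding side to ligation probability is the
package's own construction; the mechanism upstream is described only
verbally.

Target sites are written into the transcript sequences (mutated consensus
plus junction-safe boundary bases) so that every emitted target arm is an
exact transcript substring and noise-free reads are recovered at 100%.
What the generator does **not** emulate: sequencing errors, UMI/duplicate
structure, modification-induced misincorporation, skewed ligation
efficiencies beyond the two parameters above, or genome-scale reference
complexity. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not performance on real
libraries.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 4–12 genes, 40–60
transcripts, hundreds to a few thousand chimeric reads, 10,000 PAR-CLIP
reads, 20-seed replications for rate estimates; these sizes make every
statistic they compute stable while keeping a full run in minutes. All
randomness flows through explicit `numpy` generators derived from a single
seed; pipeline outputs, including the run manifest, are byte-identical
across reruns with the same configuration and seed (floats are written
with a fixed format, JSON keys sorted, no timestamps).

## Known limitations

- Arm matching and target placement are exact-match only; one mismatch or
  indel in an arm loses the read.
- The empirical E-value inherits Monte-Carlo noise from 20 decoy sets;
  E-values near the 0.01 threshold are soft.
- The exact p-value's lattice fallback (widths 11–12 with adversarial
  matrices) introduces a bounded but nonzero discretization error.
- Fold changes between orientations use a +0.5 pseudocount only for
  zero counts, so orientation-exclusive items are finite but their fold
  values depend on that convention.
- The tercile-ranking flags depend on the cohort composition; adding one
  motif can change another's flag.
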