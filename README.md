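# trfclash

Computational discovery of tRNA-fragment (tRF) binding motifs from
two-orientation chimeric reads, with Argonaute crosslinking-site profiling
and target secondary-structure analysis.

## The problem

tRNA-derived fragments are loaded into Argonaute and can act as regulatory
small RNAs, but their binding rules are mostly unknown.
Crosslinking-ligation assays (CLASH-style) capture a guide and its bound
target ligated into one chimeric read, in two orientations: *forward* pairs
carry the tRF on the 5′ end of the read, *reverse* pairs on the 3′ end.
Treating the two orientations as independent biological constructs, this
package:

- decomposes chimeric reads into an exact-match tRF arm anchored at a read
  end plus a target arm, excluding reads with ≥80% tRNA content and
  separating tRF–tRF chimeras;
- classifies fragments into the six coordinate-defined types (5p, 5i, 3p,
  3i, 3t, i) relative to the anticodon loop, the CCA-extended 3′ end and
  the genomic trailer, with canonical names
  `host_gene-[N|M|NM]-type-start-end`;
- detects and removes the polyT library artifact (targets carrying runs of
  ≥5 consecutive Ts, concentrated in forward pairs) via dinucleotide-
  composition PCA and explicit run statistics;
- discovers per-tRF target motifs with a self-contained ZOOPS
  (zero-or-one-occurrence-per-sequence) expectation–maximization PWM
  finder, assigns empirical E-values from dinucleotide-shuffled decoy
  target sets (threshold E < 0.01), and matches each motif back onto its
  tRF through the reverse complement with an **exact** PWM p-value computed
  by score-distribution convolution (threshold p < 0.001);
- profiles Argonaute crosslinking sites as T→C conversions in PAR-CLIP
  style reads (end-to-end alignment, at most one T→C mismatch, perfect
  matches preferred, reads <16 nt excluded, reads-per-million normalization
  across samples), and relates motif information content (bitscores) to the
  top conversion site with an exact binomial side-bias test;
- classifies the secondary structure of target sites from per-nucleotide
  reactivity scores (mean <0.5 over the motif region = double-stranded),
  and tests the motif-vs-flank reactivity change against class-matched
  random 12-mers.

A synthetic-data module generates every input with planted ground truth —
known tRFs, motifs, conversion hotspots, orientation bias and structure
effects — so the whole pipeline is testable end to end without downloads.

## Core statistics

- **Exact PWM match p-value.** For a motif of width *w* with log-odds
  matrix *S*, the null distribution of the match score of a random
  background *w*-mer is built by convolving the per-column score
  distributions on their exact value set; `p = P(score ≥ s_best)` then
  equals full enumeration of all 4^w words to machine precision.
- **Empirical motif E-value.** The ZOOPS EM log-likelihood-ratio score of
  the real target set is referred to a Gumbel extreme-value tail fitted to
  the best scores of dinucleotide-shuffled decoy sets, Bonferroni-scaled by
  the number of widths tested.
- **Upstream–downstream test.** For tRFs with both a forward and a reverse
  motif, the number of forward motifs starting 5′ of the reverse motif is
  tested against an exact two-sided binomial(n, ½). On the printed worked
  examples this gives p = 1.87E-4 for 60 of 85 tRF motif pairs and
  p = 1.42E-4 for 53 of 73 miRNA pairs.

## Worked example

```bash
python examples/03_motif_discovery.py
```

prints

```
tRF:                  TGGTGTTAACCTTACTATAC
planted site:         TTAACACC (revcomp of tRF[2..9])
discovered consensus: TTAACACC (width 8)
E-value:              4.46e-38  (threshold 0.01)
contributing targets: 48 of 50
match-back interval on tRF: (2, 9), exact p = 1.53e-05 (threshold 0.001, significant)
```

The finder recovers the planted 8-mer from 50 targets at 90% per-position
identity, the E-value is far below the 0.01 significance threshold, and
the match-back places the motif's complement exactly on tRF positions 2–9
where it was planted. The other examples cover read decomposition and pair
tallies (`01`), fragment classification and naming (`02`), conversion-site
profiling (`04`) and structure classification (`05`).

The same analyses run from the shell:

```bash
trfclash run-all --workdir work --seed 1
```

writes the simulated workspace, decompositions, pair tables, PCA scores,
motifs, conversion profiles, structure calls and a `manifest.json` that is
byte-identical across reruns with the same seed.

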