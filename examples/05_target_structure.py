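"""Classify target-site secondary structure from reactivity scores.

High per-nucleotide reactivity means single-stranded (SS), low means
double-stranded (DS); a site is called by the mean score over its motif
region (boundary 0.5).  The example simulates a reactivity track with a
planted DS bias, classifies every planted site, and tests the motif-vs-
flank score change against random 12-mers from the same transcripts.
"""

from trfclash import (
    ReactivityTrack,
    SimulationConfig,
    collect_site_scores,
    ds_fraction,
    make_references,
    significance_vs_random,
    simulate_reactivity,
)

cfg = SimulationConfig(seed=9, n_genes=12, n_slots_per_trf=42, n_mrna=60)
refs = make_references(cfg)
trackdf, site_truth = simulate_reactivity(cfg, refs)
track = ReactivityTrack(trackdf)

sites = [
    collect_site_scores(r.transcript_id, (r.motif_start, r.motif_end), track)
    for r in site_truth.itertuples()
]
frac = ds_fraction(sites)
print(f"classified {len(sites)} target sites")
print(f"double-stranded fraction: {frac:.3f} "
      f"(planted DS probability {cfg.p_ds})")

res = significance_vs_random(sites, refs.transcripts, track, n_draws=400, seed=2)
for cls in ("DS", "SS"):
    if cls in res:
        print(f"  {cls}: motif-vs-flank z = {res['z_' + cls]:+.1f}, "
              f"p = {res[cls]:.3g} vs class-matched random 12-mers")
# The planted reactivity shift (delta = 0.3) makes both classes deviate
# far more than random 12-mers drawn from the same transcripts.
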