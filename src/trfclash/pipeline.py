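"""File-based orchestration of the analysis stages.

Each stage reads its inputs from a working directory, writes tab-separated
outputs, and contributes an entry (inputs, outputs, record counts) to a
JSON manifest.  Stages are deterministic given the same configuration and
seed, and running them one by one equals ``run-all``.  The stage graph:

    simulate -> parse-chimeras -> classify
                               -> composition
                               -> motifs -> parclip
                                         -> structure
    report (aggregates whatever stages ran)

Randomized steps derive their generators from the single configured seed,
so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chimera, composition, motifs, parclip, structure, taxonomy
from .reference import (
    Thresholds,
    load_gene_models,
    load_transcripts,
    write_gene_models,
    write_transcripts,
)
from .simulate import (
    SimulationConfig,
    make_references,
    simulate_clash_reads,
    simulate_parclip_reads,
    simulate_reactivity,
)

__all__ = ["PipelineConfig", "load_config", "run_stage", "run_all", "STAGES"]

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    motif_widths: tuple[int, ...] = tuple(range(6, 13))
    n_decoys: int = 20
    flank: int = structure.DEFAULT_FLANK
    n_null_draws: int = 500

    def __post_init__(self) -> None:
        self.simulation = self.simulation.replace(seed=self.seed)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "simulation": asdict(self.simulation),
                "thresholds": asdict(self.thresholds),
                "motif_widths": list(self.motif_widths),
                "n_decoys": self.n_decoys,
                "flank": self.flank,
                "n_null_draws": self.n_null_draws,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a declarative YAML config; missing keys take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimulationConfig(**raw.get("simulation", {}))
    thr = Thresholds(**raw.get("thresholds", {}))
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        simulation=sim,
        thresholds=thr,
        motif_widths=tuple(raw.get("motif_widths", range(6, 13))),
        n_decoys=int(raw.get("n_decoys", 20)),
        flank=int(raw.get("flank", structure.DEFAULT_FLANK)),
        n_null_draws=int(raw.get("n_null_draws", 500)),
    )


def _need(workdir: Path, *names: str) -> list[Path]:
    paths = [workdir / n for n in names]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"missing stage input: {p}")
    return paths


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _write_fasta(path: Path, items) -> None:
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, workdir: Path) -> dict:
    refs = make_references(cfg.simulation)
    clash_reads, clash_truth = simulate_clash_reads(cfg.simulation, refs)
    pc_reads, pc_totals, pc_truth = simulate_parclip_reads(cfg.simulation, refs)
    track, site_truth = simulate_reactivity(cfg.simulation, refs, clash_truth)

    write_gene_models(refs.genes, workdir / "genes.anno.tsv", workdir / "genes.fasta")
    write_transcripts(
        refs.transcripts, workdir / "transcripts.anno.tsv", workdir / "transcripts.fasta"
    )
    _write_fasta(workdir / "clash_reads.fasta", clash_reads)
    _write_fasta(workdir / "parclip_reads.fasta", [(f"{r}|s{s}", q) for r, q, s in pc_reads])
    _write_tsv(
        pd.DataFrame(
            {"sample": range(len(pc_totals)), "total_reads": pc_totals}
        ),
        workdir / "parclip_samples.tsv",
    )
    _write_tsv(track, workdir / "reactivity.tsv")
    _write_tsv(clash_truth.reads, workdir / "truth_reads.tsv")
    truth_trfs = pd.DataFrame(
        [
            {
                "trf_name": p.name,
                "gene_id": p.record.gene_id,
                "type": p.record.type,
                "start": p.record.start,
                "end": p.record.end,
                "motif_start": p.motif_interval[0],
                "motif_end": p.motif_interval[1],
                "hotspot": p.hotspot,
                "binding_side": p.binding_side,
                "site_consensus": p.site_consensus,
            }
            for p in refs.planted
        ]
    )
    _write_tsv(truth_trfs, workdir / "truth_trfs.tsv")
    _write_tsv(site_truth, workdir / "truth_sites.tsv")
    outputs = [
        "genes.anno.tsv", "genes.fasta", "transcripts.anno.tsv", "transcripts.fasta",
        "clash_reads.fasta", "parclip_reads.fasta", "parclip_samples.tsv",
        "reactivity.tsv", "truth_reads.tsv", "truth_trfs.tsv", "truth_sites.tsv",
    ]
    return {
        "inputs": [],
        "outputs": outputs,
        "counts": {
            "genes": len(refs.genes),
            "transcripts": len(refs.transcripts),
            "clash_reads": len(clash_reads),
            "parclip_reads": len(pc_reads),
        },
    }


def _load_indexes(cfg: PipelineConfig, workdir: Path):
    genes = load_gene_models(workdir / "genes.anno.tsv", workdir / "genes.fasta")
    txs = load_transcripts(
        workdir / "transcripts.anno.tsv", workdir / "transcripts.fasta"
    )
    return chimera.GeneIndex(genes), chimera.TranscriptIndex(txs), genes, txs


def stage_parse_chimeras(cfg: PipelineConfig, workdir: Path) -> dict:
    _need(workdir, "genes.anno.tsv", "genes.fasta", "transcripts.anno.tsv",
          "transcripts.fasta", "clash_reads.fasta")
    gi, ti, _genes, _txs = _load_indexes(cfg, workdir)
    thr = cfg.thresholds
    decomps: list[chimera.ChimeraDecomposition] = []
    counts: dict[str, int] = {}

    def bump(k: str) -> None:
        counts[k] = counts.get(k, 0) + 1

    for rid, seq in chimera.read_sequences(workdir / "clash_reads.fasta"):
        tt = chimera.detect_trf_trf(seq, gi, thr)
        if tt != "not_trf_trf":
            bump(f"trf_trf:{tt}")
            continue
        d = chimera.split_read(rid, seq, gi, ti, "forward", thr)
        if isinstance(d, chimera.Rejection) and d.reason == "no_trf_arm":
            d = chimera.split_read(rid, seq, gi, ti, "reverse", thr)
        if isinstance(d, chimera.Rejection):
            bump(d.reason)
        else:
            decomps.append(d)
            bump("accepted")

    rows = [
        {
            "read_id": d.read_id,
            "orientation": d.orientation,
            "trf_name": d.trf.name,
            "trf_type": d.trf.type,
            "trf_seq": d.trf.sequence,
            "target_seq": d.target_sequence,
            "transcript_id": d.target_annotation[0],
            "category": d.target_annotation[1],
            "region": d.target_annotation[2] or ".",
            "target_start": d.target_position,
            "ambiguity": ",".join(d.ambiguity) or ".",
        }
        for d in decomps
    ]
    _write_tsv(pd.DataFrame(rows), workdir / "decompositions.tsv")
    pairs, summary = chimera.tally_pairs(decomps)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "trf_name": p.trf_name,
                    "trf_type": p.trf_type,
                    "transcript_id": p.transcript_id,
                    "target_start": p.target_interval[0],
                    "target_end": p.target_interval[1],
                    "orientation": p.orientation,
                    "category": p.target_category,
                    "read_support": p.read_support,
                    "two_read_supported": int(p.two_read_supported),
                    "target_seq": p.target_sequence,
                }
                for p in pairs
            ]
        ),
        workdir / "pairs.tsv",
    )
    _write_tsv(summary, workdir / "pair_summary.tsv")
    _write_tsv(
        pd.DataFrame(sorted(counts.items()), columns=["reason", "n"]),
        workdir / "rejections.tsv",
    )
    return {
        "inputs": ["clash_reads.fasta"],
        "outputs": ["decompositions.tsv", "pairs.tsv", "pair_summary.tsv", "rejections.tsv"],
        "counts": {"accepted": counts.get("accepted", 0), "pairs": len(pairs)},
    }


def _load_pairs(workdir: Path) -> list[chimera.PairRecord]:
    df = pd.read_csv(workdir / "pairs.tsv", sep="\t")
    return [
        chimera.PairRecord(
            trf_name=r.trf_name,
            transcript_id=r.transcript_id,
            target_interval=(int(r.target_start), int(r.target_end)),
            orientation=r.orientation,
            read_support=int(r.read_support),
            trf_type=r.trf_type,
            target_category=r.category,
            target_sequence=r.target_seq,
        )
        for r in df.itertuples()
    ]


def stage_classify(cfg: PipelineConfig, workdir: Path) -> dict:
    _need(workdir, "decompositions.tsv")
    df = pd.read_csv(workdir / "decompositions.tsv", sep="\t")
    hists = []
    counts_by_orient: dict[str, dict[str, int]] = {"forward": {}, "reverse": {}}
    for orient, grp in df.groupby("orientation"):
        recs = []
        for r in grp.itertuples():
            p = taxonomy.parse_trf_name(r.trf_name)
            recs.append(
                taxonomy.TRFRecord(
                    gene_id=p["gene_id"], origin=p["origin"], type=p["type"],
                    start=p["start"], end=p["end"], sequence=r.trf_seq,
                )
            )
            counts_by_orient[orient][r.trf_name] = (
                counts_by_orient[orient].get(r.trf_name, 0) + 1
            )
        hists.append(taxonomy.length_distribution(recs, orient))
    _write_tsv(pd.concat(hists, ignore_index=True), workdir / "length_hist.tsv")
    stats: dict[str, float] = {}
    for level in ("isoform", "isodecoder"):
        if counts_by_orient["forward"] and counts_by_orient["reverse"]:
            table, r = taxonomy.compare_orientations(
                counts_by_orient["forward"], counts_by_orient["reverse"], level
            )
            _write_tsv(table, workdir / f"orientation_compare_{level}.tsv")
            stats[f"pearson_r_{level}"] = r
    with open(workdir / "classify.json", "w") as fh:
        json.dump(stats, fh, sort_keys=True, indent=1)
    return {
        "inputs": ["decompositions.tsv"],
        "outputs": ["length_hist.tsv", "classify.json"],
        "counts": {"records": int(len(df))},
    }


def stage_composition(cfg: PipelineConfig, workdir: Path) -> dict:
    _need(workdir, "pairs.tsv")
    pairs = _load_pairs(workdir)
    thr = cfg.thresholds
    items = [
        (f"{p.trf_name}|{p.transcript_id}|{p.target_interval[0]}|{p.orientation}",
         p.target_sequence)
        for p in pairs
    ]
    vectors = composition.dinucleotide_table(items)
    _write_tsv(vectors.reset_index(names="pair_id"), workdir / "dinuc_vectors.tsv")
    reports = [
        composition.polyt_report(seq, thr, sequence_id=pid) for pid, seq in items
    ]
    if len(vectors) >= 3:
        res = composition.pca_project(vectors.values, n_components=2)
        scores = pd.DataFrame(
            {
                "pair_id": vectors.index,
                "PC1": res.scores[:, 0],
                "PC2": res.scores[:, 1],
                "orientation": [p.orientation for p in pairs],
                "polyt_flag": [int(r.has_long_run) for r in reports],
            }
        )
        _write_tsv(scores, workdir / "pca_scores.tsv")
    clean, polyt, contrast = composition.partition_by_polyt(pairs, thr)
    with open(workdir / "polyt_contrast.json", "w") as fh:
        json.dump({k: (None if v != v else v) for k, v in contrast.items()},
                  fh, sort_keys=True, indent=1)
    return {
        "inputs": ["pairs.tsv"],
        "outputs": ["dinuc_vectors.tsv", "pca_scores.tsv", "polyt_contrast.json"],
        "counts": {"pairs": len(pairs), "polyt_flagged": len(polyt)},
    }


def stage_motifs(cfg: PipelineConfig, workdir: Path) -> dict:
    _need(workdir, "pairs.tsv", "decompositions.tsv")
    pairs = _load_pairs(workdir)
    thr = cfg.thresholds
    trf_seqs = dict(
        pd.read_csv(workdir / "decompositions.tsv", sep="\t")[
            ["trf_name", "trf_seq"]
        ].drop_duplicates().itertuples(index=False)
    )
    trf_names = sorted({p.trf_name for p in pairs})
    found: list[motifs.PWMMotif] = []
    per_trf: dict[str, dict[str, motifs.PWMMotif | None]] = {}
    for idx, name in enumerate(trf_names):
        rng = np.random.default_rng([cfg.seed, 7, idx])
        per_trf[name] = {}
        sets: dict[str, motifs.TargetSet | None] = {}
        for orient in ("forward", "reverse"):
            try:
                sets[orient] = motifs.assemble_target_set(name, pairs, thr, orient)
            except motifs.InsufficientTargetsError:
                sets[orient] = None
        for orient in ("forward", "reverse"):
            m = None
            if sets[orient] is not None:
                m = motifs.discover_motif(
                    sets[orient], widths=cfg.motif_widths, seed=rng,
                    thresholds=thr, n_decoys=cfg.n_decoys,
                )
            if m is not None and name in trf_seqs:
                if not motifs.match_to_trf(m, trf_seqs[name], thr):
                    m = None  # failed match-back at p < threshold
            per_trf[name][orient] = m
            if m is not None:
                found.append(m)
        try:
            mc = motifs.combine_orientations(
                sets["forward"], sets["reverse"], thr, seed=rng, widths=cfg.motif_widths
            )
        except motifs.InsufficientTargetsError:
            mc = None
        if mc is not None and name in trf_seqs:
            if not motifs.match_to_trf(mc, trf_seqs[name], thr):
                mc = None
        per_trf[name]["combined"] = mc
        if mc is not None:
            found.append(mc)

    _write_tsv(
        pd.DataFrame(
            [
                {
                    "trf_name": m.trf_name,
                    "orientation": m.orientation,
                    "width": m.width,
                    "consensus": m.consensus,
                    "e_value": m.e_value,
                    "n_sites": m.n_sites,
                    "read_support": m.read_support,
                    "trf_start": m.trf_interval[0] if m.trf_interval else 0,
                    "trf_end": m.trf_interval[1] if m.trf_interval else 0,
                    "matchback_pvalue": m.matchback_pvalue,
                    "matrix": ";".join(
                        ",".join(_FLOAT_FMT % v for v in row) for row in m.matrix
                    ),
                }
                for m in found
            ]
        ),
        workdir / "motifs.tsv",
    )
    comparisons = [
        motifs.compare_motifs(d.get("forward"), d.get("reverse"))
        for d in per_trf.values()
    ]
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "trf_name": c.trf_name,
                    "class": c.cls,
                    "overlap_nt": c.overlap_nt,
                    "fwd_start": c.fwd_start if c.fwd_start is not None else -1,
                    "rev_start": c.rev_start if c.rev_start is not None else -1,
                }
                for c in comparisons
            ]
        ),
        workdir / "motif_comparisons.tsv",
    )
    ud: dict = {}
    try:
        n_f, n_r, p = motifs.upstream_downstream_test(comparisons)
        ud = {"n_fwd_upstream": n_f, "n_rev_upstream": n_r, "p_value": p}
    except ValueError:
        ud = {"n_fwd_upstream": 0, "n_rev_upstream": 0, "p_value": None}
    with open(workdir / "upstream_downstream.json", "w") as fh:
        json.dump(ud, fh, sort_keys=True, indent=1)
    if len(found) >= 3:
        ranked = motifs.rank_motifs(found)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "trf_name": r.motif.trf_name,
                        "orientation": r.motif.orientation,
                        "n_targets": r.n_targets,
                        "read_support": r.read_support,
                        "e_value": r.e_value,
                        "matchback_pvalue": r.matchback_pvalue,
                        "high_confidence": int(r.high_confidence),
                        **{f"top_{k}": int(v) for k, v in sorted(r.top_tercile.items())},
                    }
                    for r in ranked
                ]
            ),
            workdir / "ranked_motifs.tsv",
        )
    return {
        "inputs": ["pairs.tsv", "decompositions.tsv"],
        "outputs": ["motifs.tsv", "motif_comparisons.tsv", "upstream_downstream.json",
                    "ranked_motifs.tsv"],
        "counts": {"motifs": len(found)},
    }


def _load_motifs(workdir: Path) -> list[motifs.PWMMotif]:
    df = pd.read_csv(workdir / "motifs.tsv", sep="\t")
    out = []
    for r in df.itertuples():
        matrix = np.array(
            [[float(x) for x in row.split(",")] for row in r.matrix.split(";")]
        )
        matrix = matrix / matrix.sum(axis=1, keepdims=True)
        m = motifs.PWMMotif(
            trf_name=r.trf_name, orientation=r.orientation, width=int(r.width),
            matrix=matrix, e_value=float(r.e_value), n_sites=int(r.n_sites),
            read_support=float(r.read_support),
        )
        if int(r.trf_start) > 0:
            m.trf_interval = (int(r.trf_start), int(r.trf_end))
            m.matchback_pvalue = float(r.matchback_pvalue)
        out.append(m)
    return out


def stage_parclip(cfg: PipelineConfig, workdir: Path) -> dict:
    _need(workdir, "genes.anno.tsv", "genes.fasta", "parclip_reads.fasta",
          "parclip_samples.tsv", "motifs.tsv")
    gi, _ti, genes, _txs = _load_indexes(cfg, workdir)
    thr = cfg.thresholds
    totals_df = pd.read_csv(workdir / "parclip_samples.tsv", sep="\t")
    n_samples = len(totals_df)
    per_sample: list[list[parclip.ParclipAlignment]] = [[] for _ in range(n_samples)]
    n_aligned = n_short = 0
    for rid, seq in chimera.read_sequences(workdir / "parclip_reads.fasta"):
        sample = int(rid.rsplit("|s", 1)[1])
        if len(seq) < thr.min_parclip_read:
            n_short += 1
            continue
        a = parclip.align_parclip_read(seq, gi, thr)
        if a is not None:
            per_sample[sample].append(a)
            n_aligned += 1
    sample_totals = [max(1, len(s)) for s in per_sample]  # aligned reads per sample

    profile_rows = []
    gene_top: dict[str, int | None] = {}
    for g in genes:
        length = g.length + max(3, len(g.trailer))
        prof = parclip.conversion_profile(per_sample, sample_totals, g.gene_id, length)
        gene_top[g.gene_id] = prof.top_site
        for pos in range(length):
            if prof.rpm[pos] > 0 or prof.depth[pos] > 0:
                profile_rows.append(
                    (g.gene_id, pos + 1, prof.rpm[pos], int(prof.depth[pos]))
                )
    _write_tsv(
        pd.DataFrame(profile_rows, columns=["gene_id", "position", "rpm", "depth"]),
        workdir / "conversion_profiles.tsv",
    )
    # tRF-relative top sites for motif-bearing tRFs
    all_motifs = _load_motifs(workdir)
    top_sites: dict[str, int | None] = {}
    for m in all_motifs:
        p = taxonomy.parse_trf_name(m.trf_name)
        top = gene_top.get(p["gene_id"])
        if top is not None and p["start"] <= top <= p["end"]:
            top_sites[m.trf_name] = top - p["start"] + 1
        else:
            top_sites[m.trf_name] = None
    _write_tsv(
        pd.DataFrame(
            [(k, v if v is not None else -1) for k, v in sorted(top_sites.items())],
            columns=["trf_name", "top_site"],
        ),
        workdir / "top_sites.tsv",
    )
    hist = parclip.bitscore_histogram(all_motifs, top_sites)
    _write_tsv(
        pd.DataFrame(
            {
                "offset": hist.offsets,
                "cumulative_bitscore": hist.cumulative,
                "n_trfs": hist.n_contributing,
            }
        ),
        workdir / "bitscore_hist.tsv",
    )
    sb: dict = {}
    try:
        n_up, n_down, p = parclip.side_bias_test(all_motifs, top_sites)
        sb = {"n_upstream": n_up, "n_downstream": n_down, "p_value": p}
    except ValueError:
        sb = {"n_upstream": 0, "n_downstream": 0, "p_value": None}
    with open(workdir / "side_bias.json", "w") as fh:
        json.dump(sb, fh, sort_keys=True, indent=1)
    return {
        "inputs": ["parclip_reads.fasta", "parclip_samples.tsv", "motifs.tsv"],
        "outputs": ["conversion_profiles.tsv", "top_sites.tsv", "bitscore_hist.tsv",
                    "side_bias.json"],
        "counts": {"aligned": n_aligned, "too_short": n_short},
    }


def stage_structure(cfg: PipelineConfig, workdir: Path) -> dict:
    _need(workdir, "pairs.tsv", "motifs.tsv", "reactivity.tsv",
          "transcripts.anno.tsv", "transcripts.fasta")
    pairs = _load_pairs(workdir)
    thr = cfg.thresholds
    txs = load_transcripts(
        workdir / "transcripts.anno.tsv", workdir / "transcripts.fasta"
    )
    track = structure.ReactivityTrack.from_tsv(workdir / "reactivity.tsv")
    all_motifs = {
        (m.trf_name, m.orientation): m for m in _load_motifs(workdir)
    }
    sites: list[structure.ReactivitySite] = []
    site_rows = []
    for p in pairs:
        m = all_motifs.get((p.trf_name, p.orientation)) or all_motifs.get(
            (p.trf_name, "combined")
        )
        if m is None:
            continue
        loc = motifs.best_pwm_site(m.matrix, p.target_sequence)
        if loc is None:
            continue
        start_on_tx = p.target_interval[0] + loc
        interval = (start_on_tx, start_on_tx + m.width - 1)
        site = structure.collect_site_scores(
            p.transcript_id, interval, track, thr, cfg.flank
        )
        sites.append(site)
        site_rows.append(
            {
                "trf_name": p.trf_name,
                "transcript_id": p.transcript_id,
                "motif_start": interval[0],
                "motif_end": interval[1],
                "orientation": p.orientation,
                "class": site.cls,
            }
        )
    _write_tsv(pd.DataFrame(site_rows), workdir / "structure_sites.tsv")
    stats: dict = {"n_sites": len(sites)}
    classified = [s for s in sites if s.cls in ("SS", "DS")]
    if classified:
        _write_tsv(structure.aligned_profile(classified), workdir / "aligned_profile.tsv")
        stats["ds_fraction"] = structure.ds_fraction(classified)
        pvals = structure.significance_vs_random(
            classified, txs, track,
            n_draws=cfg.n_null_draws,
            seed=np.random.default_rng([cfg.seed, 11]),
            thresholds=thr, flank=cfg.flank,
        )
        stats.update({f"p_{k}" if k in ("DS", "SS") else k: v for k, v in pvals.items()})
    with open(workdir / "structure_stats.json", "w") as fh:
        json.dump(stats, fh, sort_keys=True, indent=1)
    outputs = ["structure_sites.tsv", "structure_stats.json"]
    if classified:
        outputs.append("aligned_profile.tsv")
    return {
        "inputs": ["pairs.tsv", "motifs.tsv", "reactivity.tsv"],
        "outputs": outputs,
        "counts": {"sites": len(sites), "classified": len(classified)},
    }


def stage_report(cfg: PipelineConfig, workdir: Path) -> dict:
    report: dict = {"seed": cfg.seed}
    for name in ("classify.json", "polyt_contrast.json", "upstream_downstream.json",
                 "side_bias.json", "structure_stats.json"):
        p = workdir / name
        if p.exists():
            with open(p) as fh:
                report[name.removesuffix(".json")] = json.load(fh)
    for name in ("pairs.tsv", "motifs.tsv"):
        p = workdir / name
        if p.exists():
            report[f"n_{name.removesuffix('.tsv')}"] = int(
                len(pd.read_csv(p, sep="\t"))
            )
    with open(workdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return {"inputs": [], "outputs": ["report.json"], "counts": {}}


STAGES = {
    "simulate": stage_simulate,
    "parse-chimeras": stage_parse_chimeras,
    "classify": stage_classify,
    "composition": stage_composition,
    "motifs": stage_motifs,
    "parclip": stage_parclip,
    "structure": stage_structure,
    "report": stage_report,
}


def _update_manifest(cfg: PipelineConfig, workdir: Path, name: str, entry: dict) -> None:
    mpath = workdir / "manifest.json"
    manifest = {"version": "0.1.0", "seed": cfg.seed,
                "config_hash": cfg.config_hash(), "stages": {}}
    if mpath.exists():
        with open(mpath) as fh:
            manifest = json.load(fh)
    manifest["seed"] = cfg.seed
    manifest["config_hash"] = cfg.config_hash()
    manifest["stages"][name] = entry
    for out in entry["outputs"]:
        if not (workdir / out).exists():
            raise RuntimeError(f"stage {name} did not produce {out}")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)


def run_stage(name: str, cfg: PipelineConfig, workdir: str | Path) -> dict:
    """Run one stage, update the manifest, and return its entry."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    entry = STAGES[name](cfg, workdir)
    _update_manifest(cfg, workdir, name, entry)
    return entry


def run_all(cfg: PipelineConfig, workdir: str | Path) -> dict:
    """All stages in order; returns the final manifest."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    mpath = workdir / "manifest.json"
    if mpath.exists():
        mpath.unlink()
    for name in STAGES:
        run_stage(name, cfg, workdir)
    with open(mpath) as fh:
        return json.load(fh)
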