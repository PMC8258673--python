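import numpy as np
import pandas as pd
import pytest

from trfclash import (
    ReactivityTrack,
    TranscriptModel,
    aligned_profile,
    collect_site_scores,
    ds_fraction,
    significance_vs_random,
)
from trfclash.structure import _site_statistic

from conftest import random_seq


def _track(tx_scores: dict[str, list[float]]) -> ReactivityTrack:
    rows = [
        (tid, pos + 1, s)
        for tid, scores in tx_scores.items()
        for pos, s in enumerate(scores)
    ]
    return ReactivityTrack(
        pd.DataFrame(rows, columns=["transcript_id", "position", "score"])
    )


class TestClassification:
    def test_high_scores_are_single_stranded(self):
        track = _track({"tx": [0.9] * 60})
        site = collect_site_scores("tx", (21, 32), track)
        assert site.cls == "SS"

    def test_low_scores_are_double_stranded(self):
        track = _track({"tx": [0.1] * 60})
        assert collect_site_scores("tx", (21, 32), track).cls == "DS"

    def test_boundary_mean_is_single_stranded(self):
        track = _track({"tx": [0.5] * 60})
        assert collect_site_scores("tx", (21, 32), track).cls == "SS"

    def test_absent_transcript_is_no_data(self):
        track = _track({"tx": [0.5] * 60})
        assert collect_site_scores("other", (5, 10), track).cls == "no_data"


class TestAlignedProfile:
    def test_single_site_profile_equals_its_scores(self):
        scores = [0.2] * 20 + [0.1] * 8 + [0.3] * 20
        track = _track({"tx": [0.0] * 10 + scores + [0.0] * 10})
        site = collect_site_scores("tx", (31, 38), track)
        prof = aligned_profile([site])
        motif_rows = prof[(prof.offset >= 0) & (prof.offset < 8)]
        assert np.allclose(motif_rows["mean_score"], 0.1)
        assert (prof["n"] == 1).all()

    def test_two_sites_average(self):
        track = _track({"a": [0.2] * 80, "b": [0.4] * 80})
        sites = [
            collect_site_scores("a", (31, 38), track),
            collect_site_scores("b", (31, 38), track),
        ]
        prof = aligned_profile(sites)
        assert np.allclose(prof["mean_score"], 0.3)
        assert (prof["n"] == 2).all()

    def test_mean_invariant_to_site_order(self):
        rng = np.random.default_rng(4)
        track = _track({f"t{i}": list(rng.random(80)) for i in range(6)})
        sites = [collect_site_scores(f"t{i}", (31, 38), track) for i in range(6)]
        a = aligned_profile(sites)
        b = aligned_profile(sites[::-1])
        pd.testing.assert_frame_equal(
            a.sort_values(["class", "offset"]).reset_index(drop=True),
            b.sort_values(["class", "offset"]).reset_index(drop=True),
        )

    def test_ds_effect_separates_classes_only_over_motif(self):
        """A planted reactivity drop in the motif region splits the class
        curves at motif offsets but not in the flanks."""
        rng = np.random.default_rng(11)
        sites = []
        track_data = {}
        for i in range(120):
            tid = f"t{i}"
            scores = np.clip(rng.uniform(0, 1, 80), 0, 1)
            ds = i % 2 == 0
            delta = -0.3 if ds else 0.3
            scores[30:38] = np.clip(scores[30:38] + delta, 0, 1)
            track_data[tid] = list(scores)
        track = _track(track_data)
        sites = [collect_site_scores(f"t{i}", (31, 38), track) for i in range(120)]
        prof = aligned_profile(sites).pivot(index="offset", columns="class", values="mean_score")
        motif = prof.loc[0:7]
        flank = prof.loc[-15:-6]
        assert (motif["SS"] - motif["DS"]).mean() > 0.4
        assert abs((flank["SS"] - flank["DS"]).mean()) < 0.15


class TestSignificance:
    def _workspace(self, n_sites, delta, seed):
        rng = np.random.default_rng(seed)
        txs = [
            TranscriptModel(f"t{i}", "mRNA", random_seq(rng, 800))
            for i in range(10)
        ]
        data = {t.transcript_id: rng.uniform(0, 1, 800) for t in txs}
        sites = []
        for j in range(n_sites):
            tid = f"t{j % 10}"
            start = 50 + (j // 10) * 35
            if delta:
                data[tid][start - 1 : start + 11] = np.clip(
                    data[tid][start - 1 : start + 11] - delta, 0, 1
                )
        track = _track({k: list(v) for k, v in data.items()})
        for j in range(n_sites):
            tid = f"t{j % 10}"
            start = 50 + (j // 10) * 35
            sites.append(collect_site_scores(tid, (start, start + 11), track))
        return sites, txs, track

    def test_toy_z_matches_hand_computation(self):
        sites, txs, track = self._workspace(5, 0.4, 3)
        res = significance_vs_random(sites, txs, track, n_draws=200, seed=1)
        group = np.array([_site_statistic(s) for s in sites if s.cls == "DS"])
        rng = np.random.default_rng(1)
        # rebuild the class-conditioned null exactly as the implementation does
        null = {"DS": [], "SS": []}
        while sum(len(v) for v in null.values()) < 200:
            t = txs[int(rng.integers(len(txs)))]
            start = int(rng.integers(1, t.length - 12 + 2))
            s = collect_site_scores(t.transcript_id, (start, start + 11), track)
            v = _site_statistic(s)
            if s.cls in null and not np.isnan(v):
                null[s.cls].append(v)
        nds = np.array(null["DS"])
        z = (group.mean() - nds.mean()) / (nds.std(ddof=1) / np.sqrt(len(group)))
        from scipy.stats import norm
        assert res["z_DS"] == pytest.approx(z, abs=1e-12)
        assert res["DS"] == pytest.approx(2 * norm.sf(abs(z)), abs=1e-12)

    def test_null_sites_are_calibrated(self):
        """Sites drawn from the null give roughly uniform p-values."""
        n_small = 0
        for rep in range(50):
            sites, txs, track = self._workspace(20, 0.0, 100 + rep)
            res = significance_vs_random(
                sites, txs, track, n_draws=150, seed=200 + rep
            )
            ps = [v for k, v in res.items() if k in ("DS", "SS")]
            if min(ps) < 0.05 / len(ps):  # per-replicate two-class correction
                n_small += 1
        assert 0 <= n_small <= 6  # ~1-12% of 50 replicates

    def test_planted_effect_is_detected(self):
        hits = 0
        for rep in range(10):
            sites, txs, track = self._workspace(200, 0.3, 300 + rep)
            res = significance_vs_random(sites, txs, track, n_draws=300, seed=rep)
            if res["DS"] < 1e-6:
                hits += 1
        assert hits >= 9

    def test_too_few_draws_rejected(self):
        sites, txs, track = self._workspace(5, 0.3, 1)
        with pytest.raises(ValueError):
            significance_vs_random(sites, txs, track, n_draws=50, seed=0)


class TestDsFraction:
    def test_no_data_excluded_from_denominator(self):
        track = _track({"a": [0.1] * 60, "b": [0.9] * 60})
        sites = (
            [collect_site_scores("a", (21, 32), track) for _ in range(3)]
            + [collect_site_scores("b", (21, 32), track)]
            + [collect_site_scores("missing", (21, 32), track) for _ in range(2)]
        )
        assert ds_fraction(sites) == pytest.approx(0.75)

    def test_all_no_data_rejected(self):
        track = _track({"a": [0.5] * 10})
        sites = [collect_site_scores("x", (1, 5), track)]
        with pytest.raises(ValueError):
            ds_fraction(sites)

    def test_planted_ds_probability_concentrates(self):
        from trfclash.simulate import SimulationConfig, make_references, simulate_reactivity
        from trfclash.structure import ReactivityTrack, collect_site_scores

        cfg = SimulationConfig(seed=17, n_genes=12, n_slots_per_trf=42, n_mrna=60, p_ds=0.9)
        refs = make_references(cfg)
        trackdf, site_truth = simulate_reactivity(cfg, refs)
        track = ReactivityTrack(trackdf)
        sites = [
            collect_site_scores(r.transcript_id, (r.motif_start, r.motif_end), track)
            for r in site_truth.itertuples()
        ]
        assert len(sites) >= 500
        assert ds_fraction(sites) == pytest.approx(0.9, abs=0.05)
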