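"""The synthetic cohort generator: determinism, round-trips, planted effects."""

import numpy as np
import pandas as pd
import pytest

from engramflow import synthdata as sd
from engramflow.behavior import score_block, score_table, gains_table
from engramflow.bold_features import compute_ilc, mvlc_pattern, similarity_difference
from engramflow.config import CohortConfig, EffectSpec
from engramflow.errors import ConfigurationError, InputError
from engramflow.mrs_quant import quantify_panel


class TestMakeCohort:
    def test_default_cohort_size(self):
        roster = sd.make_cohort(CohortConfig())
        assert len(roster) == 57
        assert (roster["group"] == "Learning").sum() == 36
        assert (roster["group"] == "Control").sum() == 21

    def test_custom_counts(self):
        roster = sd.make_cohort(CohortConfig(n_learning=4, n_control=4))
        assert len(roster) == 8

    def test_deterministic_under_seed(self):
        a = sd.make_cohort(CohortConfig(master_seed=5)).to_csv()
        b = sd.make_cohort(CohortConfig(master_seed=5)).to_csv()
        assert a == b

    @pytest.mark.parametrize("kwargs", [
        {"n_learning": 0}, {"n_learning": 3}, {"voxel_size": 0.0}, {"tr": -1.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            sd.make_cohort(CohortConfig(**kwargs))


class TestSimulateMetabolites:
    def test_baseline_dependence_is_negative(self):
        cfg = CohortConfig(n_learning=200, n_control=4, master_seed=1)
        eff = EffectSpec(regression_to_mean_slope=-0.5, qc_contamination_rate=0.0)
        _, lat = sd.simulate_metabolites(sd.make_cohort(cfg), eff, cfg)
        L = lat[lat["group"] == "Learning"]
        panel, _ = sd.simulate_metabolites(sd.make_cohort(cfg), eff, cfg)
        pre = panel.query("metabolite == 'GABA' and timepoint == 'pre' and group == 'Learning'")
        pre = pre.set_index("subject_id")["conc_raw"]
        d = L.set_index("subject_id")["d_gaba_avg"]
        assert np.corrcoef(pre[d.index], d)[0, 1] < 0

    def test_post_coupling_recovered_at_large_n(self):
        cfg = CohortConfig(n_learning=500, n_control=4, master_seed=2)
        eff = EffectSpec(qc_contamination_rate=0.0)
        panel, _ = sd.simulate_metabolites(sd.make_cohort(cfg), eff, cfg)
        q = quantify_panel(panel)
        q = q[q["group"] == "Learning"]
        wide = q.pivot_table(index=["subject_id", "metabolite"],
                             columns="timepoint", values="conc")
        posts = [c for c in wide.columns if c.startswith("post")]
        glu = wide.xs("Glu", level=1)[posts].mean(axis=1)
        gaba = wide.xs("GABA", level=1)[posts].mean(axis=1)
        assert np.corrcoef(glu, gaba)[0, 1] == pytest.approx(0.58, abs=0.1)

    def test_degenerate_noise_free_draw_has_zero_deltas(self):
        cfg = CohortConfig(n_learning=10, n_control=4, master_seed=3)
        eff = EffectSpec(
            regression_to_mean_slope=0.0, control_glu_slope_factor=0.0,
            coupling_r_pre=0.0, coupling_r_post=0.0,
            scan_noise_sd={m: 0.0 for m in ("Glu", "GABA", "NAA", "Gln", "Cr")},
            post_innovation_sd={m: 0.0 for m in ("Glu", "GABA", "NAA", "Gln", "Cr")},
            qc_contamination_rate=0.0)
        _, lat = sd.simulate_metabolites(sd.make_cohort(cfg), eff, cfg)
        for col in ("d_glu_imm", "d_glu_avg", "d_gaba_30"):
            assert lat[col].abs().max() == 0.0

    def test_empty_roster_rejected(self):
        with pytest.raises(InputError):
            sd.simulate_metabolites(pd.DataFrame(), EffectSpec(), CohortConfig())


@pytest.fixture(scope="module")
def cohort_tables():
    cfg = CohortConfig(n_learning=40, n_control=4, master_seed=4)
    eff = EffectSpec()
    roster = sd.make_cohort(cfg)
    _, lat = sd.simulate_metabolites(roster, eff, cfg)
    behav, lat = sd.simulate_behavior(roster, eff, cfg, lat)
    return behav, lat


class TestSimulateBehavior:

    def test_streams_roundtrip_through_scoring(self, cohort_tables):
        behav, _ = cohort_tables
        for rec in behav.itertuples(index=False):
            assert score_block(rec.keystream)[0] == rec.n_correct

    def test_gain_partition_matches_scored_signs(self, cohort_tables):
        behav, lat = cohort_tables
        scores = score_table(behav)
        gains = gains_table(scores).set_index("subject_id")
        lat = lat.dropna(subset=["partition"]).set_index("subject_id")
        for sid, row in lat.iterrows():
            g = gains.loc[sid, "overnight_gain_pct"]
            expected = "improved" if g > 0 else ("declined" if g < 0 else "level")
            assert row["partition"] == expected

    def test_mean_gain_matches_target_at_large_n(self):
        cfg = CohortConfig(n_learning=500, n_control=4, master_seed=5)
        roster = sd.make_cohort(cfg)
        eff = EffectSpec()
        _, lat = sd.simulate_metabolites(roster, eff, cfg)
        behav, _ = sd.simulate_behavior(roster, eff, cfg, lat)
        gains = gains_table(score_table(behav))
        assert gains["overnight_gain_pct"].mean() == pytest.approx(10.46, abs=1.0)

    def test_invalid_changepoint_rejected(self):
        cfg = CohortConfig(n_learning=6, n_control=4)
        with pytest.raises(ConfigurationError):
            eff = EffectSpec(changepoint_block=13)
            roster = sd.make_cohort(cfg)
            _, lat = sd.simulate_metabolites(roster, EffectSpec(), cfg)
            sd.simulate_behavior(roster, eff, cfg, lat)


class TestSimulateGmVolumes:
    def _gm_and_latents(self, eff, n=1000, seed=6):
        cfg = CohortConfig(n_learning=n, n_control=4, master_seed=seed)
        roster = sd.make_cohort(cfg)
        _, lat = sd.simulate_metabolites(roster, eff, cfg)
        gm = sd.simulate_gm_volumes(roster, eff, cfg, lat)
        L = gm[gm["group"] == "Learning"].pivot_table(
            index="subject_id", columns="roi", values="gm_change")
        return L.join(lat.set_index("subject_id"))

    def test_planted_gaba_gm_correlation_recovered(self):
        f = self._gm_and_latents(EffectSpec(qc_contamination_rate=0.0))
        r = np.corrcoef(f["d_gaba_30"], f["M1"])[0, 1]
        # planted on the partial scale; the marginal correlation is slightly
        # stronger than the -0.48 partial target
        assert r == pytest.approx(-0.5, abs=0.08)

    def test_null_effect_gives_no_correlation(self):
        from engramflow.config import null_effects
        f = self._gm_and_latents(null_effects())
        assert abs(np.corrcoef(f["d_gaba_30"], f["M1"])[0, 1]) < 0.1

    def test_pcc_is_independent_of_gaba(self):
        f = self._gm_and_latents(EffectSpec(qc_contamination_rate=0.0))
        assert abs(np.corrcoef(f["d_gaba_30"], f["PCC"])[0, 1]) < 0.1


class TestSimulateBoldRun:
    def _roi(self, shape=(10, 10, 10)):
        roi = np.zeros(shape, bool)
        roi[3:7, 3:7, 3:7] = True
        return roi

    def _config(self):
        return CohortConfig(n_learning=4, n_control=4, grid_shape=(10, 10, 10),
                            n_volumes_rest=100)

    def test_fidelity_out_of_range_rejected(self):
        with pytest.raises(InputError):
            sd.simulate_bold_run("post_rest", self._roi(), self._config(),
                                 EffectSpec(), rng=np.random.default_rng(0),
                                 pattern_rng=np.random.default_rng(1), fidelity=1.5)

    def test_full_fidelity_low_noise_reproduces_task_pattern(self):
        # long runs shrink the Monte-Carlo error of the ILC pattern estimate
        cfg = CohortConfig(n_learning=4, n_control=4, grid_shape=(10, 10, 10),
                           n_volumes_rest=500)
        eff = EffectSpec(bold_noise_sd=1e-3, ar1_coef=0.0)
        roi = self._roi()
        def run(cond, fid, seed):
            return sd.simulate_bold_run(cond, roi, cfg, eff,
                                        rng=np.random.default_rng(seed),
                                        pattern_rng=np.random.default_rng(99),
                                        fidelity=fid)
        task = mvlc_pattern(compute_ilc(run("task", 1.0, 1), roi=roi), roi)
        post = mvlc_pattern(compute_ilc(run("post_rest", 1.0, 2), roi=roi), roi)
        assert np.corrcoef(task, post)[0, 1] > 0.95

    def test_zero_fidelity_similarity_difference_centers_on_zero(self):
        cfg = self._config()
        eff = EffectSpec()
        roi = self._roi()
        diffs = []
        for i in range(40):
            def run(cond, fid, purpose):
                return sd.simulate_bold_run(cond, roi, cfg, eff,
                                            rng=sd._rng(7, i, purpose),
                                            pattern_rng=sd._rng(7, i, 3),
                                            fidelity=fid)
            task = mvlc_pattern(compute_ilc(run("task", 1.0, 4), roi=roi), roi)
            pre = mvlc_pattern(compute_ilc(run("pre_rest", 0.0, 5), roi=roi), roi)
            post = mvlc_pattern(compute_ilc(run("post_rest", 0.0, 6), roi=roi), roi)
            diffs.append(similarity_difference(task, pre, post).similarity_difference)
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2.5 * se

    def test_pure_noise_has_zero_mean_ilc(self):
        cfg = self._config()
        eff = EffectSpec(ar1_coef=0.0)
        means = []
        for i in range(10):
            run = sd.simulate_bold_run("pre_rest", None, cfg, eff,
                                       rng=np.random.default_rng(i))
            means.append(compute_ilc(run).mean())
        se = np.std(means) / np.sqrt(len(means))
        # ILC values are O(0.1-1); a 1e-3 floor absorbs sub-MC-resolution noise
        assert abs(np.mean(means)) < max(2.0 * se, 1e-3)

    def test_planted_fc_target_realized(self):
        cfg = CohortConfig(n_learning=4, n_control=4, grid_shape=(10, 10, 10),
                           n_volumes_rest=2000)
        eff = EffectSpec(ar1_coef=0.0)
        from engramflow.bold_features import roi_to_roi_fc
        a = np.zeros((10, 10, 10), bool); a[:3] = True
        b = np.zeros((10, 10, 10), bool); b[7:] = True
        run = sd.simulate_bold_run("pre_rest", None, cfg, eff,
                                   rng=np.random.default_rng(3),
                                   fc_latents=[(a, b, 0.4)])
        assert np.tanh(roi_to_roi_fc(run, a, b)) == pytest.approx(0.4, abs=0.07)


class TestCohortOutput:
    def test_written_files_are_deterministic(self, tmp_path):
        import hashlib
        cfg = CohortConfig(n_learning=4, n_control=4, grid_shape=(8, 8, 8),
                           n_volumes_rest=24, task_on_duration=6.0,
                           task_off_duration=6.0, n_blocks_day1=4,
                           master_seed=11)
        eff = EffectSpec(changepoint_block=3)

        def digest(out):
            cohort = sd.simulate_cohort(cfg, eff)
            written = sd.write_cohort(cohort, out, write_nifti=False)
            h = hashlib.sha256()
            for path in sorted(written):
                h.update(open(path, "rb").read())
            return h.hexdigest()

        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_masks_disjoint_and_on_grid(self):
        cfg = CohortConfig()
        masks = sd.make_roi_masks(cfg)
        total = np.zeros(cfg.grid_shape, dtype=int)
        for m in masks.values():
            assert m.shape == cfg.grid_shape
            total += m.astype(int)
        assert total.max() == 1  # no overlap
        assert masks["M1"].sum() >= 10
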