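"""End-to-end orchestration: simulate -> quantify -> score -> bold -> stats.

``run_all`` executes the full analysis on a synthetic cohort and emits a
report mirroring the study's results structure: metabolite dynamics (mixed
model), the coupling change, baseline-dependence correlations, the
Glu/GABA <-> overnight-gain battery, the connectivity-change battery, the
gray-matter battery, and the MVLC reactivation battery — each family
FDR-corrected on its own.
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import behavior as beh
from . import bold_features as bf
from . import mrs_quant as mrs
from . import stats as st
from . import synthdata as sd
from .config import RunConfig
from .errors import EngramflowError

logger = logging.getLogger(__name__)

#: default hypothesis-family battery; each test is
#: (family, x, y, controls, covariates, tail)
def default_battery() -> list[dict]:
    tests = []

    def add(family, x, y, controls=(), covariates=(), tail="two-sided"):
        tests.append({"family": family, "x": x, "y": y,
                      "controls": tuple(controls), "covariates": tuple(covariates),
                      "tail": tail})

    for span in ("imm", "30", "avg"):
        add("glu_gain", f"d_glu_{span}", "overnight_gain_pct",
            controls=[f"d_gaba_{span}"], covariates=["day1_last"])
        add("gaba_gain", f"d_gaba_{span}", "overnight_gain_pct",
            controls=[f"d_glu_{span}"], covariates=["day1_last"])
        for edge in ("putamen_R", "putamen_L", "PCC"):
            add(f"glu_fc_{edge.lower()}", f"d_glu_{span}", f"dz_overnight_{edge}",
                controls=[f"d_gaba_{span}"])
            add(f"gaba_fc_{edge.lower()}", f"d_gaba_{span}", f"dz_overnight_{edge}",
                controls=[f"d_glu_{span}"])
        add("gaba_gm_m1", f"d_gaba_{span}", "dgm_M1", controls=[f"d_glu_{span}"])
        add("glu_gm_m1", f"d_glu_{span}", "dgm_M1", controls=[f"d_gaba_{span}"])
    add("gaba_gm_pcc", "d_gaba_30", "dgm_PCC", controls=["d_glu_30"])
    add("mvlc", "d_glu_imm", "similarity_difference", controls=["d_gaba_imm"])
    add("mvlc", "d_gaba_imm", "similarity_difference", controls=["d_glu_imm"])
    add("fc_gain", "dz_overnight_putamen_R", "overnight_gain_pct",
        covariates=["day1_last"], tail="greater")
    add("gm_gain", "dgm_M1", "overnight_gain_pct",
        covariates=["day1_last"], tail="greater")
    for span in ("imm", "avg"):
        add("activation", f"d_glu_{span}", "beta_task", controls=[f"d_gaba_{span}"])
        add("activation", f"d_gaba_{span}", "beta_task", controls=[f"d_glu_{span}"])
        add("activation", f"d_glu_{span}", "total_keypresses", controls=[f"d_gaba_{span}"])
        add("activation", f"d_gaba_{span}", "total_keypresses", controls=[f"d_glu_{span}"])
    return tests


def _bold_stage(cohort: sd.SyntheticCohort, config: RunConfig,
                late_start_block: int = 4) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject BOLD features: FC edges, MVLC similarity, task beta."""
    masks = cohort.masks
    edges = ("putamen_R", "putamen_L", "PCC")
    fc_rows, mvlc_rows = [], []
    onsets, durations = sd.task_block_design(cohort.config)
    n_blocks = cohort.config.n_blocks_day1
    late_start = int(np.clip(late_start_block, 2, max(n_blocks - 2, 2)))
    seg_late = [b for b in range(n_blocks) if b + 1 >= late_start]
    # keep enough late-phase volumes for a stable pattern on small configs
    block_vols = int(round(cohort.config.task_on_duration / cohort.config.tr))
    total_late = len(seg_late) * block_vols
    drop = min(config.transition_volumes, block_vols // 2,
               max((total_late - 20) // max(len(seg_late), 1), 0))
    for rec in cohort.roster.itertuples(index=False):
        runs = cohort.bold_runs(rec.subject_id)
        z = {}
        for session in ("pre_rest", "post_rest", "day2_rest"):
            for edge in edges:
                z[(session, edge)] = bf.roi_to_roi_fc(runs[session], masks["M1"], masks[edge])
                fc_rows.append({"subject_id": rec.subject_id, "group": rec.group,
                                "session": session, "edge": f"M1-{edge}",
                                "z": z[(session, edge)]})
        for edge in edges:
            fc_rows.append({"subject_id": rec.subject_id, "group": rec.group,
                            "session": "overnight_change", "edge": f"M1-{edge}",
                            "z": bf.fc_change(z[("day2_rest", edge)], z[("pre_rest", edge)])})
            fc_rows.append({"subject_id": rec.subject_id, "group": rec.group,
                            "session": "short_term_change", "edge": f"M1-{edge}",
                            "z": bf.fc_change(z[("post_rest", edge)], z[("pre_rest", edge)])})

        if rec.group != "Learning":
            continue
        task = runs["task"]
        # the GLM beta is read out over M1 only; restrict the fit to its box
        bbox = tuple(slice(idx.min(), idx.max() + 1) for idx in np.nonzero(masks["M1"]))
        task_m1 = bf.BoldRun(data=task.data[bbox], tr=task.tr,
                             condition=task.condition, voxel_size=task.voxel_size)
        glm = bf.glm_activation(task_m1, onsets, durations, early_blocks=(0, 1, 2))
        beta_task = float(glm["beta_late"][masks["M1"][bbox]].mean())
        late = bf.late_phase_data(task, onsets, durations, seg_late,
                                  drop_transition=drop)
        m1 = masks["M1"]
        pattern_task = bf.mvlc_pattern(
            bf.compute_ilc(late, config.ilc_kernel_mm, roi=m1), m1)
        pattern_pre = bf.mvlc_pattern(
            bf.compute_ilc(runs["pre_rest"], config.ilc_kernel_mm, roi=m1), m1)
        pattern_post = bf.mvlc_pattern(
            bf.compute_ilc(runs["post_rest"], config.ilc_kernel_mm, roi=m1), m1)
        sim = bf.similarity_difference(pattern_task, pattern_pre, pattern_post)
        mvlc_rows.append({"subject_id": rec.subject_id,
                          "r_task_pre": sim.r_task_pre, "r_task_post": sim.r_task_post,
                          "similarity_difference": sim.similarity_difference,
                          "beta_task": beta_task})
    return pd.DataFrame(fc_rows), pd.DataFrame(mvlc_rows)


def build_feature_table(deltas: pd.DataFrame, gains: pd.DataFrame,
                        block_scores: pd.DataFrame, fc_edges: pd.DataFrame,
                        gm: pd.DataFrame, mvlc: pd.DataFrame,
                        roster: pd.DataFrame) -> pd.DataFrame:
    """Merge per-subject change scores into the battery's feature table."""
    feats = roster[["subject_id", "group"]].copy()
    wide = deltas.pivot_table(index="subject_id", columns="metabolite",
                              values=["immediate_change", "change_30min",
                                      "averaged_change", "baseline"])
    for met in ("Glu", "GABA"):
        key = met.lower()
        for col, span in (("immediate_change", "imm"), ("change_30min", "30"),
                          ("averaged_change", "avg"), ("baseline", "baseline")):
            if (col, met) in wide.columns:
                name = f"d_{key}_{span}" if span != "baseline" else f"baseline_{key}"
                feats = feats.merge(wide[(col, met)].rename(name),
                                    left_on="subject_id", right_index=True, how="left")
    feats = feats.merge(gains, on="subject_id", how="left")
    presses = (block_scores[block_scores["day"] == 1]
               .groupby("subject_id")["n_keypresses"].sum().rename("total_keypresses"))
    feats = feats.merge(presses, left_on="subject_id", right_index=True, how="left")
    for session in ("overnight_change", "short_term_change"):
        sub = fc_edges[fc_edges["session"] == session]
        prefix = "dz_overnight" if session == "overnight_change" else "dz_short"
        wide_fc = sub.pivot_table(index="subject_id", columns="edge", values="z")
        wide_fc.columns = [f"{prefix}_{c.split('-', 1)[1]}" for c in wide_fc.columns]
        feats = feats.merge(wide_fc, left_on="subject_id", right_index=True, how="left")
    gm_wide = gm.pivot_table(index="subject_id", columns="roi", values="gm_change")
    gm_wide.columns = [f"dgm_{c}" for c in gm_wide.columns]
    feats = feats.merge(gm_wide, left_on="subject_id", right_index=True, how="left")
    if not mvlc.empty:
        feats = feats.merge(mvlc, on="subject_id", how="left")
    return feats


def apply_iqr_exclusions(features: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Mask values beyond 3 x IQR within group (metabolites use the 3-SD rule)."""
    out = features.copy()
    if columns is None:
        columns = [c for c in out.columns
                   if c.startswith(("overnight_gain", "dz_", "dgm_", "similarity", "beta_task"))]
    for col in columns:
        for grp, sub in out.groupby("group"):
            vals = sub[col].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            if finite.sum() < 4:
                continue
            mask = np.zeros(len(vals), dtype=bool)
            mask[finite] = st.iqr_outliers(vals[finite])
            if mask.any():
                logger.info("IQR exclusion: %d value(s) of %s in %s group", mask.sum(), col, grp)
                out.loc[sub.index[mask], col] = np.nan
    return out


def run_battery(features: pd.DataFrame, battery: list[dict] | None = None,
                group: str = "Learning") -> pd.DataFrame:
    """Partial-correlation battery with BH-FDR within each hypothesis family."""
    battery = battery if battery is not None else default_battery()
    sub = features[features["group"] == group]
    rows = []
    for spec in battery:
        cols = [spec["x"], spec["y"], *spec["controls"], *spec["covariates"]]
        if any(c not in sub.columns for c in cols):
            continue
        try:
            res = st.partial_correlation(
                sub[spec["x"]], sub[spec["y"]],
                controls=[sub[c] for c in spec["controls"]],
                covariates=[sub[c] for c in spec["covariates"]],
                tail=spec["tail"], control_names=tuple(spec["controls"]),
                covariate_names=tuple(spec["covariates"]))
        except EngramflowError as e:
            logger.warning("battery test %s ~ %s failed: %s", spec["x"], spec["y"], e)
            continue
        rows.append({"family": spec["family"], "x": spec["x"], "y": spec["y"],
                     "controls": ";".join(spec["controls"]),
                     "covariates": ";".join(spec["covariates"]), "group": group,
                     "r": res.r, "df": res.df, "n": res.n, "p": res.p,
                     "tail": spec["tail"]})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = st.bh_fdr(out["p"].to_numpy(), out["family"].to_numpy())
    return out


def run_all(config: RunConfig, out_dir: str | None = None) -> dict:
    """Execute the full pipeline; returns the report (and writes it if asked).

    The report dict contains per-stage tables (DataFrames) plus a JSON-ready
    ``summary``.  Any stage failure aborts with the stage name attached.
    """
    config.validate()
    t0 = time.time()
    report: dict = {"seed": config.cohort.master_seed, "stages": {}}

    def _stage(name):
        report["stages"][name] = round(time.time() - t0, 2)
        logger.info("stage %s done at %.1fs", name, time.time() - t0)

    try:
        cohort = sd.simulate_cohort(config.cohort, config.effects)
        if out_dir:
            sd.write_cohort(cohort, out_dir, write_nifti=config.write_nifti)
        _stage("simulate")
    except Exception as e:
        raise EngramflowError(f"stage simulate failed: {e}") from e

    try:
        quant = mrs.quantify_panel(cohort.metabolites,
                                   tissue_correction=config.tissue_correction,
                                   cr_ref=config.cr_referenced)
        qc = mrs.qc_flags(quant, group_pooled=config.group_pooled_qc)
        deltas = mrs.delta_features(qc)
        _stage("quantify")
    except Exception as e:
        raise EngramflowError(f"stage quantify failed: {e}") from e

    try:
        scores = beh.score_table(cohort.behavior, strict_reset=config.strict_reset_scoring)
        segmentation = beh.segment_phases(scores[scores["day"] == 1], alpha=config.alpha)
        gains = beh.gains_table(scores)
        _stage("behavior")
    except Exception as e:
        raise EngramflowError(f"stage behavior failed: {e}") from e

    try:
        late_start = segmentation.boundary_block
        if segmentation.no_plateau:
            late_start = config.effects.changepoint_block
        fc_edges, mvlc = _bold_stage(cohort, config, late_start_block=late_start)
        _stage("bold")
    except Exception as e:
        raise EngramflowError(f"stage bold failed: {e}") from e

    try:
        features = build_feature_table(deltas, gains, scores, fc_edges,
                                       cohort.gm_volumes, mvlc, cohort.roster)
        features = apply_iqr_exclusions(features)

        lmm_rows = []
        clean = qc[~qc["excluded"]]
        for met in ("Glu", "GABA"):
            sub = clean[clean["metabolite"] == met]
            try:
                res = st.fit_time_group_lmm(sub, "conc")
                eff = res.effects.copy()
                eff.insert(0, "metabolite", met)
                lmm_rows.append(eff)
            except EngramflowError as e:
                logger.warning("LMM for %s failed: %s", met, e)
        lmm_effects = pd.concat(lmm_rows, ignore_index=True) if lmm_rows else pd.DataFrame()

        coupling = {}
        for grp in ("Learning", "Control"):
            sub = deltas[deltas["group"] == grp]
            wide_b = sub.pivot_table(index="subject_id", columns="metabolite", values="baseline")
            wide_a = sub.pivot_table(index="subject_id", columns="metabolite",
                                     values="averaged_change")
            post = wide_b + wide_a
            merged = wide_b.join(post, lsuffix="_pre", rsuffix="_post").dropna(
                subset=["Glu_pre", "GABA_pre", "Glu_post", "GABA_post"])
            try:
                coupling[grp] = st.coupling_change(
                    merged["Glu_pre"], merged["GABA_pre"],
                    merged["Glu_post"], merged["GABA_post"])
            except EngramflowError as e:
                logger.warning("coupling change for %s failed: %s", grp, e)

        base_rows = []
        for grp in ("Learning", "Control"):
            for met in ("Glu", "GABA"):
                sub = deltas[(deltas["group"] == grp) & (deltas["metabolite"] == met)].dropna(
                    subset=["baseline", "averaged_change"])
                if len(sub) < 5:
                    continue
                res = st.partial_correlation(sub["baseline"], sub["averaged_change"])
                base_rows.append({"group": grp, "metabolite": met, "r": res.r,
                                  "df": res.df, "p": res.p})
        baseline_dep = pd.DataFrame(base_rows)
        if not baseline_dep.empty:
            baseline_dep["q"] = st.bh_fdr(baseline_dep["p"].to_numpy())

        battery = run_battery(features)
        mvlc_group = None
        if not mvlc.empty:
            diffs = mvlc["similarity_difference"].dropna()
            if len(diffs) > 2:
                from scipy import stats as sps
                t, p = sps.ttest_1samp(diffs, 0.0)
                mvlc_group = {"mean": float(diffs.mean()), "t": float(t),
                              "p": float(p), "n": int(len(diffs))}
        _stage("stats")
    except EngramflowError:
        raise
    except Exception as e:
        raise EngramflowError(f"stage stats failed: {e}") from e

    sig = {}
    if not battery.empty:
        for fam, sub in battery.groupby("family"):
            sig[fam] = bool((sub["q"] < config.alpha).any())

    report.update({
        "qc": qc, "deltas": deltas, "scores": scores, "gains": gains,
        "fc_edges": fc_edges, "mvlc": mvlc, "features": features,
        "battery": battery, "lmm_effects": lmm_effects,
        "baseline_dependence": baseline_dep, "coupling": coupling,
        "segmentation": segmentation, "mvlc_group": mvlc_group,
        "significant_families": sig,
    })
    report["summary"] = _summary(report, config)
    if out_dir:
        write_report(report, config, out_dir)
    return report


def _summary(report: dict, config: RunConfig) -> dict:
    gains = report["gains"]
    seg = report["segmentation"]
    out = {
        "seed": config.cohort.master_seed,
        "n_learning": int(config.cohort.n_learning),
        "n_control": int(config.cohort.n_control),
        "qc_excluded": int(report["qc"]["excluded"].sum()),
        "mean_overnight_gain_pct": float(gains["overnight_gain_pct"].mean()),
        "sem_overnight_gain_pct": float(gains["overnight_gain_pct"].sem()),
        "phase_boundary_block": int(seg.boundary_block),
        "coupling": {g: {k: round(float(v), 6) for k, v in d.items()}
                     for g, d in report["coupling"].items()},
        "significant_families": report["significant_families"],
        "mvlc_group": report["mvlc_group"],
    }
    if not report["battery"].empty:
        key = report["battery"].query("family == 'glu_gain' and x == 'd_glu_avg'")
        if len(key):
            out["glu_avg_gain_partial_r"] = float(key["r"].iloc[0])
    return out


def write_report(report: dict, config: RunConfig, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for name in ("qc", "deltas", "scores", "gains", "fc_edges", "mvlc",
                 "features", "battery", "lmm_effects", "baseline_dependence"):
        df = report[name]
        if isinstance(df, pd.DataFrame):
            fname = {"qc": "metabolites_qc.csv", "deltas": "delta_features.csv",
                     "scores": "block_scores.csv", "gains": "overnight_gains.csv",
                     "fc_edges": "fc_edges.csv", "mvlc": "mvlc_similarity.csv",
                     "features": "features.csv", "battery": "correlation_battery.csv",
                     "lmm_effects": "lmm_effects.csv",
                     "baseline_dependence": "baseline_dependence.csv"}[name]
            df.to_csv(os.path.join(out_dir, fname), index=False, float_format="%.8g")
    seg = report["segmentation"]
    with open(os.path.join(out_dir, "phase_segmentation.json"), "w") as fh:
        json.dump({"boundary_block": seg.boundary_block, "early_blocks": list(seg.early_blocks),
                   "late_blocks": list(seg.late_blocks), "no_plateau": seg.no_plateau,
                   "method": seg.method}, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report["summary"], fh, indent=2, sort_keys=True, default=float)
    _write_markdown(report, config, os.path.join(out_dir, "report.md"))
    config.to_yaml(os.path.join(out_dir, "run_config.yaml"))


def _write_markdown(report: dict, config: RunConfig, path: str) -> None:
    s = report["summary"]
    lines = [
        "# Synthetic cohort analysis report",
        f"seed: {s['seed']}  |  n = {s['n_learning']} Learning + {s['n_control']} Control",
        "",
        "## Behavior",
        f"- learning-phase boundary: block {s['phase_boundary_block']}"
        f" (early = blocks < {s['phase_boundary_block']})",
        f"- mean overnight gain: {s['mean_overnight_gain_pct']:.2f}%"
        f" +/- {s['sem_overnight_gain_pct']:.2f}% (SEM)",
        "",
        "## Excitation/inhibition coupling",
    ]
    for grp, d in s["coupling"].items():
        lines.append(f"- {grp}: r_pre = {d['r_pre']:.3f}, r_post = {d['r_post']:.3f}, "
                     f"Z = {d['Z']:.2f}, p = {d['p']:.4f}")
    lines += ["", "## Correlation battery (q < {:.2f} families)".format(config.alpha)]
    for fam, flag in sorted(s["significant_families"].items()):
        lines.append(f"- {fam}: {'significant' if flag else 'ns'}")
    if s.get("mvlc_group"):
        m = s["mvlc_group"]
        lines += ["", "## MVLC reactivation (group level)",
                  f"- mean similarity difference {m['mean']:.4f}, "
                  f"t = {m['t']:.2f}, p = {m['p']:.3f} (n = {m['n']})"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def validate_outputs(out_dir: str) -> dict:
    """Schema/invariant checks over a pipeline output directory."""
    checks = []

    def _check(name, ok, detail=""):
        checks.append({"check": name, "pass": bool(ok), "detail": detail})

    expected = ["metabolites.csv", "behavior.csv", "gm_volumes.csv",
                "metabolites_qc.csv", "delta_features.csv", "block_scores.csv",
                "overnight_gains.csv", "fc_edges.csv", "mvlc_similarity.csv",
                "correlation_battery.csv", "report.json"]
    for fname in expected:
        path = os.path.join(out_dir, fname)
        _check(f"exists:{fname}", os.path.exists(path))
    try:
        panel = pd.read_csv(os.path.join(out_dir, "metabolites.csv"))
        sums = panel[["f_gm", "f_wm", "f_csf"]].sum(axis=1)
        _check("tissue_fractions_sum_to_1", np.allclose(sums, 1.0, atol=1e-6))
    except Exception as e:
        _check("tissue_fractions_sum_to_1", False, str(e))
    try:
        bat = pd.read_csv(os.path.join(out_dir, "correlation_battery.csv"))
        _check("battery_r_in_range", bat["r"].abs().le(1.0 + 1e-9).all())
        _check("battery_q_ge_p", (bat["q"] >= bat["p"] - 1e-12).all())
    except Exception as e:
        _check("battery_r_in_range", False, str(e))
    return {"pass": all(c["pass"] for c in checks), "checks": checks}
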