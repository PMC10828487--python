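"""Seeded synthetic two-day cohort with the planted effect structure.

The generator emulates the study conditions end-to-end: a Learning group
(n=36) and a Control group (n=21); six MRS time points (baseline, four post
scans over ~30 min, day-2 baseline); 12 practice blocks of the 4-1-3-2-4
sequence plus one day-2 test block; pre/post/day-2 resting BOLD and one task
run on a scaled-down grid; per-subject ROI gray-matter values.

Planted structure (all targets on the measured scale — the generator inverts
its own noise model so large-n sample statistics recover the stated values):

* baseline-dependent metabolite change (negative regression-to-the-mean
  slope for GABA in both groups, Glu mainly after learning);
* Glu-GABA coupling across Learning subjects rising from ``coupling_r_pre``
  at baseline to ``coupling_r_post`` over the post-learning period;
* overnight behavioral gain (mean 10.46%) whose partial correlation with the
  averaged Glu change given the GABA change is ``glu_gain_partial_r``;
* overnight M1 gray-matter change correlated with the 30-min GABA change;
* overnight M1 <-> right-putamen connectivity change correlated with the
  immediate Glu change (PCC and left-putamen edges stay null);
* post-rest BOLD whose local-correlation pattern mixes in the task pattern
  with weight ``reactivation_fidelity``.

Everything is deterministic under (config, master_seed); per-subject and
per-purpose substreams are derived from ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .behavior import TARGET_SEQUENCE, score_block
from .bold_features import BoldRun, _convolved_boxcar
from .config import METABOLITES, CohortConfig, EffectSpec
from .errors import ConfigurationError, InputError
from .mrs_quant import tissue_correction_factor

logger = logging.getLogger(__name__)

# purpose codes for per-subject random substreams
_P_METAB, _P_BEHAVIOR, _P_PATTERN, _P_TASK, _P_PRE, _P_POST, _P_DAY2, _P_GM, _P_FC = range(9)


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


# ---------------------------------------------------------------------------
# roster
# ---------------------------------------------------------------------------

def make_cohort(config: CohortConfig) -> pd.DataFrame:
    """Subject roster: id, group, and per-subject seed substream index."""
    config.validate()
    n = config.n_subjects
    ids = [f"sub-{i + 1:02d}" for i in range(n)]
    groups = ["Learning"] * config.n_learning + ["Control"] * config.n_control
    return pd.DataFrame({"subject_id": ids, "group": groups,
                         "subject_index": np.arange(n)})


# ---------------------------------------------------------------------------
# metabolites
# ---------------------------------------------------------------------------

def _post_labels(n_post: int) -> list[str]:
    return [f"post{10 * i}" for i in range(n_post)]


def _coupling_solution(effects: EffectSpec, n_post: int) -> dict:
    """Baseline correlation and innovation covariance hitting the measured-
    scale coupling targets, from the generator's own noise model."""
    out = {}
    for grp in ("Learning", "Control"):
        sB = {m: effects.baseline_sd[m] for m in ("Glu", "GABA")}
        se = {m: effects.scan_noise_sd[m] for m in ("Glu", "GABA")}
        sz = {m: effects.post_innovation_sd[m] for m in ("Glu", "GABA")}
        slope = {"GABA": effects.regression_to_mean_slope,
                 "Glu": effects.regression_to_mean_slope * (
                     1.0 if grp == "Learning" else effects.control_glu_slope_factor)}
        v_pre = {m: sB[m] ** 2 + se[m] ** 2 for m in sB}
        v_post = {m: (1 + slope[m]) ** 2 * sB[m] ** 2 + sz[m] ** 2 + se[m] ** 2 / n_post
                  for m in sB}
        denom = sB["Glu"] * sB["GABA"]
        rho_b = 0.0
        if denom > 0:
            rho_b = effects.coupling_r_pre * np.sqrt(v_pre["Glu"] * v_pre["GABA"]) / denom
            rho_b = float(np.clip(rho_b, -0.98, 0.98))
        r_post_target = effects.coupling_r_post if grp == "Learning" else effects.coupling_r_pre
        c_z = (r_post_target * np.sqrt(v_post["Glu"] * v_post["GABA"])
               - (1 + slope["Glu"]) * (1 + slope["GABA"]) * rho_b * denom)
        c_max = 0.98 * sz["Glu"] * sz["GABA"]
        if c_max > 0 and abs(c_z) > c_max:
            logger.warning("%s innovation covariance clipped (%.3f -> %.3f)", grp, c_z, c_max)
            c_z = float(np.sign(c_z) * c_max)
        elif c_max == 0:
            c_z = 0.0
        out[grp] = {"rho_b": rho_b, "c_z": c_z, "slope": slope,
                    "v_pre": v_pre, "v_post": v_post}
    return out


def delta_moments(effects: EffectSpec, group: str = "Learning",
                  n_post: int = 4) -> dict:
    """Population variances/covariance of the measured change scores.

    Used to standardize planted cross-modal effects without conditioning on
    the realized sample (which would distort sampling distributions).
    """
    sol = _coupling_solution(effects, n_post)[group]
    out = {}
    for m in ("Glu", "GABA"):
        sB = effects.baseline_sd[m]
        se = effects.scan_noise_sd[m]
        sz = effects.post_innovation_sd[m]
        s = sol["slope"][m]
        core = s ** 2 * sB ** 2 + sz ** 2
        out[m] = {"var_imm": core + 2 * se ** 2,
                  "var_30": core + 2 * se ** 2,
                  "var_avg": core + se ** 2 + se ** 2 / n_post}
    # the Glu/GABA change scores share only the baseline coupling and the
    # post-period innovation covariance, for every span (imm/30/avg)
    out["cov"] = (sol["slope"]["Glu"] * sol["slope"]["GABA"] * sol["rho_b"]
                  * effects.baseline_sd["Glu"] * effects.baseline_sd["GABA"]
                  + sol["c_z"])
    for span in ("imm", "30", "avg"):
        denom = np.sqrt(out["Glu"][f"var_{span}"] * out["GABA"][f"var_{span}"])
        out[f"rho_{span}"] = float(np.clip(out["cov"] / denom, -0.99, 0.99)) if denom > 0 else 0.0
    return out


def partial_plant_coef(target_partial_r: float, rho_xy: float) -> float:
    """Loading c on a standardized predictor x so that an outcome
    c*x + sqrt(1-c^2)*noise has partial correlation ``target_partial_r``
    with x given a second variable y, where rho_xy = corr(x, y).

    Solving partial_r = c sqrt(1-rho^2) / sqrt(1 - c^2 rho^2) for c.  By
    construction the outcome's partial correlation with y given x is zero.
    """
    t, rho = target_partial_r, rho_xy
    c2 = t * t / max(1.0 - rho * rho + t * t * rho * rho, 1e-9)
    return float(np.sign(t) * np.sqrt(min(c2, 1.0)))


def simulate_metabolites(roster: pd.DataFrame, effects: EffectSpec,
                         config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long metabolite panel and the per-subject latent table.

    The panel holds raw water-scaled ratios (``conc_raw``) together with the
    voxel tissue fractions and QC metrics, exactly as the quantification
    stage expects them; latents carry the clean measured change scores the
    other planted effects condition on.
    """
    if roster.empty:
        raise InputError("empty roster")
    effects.validate(config.n_blocks_day1)
    rng = _rng(config.master_seed, 999, _P_METAB)
    n = len(roster)
    n_post = config.n_post_scans
    post_labels = _post_labels(n_post)
    sol = _coupling_solution(effects, n_post)
    is_learning = (roster["group"] == "Learning").to_numpy()

    mu = effects.baseline_mean
    sB = effects.baseline_sd
    se = effects.scan_noise_sd
    sz = effects.post_innovation_sd

    # true baselines; Glu-GABA correlated, others independent
    B = {}
    z_glu = rng.standard_normal(n)
    z_shared = rng.standard_normal(n)
    rho_b = np.where(is_learning, sol["Learning"]["rho_b"], sol["Control"]["rho_b"])
    z_gaba = rho_b * z_glu + np.sqrt(1 - rho_b ** 2) * z_shared
    B["Glu"] = mu["Glu"] + sB["Glu"] * z_glu
    B["GABA"] = mu["GABA"] + sB["GABA"] * z_gaba
    for m in ("NAA", "Gln", "Cr"):
        B[m] = mu[m] + sB[m] * rng.standard_normal(n)

    # post-period plateau levels
    P = {}
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    for grp, grp_mask in (("Learning", is_learning), ("Control", ~is_learning)):
        s = sol[grp]
        rho_z = 0.0
        if sz["Glu"] * sz["GABA"] > 0:
            rho_z = np.clip(s["c_z"] / (sz["Glu"] * sz["GABA"]), -0.99, 0.99)
        zeta_glu = sz["Glu"] * e1
        zeta_gaba = sz["GABA"] * (rho_z * e1 + np.sqrt(1 - rho_z ** 2) * e2)
        for m, zeta in (("Glu", zeta_glu), ("GABA", zeta_gaba)):
            vals = mu[m] + (1 + s["slope"][m]) * (B[m] - mu[m]) + zeta
            P.setdefault(m, np.zeros(n))
            P[m][grp_mask] = vals[grp_mask]
    for m in ("NAA", "Gln", "Cr"):
        P[m] = B[m] + sz[m] * rng.standard_normal(n)

    # tissue fractions: per-subject voxel composition, stable across sessions
    f_gm = np.clip(rng.normal(0.55, 0.04, n), 0.40, 0.70)
    f_csf = np.clip(rng.normal(0.08, 0.02, n), 0.02, 0.20)
    f_wm = 1.0 - f_gm - f_csf
    factors = np.array([tissue_correction_factor(g, w, c)
                        for g, w, c in zip(f_gm, f_wm, f_csf)])

    crlb_base = {"Glu": 3.0, "GABA": 8.0, "NAA": 2.0, "Gln": 12.0, "Cr": 2.0}
    rows = []
    clean = {m: {} for m in METABOLITES}
    timepoints = ["pre", *post_labels, "day2"]
    for m in METABOLITES:
        meas = {"pre": B[m] + se[m] * rng.standard_normal(n)}
        for lbl in post_labels:
            meas[lbl] = P[m] + se[m] * rng.standard_normal(n)
        drift = 0.5 * sz[m] * rng.standard_normal(n)
        meas["day2"] = B[m] + drift + se[m] * rng.standard_normal(n)
        clean[m] = meas
        for tp in timepoints:
            value = meas[tp].copy()
            crlb = np.abs(crlb_base[m] + 0.3 * crlb_base[m] * rng.standard_normal(n))
            snr = np.clip(rng.normal(45.0, 4.0, n), 31.0, None)
            lw = np.clip(rng.normal(9.5, 1.2, n), 5.0, 14.9)
            # QC contamination: corrupted scans that the QC stage must catch
            bad = rng.random(n) < effects.qc_contamination_rate
            kind = rng.integers(0, 3, n)
            pooled_sd = np.sqrt(sB[m] ** 2 + se[m] ** 2)
            lw = np.where(bad & (kind == 0), rng.uniform(15.5, 22.0, n), lw)
            snr = np.where(bad & (kind == 1), rng.uniform(15.0, 30.0, n), snr)
            shift = np.sign(rng.standard_normal(n)) * rng.uniform(4.5, 6.0, n) * pooled_sd
            value = np.where(bad & (kind == 2), value + shift, value)
            for i in range(n):
                rows.append((roster["subject_id"].iat[i], roster["group"].iat[i],
                             tp, m, value[i] / factors[i], crlb[i], snr[i], lw[i],
                             f_gm[i], f_wm[i], f_csf[i]))
    panel = pd.DataFrame(rows, columns=[
        "subject_id", "group", "timepoint", "metabolite", "conc_raw",
        "crlb_pct", "snr", "linewidth_hz", "f_gm", "f_wm", "f_csf"])

    # latent table: clean measured change scores + standardized versions
    lat = {"subject_id": roster["subject_id"].to_numpy(),
           "group": roster["group"].to_numpy()}
    last_post = post_labels[-1]
    for m in ("Glu", "GABA"):
        avg_post = np.mean([clean[m][lbl] for lbl in post_labels], axis=0)
        lat[f"d_{m.lower()}_imm"] = clean[m][post_labels[0]] - clean[m]["pre"]
        lat[f"d_{m.lower()}_30"] = clean[m][last_post] - clean[m]["pre"]
        lat[f"d_{m.lower()}_avg"] = avg_post - clean[m]["pre"]
    latents = pd.DataFrame(lat)

    # population-standardized change scores: planted cross-modal effects load
    # on these with coefficients solved so the PARTIAL correlation given the
    # other metabolite's change equals the stated target (see
    # partial_plant_coef) — matching how the battery later measures them
    mom = delta_moments(effects, "Learning", n_post)
    for met in ("Glu", "GABA"):
        for span in ("imm", "30", "avg"):
            sd = max(np.sqrt(mom[met][f"var_{span}"]), 1e-12)
            latents[f"z_{met.lower()}_{span}"] = latents[f"d_{met.lower()}_{span}"] / sd
    return panel, latents


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _emit_stream(n_correct: int, rng: np.random.Generator,
                 error_rate: float) -> str:
    """Key-press stream scoring exactly ``n_correct`` under score_block."""
    target = "".join(map(str, TARGET_SEQUENCE))
    for _ in range(30):
        parts = [target] * n_correct
        n_err = rng.poisson(error_rate * max(len(target) * n_correct, 1))
        stream = list("".join(parts))
        for _ in range(n_err):
            pos = int(rng.integers(0, (len(stream) // len(target)) + 1)) * len(target)
            stream.insert(min(pos, len(stream)), str(rng.integers(1, 5)))
        # occasionally a trailing incomplete attempt
        tail = target[: int(rng.integers(0, len(target)))]
        candidate = "".join(stream) + tail
        got, _ = score_block(candidate)
        if got == n_correct:
            return candidate
    return target * n_correct  # always scores exactly n_correct


def simulate_behavior(roster: pd.DataFrame, effects: EffectSpec,
                      config: CohortConfig,
                      latents: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Key-press streams for the Learning group plus updated latents.

    Day-1 counts follow a saturating learning curve reaching its plateau at
    ``changepoint_block`` (the first block with no further group-level
    change); the day-2 test count applies the planted overnight gain, whose
    partial correlation with the subject's averaged Glu change given the
    GABA change equals ``glu_gain_partial_r`` and which decreases with day-1
    final performance.  Streams round-trip through ``behavior.score_block``.
    """
    effects.validate(config.n_blocks_day1)
    c = effects.changepoint_block
    n_blocks = config.n_blocks_day1
    learners = roster[roster["group"] == "Learning"]
    lat = latents.set_index("subject_id")
    rows = []
    planted = []
    mom = delta_moments(effects, "Learning", config.n_post_scans)
    c1 = partial_plant_coef(effects.glu_gain_partial_r, mom["rho_avg"])
    lam = effects.day1_perf_gain_r
    resid_sd = np.sqrt(max(1.0 - c1 ** 2 - lam ** 2, 0.0))
    day1_pop_sd = np.sqrt(effects.asymptote_sd ** 2 + effects.within_block_sd ** 2 + 1 / 12)

    for rec in learners.itertuples(index=False):
        srng = _rng(config.master_seed, rec.subject_index, _P_BEHAVIOR)
        A = srng.normal(effects.asymptote_mean, effects.asymptote_sd)
        S = srng.normal(effects.start_mean, effects.start_sd)
        S = min(S, A - 1.0)
        counts = []
        for b in range(1, n_blocks + 1):
            if c <= 2 or b >= c - 1:
                m_b = A
            else:
                m_b = S + (A - S) * (b - 1) / (c - 2)
            counts.append(max(1, int(round(m_b + srng.normal(0.0, effects.within_block_sd)))))
        day1_last = counts[-1]
        z_day1 = (day1_last - effects.asymptote_mean) / day1_pop_sd
        z_glu = float(lat.loc[rec.subject_id, "z_glu_avg"])
        gain = (effects.overnight_gain_mean + effects.overnight_gain_sd
                * (c1 * z_glu + lam * z_day1 + resid_sd * srng.standard_normal()))
        gain = max(gain, -60.0)
        day2 = max(0, int(round(day1_last * (1.0 + gain / 100.0))))
        for b, cnt in enumerate(counts, start=1):
            rows.append({"subject_id": rec.subject_id, "day": 1, "block": b,
                         "keystream": _emit_stream(cnt, srng, effects.keypress_error_rate),
                         "n_correct": cnt})
        rows.append({"subject_id": rec.subject_id, "day": 2, "block": 1,
                     "keystream": _emit_stream(day2, srng, effects.keypress_error_rate),
                     "n_correct": day2})
        delta = day2 - day1_last
        planted.append({"subject_id": rec.subject_id, "gain_planted_pct": gain,
                        "day1_last": day1_last, "day2_test": day2,
                        "partition": "improved" if delta > 0 else
                                     ("declined" if delta < 0 else "level")})
    behavior = pd.DataFrame(rows)
    latents = latents.merge(pd.DataFrame(planted), on="subject_id", how="left")
    return behavior, latents


# ---------------------------------------------------------------------------
# gray matter
# ---------------------------------------------------------------------------

def simulate_gm_volumes(roster: pd.DataFrame, effects: EffectSpec,
                        config: CohortConfig, latents: pd.DataFrame) -> pd.DataFrame:
    """Day-1/day-2 modulated ROI gray-matter values (M1 and PCC).

    The overnight M1 change correlates with the subject's measured 30-min
    GABA change at ``gaba_gm_r`` in the Learning group; the PCC change and
    the Control group are planted null.
    """
    rng = _rng(config.master_seed, 999, _P_GM)
    lat = latents.set_index("subject_id")
    mom = delta_moments(effects, "Learning", config.n_post_scans)
    c1 = partial_plant_coef(effects.gaba_gm_r, mom["rho_30"])
    rows = []
    for rec in roster.itertuples(index=False):
        z30 = float(lat.loc[rec.subject_id, "z_gaba_30"])
        for roi in ("M1", "PCC"):
            day1 = rng.normal(effects.gm_day1_mean, effects.gm_day1_sd)
            noise = rng.standard_normal()
            if roi == "M1" and rec.group == "Learning":
                change = effects.gm_change_sd * (c1 * z30 + np.sqrt(1 - c1 ** 2) * noise)
            else:
                change = effects.gm_change_sd * noise
            rows.append({"subject_id": rec.subject_id, "group": rec.group, "roi": roi,
                         "gm_day1": day1, "gm_day2": day1 + change, "gm_change": change})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def make_roi_masks(config: CohortConfig) -> dict[str, np.ndarray]:
    """Disjoint cuboid ROI masks on the simulation grid (M1, putamen L/R, PCC)."""
    nx, ny, nz = config.grid_shape
    masks = {}

    def _cube(x0, x1, y0, y1, z0, z1):
        m = np.zeros(config.grid_shape, dtype=bool)
        m[max(x0, 0):min(x1, nx), max(y0, 0):min(y1, ny), max(z0, 0):min(z1, nz)] = True
        return m

    cx, cy, cz = nx // 2, ny // 2, nz // 2
    masks["M1"] = _cube(cx - 2, cx + 2, cy - 2, cy + 2, cz - 2, cz + 2)
    masks["putamen_R"] = _cube(nx - 5, nx - 2, 1, 4, cz - 2, cz + 1)
    masks["putamen_L"] = _cube(1, 4, 1, 4, cz - 2, cz + 1)
    masks["PCC"] = _cube(cx - 2, cx + 1, ny - 5, ny - 2, cz - 2, cz + 1)
    for name, m in masks.items():
        if not m.any():
            raise ConfigurationError(f"grid too small for ROI {name}")
    return masks


def _pattern_clusters(roi: np.ndarray) -> list[np.ndarray]:
    """Partition ROI voxels into 2x2x2 neighborhoods (flat-index arrays)."""
    coords = np.argwhere(roi)
    keys = coords // 2
    order = np.lexsort(keys.T[::-1])
    flat = np.ravel_multi_index(coords.T, roi.shape)
    clusters = []
    prev = None
    for i in order:
        k = tuple(keys[i])
        if k != prev:
            clusters.append([])
            prev = k
        clusters[-1].append(flat[i])
    return [np.asarray(c) for c in clusters]


def _solve_shared_weight(r: float, va: float, vb: float) -> float:
    """w such that adding w*g to both ROI means yields correlation ~r."""
    x = abs(r) / max(1.0 - abs(r), 1e-6) * np.sqrt(max(va * vb, 1e-12))
    for _ in range(40):
        x = abs(r) * np.sqrt((x + va) * (x + vb))
    return float(np.sqrt(x))


def simulate_bold_run(condition: str, roi: np.ndarray | None, config: CohortConfig,
                      effects: EffectSpec, *, rng: np.random.Generator,
                      pattern_rng: np.random.Generator | None = None,
                      fidelity: float = 0.0, n_volumes: int | None = None,
                      fc_latents=None, activation=None) -> BoldRun:
    """One synthetic 4D BOLD run.

    Voxel time series are AR(1) noise plus shared latent signals assigned to
    2x2x2 neighborhoods of the pattern ROI, so the ILC map over the ROI has
    a reproducible spatial pattern governed by ``pattern_rng``: latent
    strengths for the task pattern are drawn from ``pattern_rng`` and mixed
    into this run with weight ``fidelity`` (variance-share mixing); the
    complementary share uses run-specific independent strengths.  Mask-
    external voxels are pure noise unless touched by ``fc_latents`` — a list
    of ``(mask_a, mask_b, r_target)`` tuples planting ROI-to-ROI
    connectivity via a shared global signal — or by ``activation``, an
    ``(onsets, durations, amplitude, mask)`` HRF-convolved task response.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise InputError(f"fidelity must lie in [0, 1], got {fidelity}")
    shape = tuple(config.grid_shape)
    if roi is not None and (roi.shape != shape or not roi.any()):
        raise InputError("pattern ROI must be a nonempty mask on the grid")
    T = int(n_volumes if n_volumes is not None else config.n_volumes_rest)

    phi = effects.ar1_coef
    innov_sd = effects.bold_noise_sd * np.sqrt(max(1.0 - phi ** 2, 1e-12))
    burn = 20 if phi > 0 else 0
    white = rng.normal(0.0, innov_sd if phi > 0 else effects.bold_noise_sd,
                       size=shape + (T + burn,)).astype(np.float32)
    if phi > 0:
        noise = lfilter([1.0], [1.0, -phi], white, axis=-1)[..., burn:].astype(np.float32)
    else:
        noise = white
    data = noise
    flat = data.reshape(-1, T)

    if roi is not None:
        clusters = _pattern_clusters(roi)
        K = len(clusters)
        if pattern_rng is None:
            raise InputError("pattern_rng is required when a pattern ROI is given")
        a_task = effects.latent_strength * (0.5 + pattern_rng.uniform(0.0, 1.0, K))
        a_ind = effects.latent_strength * (0.5 + rng.uniform(0.0, 1.0, K))
        a_run = np.sqrt(fidelity * a_task ** 2 + (1.0 - fidelity) * a_ind ** 2)
        for k, vox in enumerate(clusters):
            latent = rng.standard_normal(T).astype(np.float32)
            flat[vox] += a_run[k] * latent

    if fc_latents:
        for mask_a, mask_b, r_target in fc_latents:
            if abs(r_target) < 1e-6:
                continue
            va = float(np.var(data[mask_a.astype(bool)].mean(axis=0)))
            vb = float(np.var(data[mask_b.astype(bool)].mean(axis=0)))
            w = _solve_shared_weight(r_target, va, vb)
            g = rng.standard_normal(T).astype(np.float32)
            data[mask_a.astype(bool)] += w * g
            data[mask_b.astype(bool)] += np.sign(r_target) * w * g

    if activation is not None:
        onsets, durations, amplitude, mask = activation
        reg = _convolved_boxcar(onsets, durations, T, config.tr).astype(np.float32)
        data[mask.astype(bool)] += amplitude * reg

    return BoldRun(data=data, tr=config.tr, condition=condition,
                   voxel_size=config.voxel_size)


def task_block_design(config: CohortConfig) -> tuple[list[float], list[float]]:
    """Onsets and durations (s) of the practice blocks in the task run."""
    onsets, durations = [], []
    t = 0.0
    for _ in range(config.n_blocks_day1):
        onsets.append(t)
        durations.append(config.task_on_duration)
        t += config.task_on_duration + config.task_off_duration
    return onsets, durations


def simulate_subject_bold(subject_index: int, group: str, config: CohortConfig,
                          effects: EffectSpec, masks: dict[str, np.ndarray],
                          fc_targets: dict[str, dict[str, float]] | None = None,
                          fidelity: float | None = None) -> dict[str, BoldRun]:
    """All four runs for one subject (task only for Learning subjects).

    ``fc_targets`` maps session -> {edge: r}; ``fidelity`` overrides the
    cohort-level reactivation fidelity for the post-rest run.
    """
    seed = config.master_seed
    pattern_rng = _rng(seed, subject_index, _P_PATTERN)
    fid = effects.reactivation_fidelity if fidelity is None else fidelity
    fc_targets = fc_targets or {}

    def _edges(session):
        t = fc_targets.get(session, {})
        return [(masks["M1"], masks["putamen_R"], t.get("putamen_R", 0.0)),
                (masks["M1"], masks["putamen_L"], t.get("putamen_L", 0.0)),
                (masks["M1"], masks["PCC"], t.get("PCC", 0.0))]

    runs = {}
    specs = [("pre_rest", _P_PRE, 0.0), ("post_rest", _P_POST, fid),
             ("day2_rest", _P_DAY2, 0.0)]
    for condition, purpose, f in specs:
        # fresh pattern_rng clone so every run sees the same task strengths
        runs[condition] = simulate_bold_run(
            condition, masks["M1"], config, effects,
            rng=_rng(seed, subject_index, purpose),
            pattern_rng=_rng(seed, subject_index, _P_PATTERN), fidelity=f,
            fc_latents=_edges(condition))
    if group == "Learning":
        onsets, durations = task_block_design(config)
        amp_rng = _rng(seed, subject_index, _P_TASK)
        amp = effects.bold_noise_sd * max(
            amp_rng.normal(effects.activation_amplitude_mean,
                           effects.activation_amplitude_sd), 0.1)
        runs["task"] = simulate_bold_run(
            "task", masks["M1"], config, effects, rng=amp_rng,
            pattern_rng=_rng(seed, subject_index, _P_PATTERN), fidelity=1.0,
            n_volumes=config.n_volumes_task,
            fc_latents=_edges("task"),
            activation=(onsets, durations, amp, masks["M1"]))
    return runs


def plant_fc_targets(roster: pd.DataFrame, effects: EffectSpec,
                     config: CohortConfig, latents: pd.DataFrame) -> pd.DataFrame:
    """Per-subject session-level connectivity targets (Fisher-z scale).

    The M1 <-> right-putamen overnight change correlates with the immediate
    Glu change; the target correlation is pre-inflated for the finite-scan
    attenuation of measured Fisher-z values so the *measured* association
    matches ``fc_glu_r``.  PCC targets drift without planted change; the
    left putamen carries no shared signal.
    """
    rng = _rng(config.master_seed, 999, _P_FC)
    n_eff = max(config.n_volumes_rest - 3, 5)
    meas_sd = np.sqrt(2.0 / n_eff)  # sd of a measured overnight dz under H0
    atten = effects.fc_change_sd / np.sqrt(effects.fc_change_sd ** 2 + meas_sd ** 2)
    r_eff = float(np.clip(effects.fc_glu_r / max(atten, 1e-6), -0.95, 0.95))
    mom = delta_moments(effects, "Learning", config.n_post_scans)
    c1 = partial_plant_coef(r_eff, mom["rho_imm"])
    lat = latents.set_index("subject_id")
    rows = []
    for rec in roster.itertuples(index=False):
        z_pre = np.arctanh(np.clip(rng.normal(effects.fc_base_mean, effects.fc_base_sd),
                                   -0.8, 0.8))
        z_post = z_pre + rng.normal(0.0, effects.fc_session_jitter_sd)
        noise = rng.standard_normal()
        if rec.group == "Learning" and abs(effects.fc_glu_r) > 0:
            z_imm = float(lat.loc[rec.subject_id, "z_glu_imm"])
            dz = effects.fc_change_sd * (c1 * z_imm + np.sqrt(1 - c1 ** 2) * noise)
        else:
            dz = effects.fc_change_sd * noise
        z_pcc_pre = np.arctanh(np.clip(rng.normal(effects.fc_pcc_mean, effects.fc_pcc_sd),
                                       -0.8, 0.8))
        rows.append({"subject_id": rec.subject_id,
                     "pre_putamen_R": float(np.tanh(z_pre)),
                     "post_putamen_R": float(np.tanh(z_post)),
                     "day2_putamen_R": float(np.tanh(z_pre + dz)),
                     "pre_PCC": float(np.tanh(z_pcc_pre)),
                     "post_PCC": float(np.tanh(z_pcc_pre + rng.normal(0, effects.fc_session_jitter_sd))),
                     "day2_PCC": float(np.tanh(z_pcc_pre + rng.normal(0, effects.fc_session_jitter_sd))),
                     "dz_planted_putamen_R": float(dz)})
    return latents.merge(pd.DataFrame(rows), on="subject_id", how="left")


# ---------------------------------------------------------------------------
# cohort orchestration and file output
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: CohortConfig
    effects: EffectSpec
    roster: pd.DataFrame
    metabolites: pd.DataFrame
    behavior: pd.DataFrame
    gm_volumes: pd.DataFrame
    latents: pd.DataFrame = field(repr=False, default=None)
    masks: dict = field(repr=False, default=None)

    def fc_targets_for(self, subject_id: str) -> dict[str, dict[str, float]]:
        row = self.latents.set_index("subject_id").loc[subject_id]
        return {session: {"putamen_R": float(row[f"{session.split('_')[0]}_putamen_R"]),
                          "PCC": float(row[f"{session.split('_')[0]}_PCC"])}
                for session in ("pre_rest", "post_rest", "day2_rest")}

    def bold_runs(self, subject_id: str) -> dict[str, BoldRun]:
        rec = self.roster.set_index("subject_id").loc[subject_id]
        return simulate_subject_bold(int(rec["subject_index"]), rec["group"],
                                     self.config, self.effects, self.masks,
                                     fc_targets=self.fc_targets_for(subject_id),
                                     fidelity=self._subject_fidelity(subject_id))

    def _subject_fidelity(self, subject_id: str) -> float:
        row = self.latents.set_index("subject_id").loc[subject_id]
        base = self.effects.reactivation_fidelity
        slope = self.effects.fidelity_glu_slope
        z = float(row["z_glu_imm"]) if np.isfinite(row["z_glu_imm"]) else 0.0
        return float(np.clip(base + slope * z, 0.0, 1.0))


def simulate_cohort(config: CohortConfig, effects: EffectSpec | None = None) -> SyntheticCohort:
    """Full synthetic cohort (tables in memory; BOLD runs generated on demand)."""
    effects = effects if effects is not None else EffectSpec()
    roster = make_cohort(config)
    panel, latents = simulate_metabolites(roster, effects, config)
    behavior, latents = simulate_behavior(roster, effects, config, latents)
    gm = simulate_gm_volumes(roster, effects, config, latents)
    latents = plant_fc_targets(roster, effects, config, latents)
    masks = make_roi_masks(config)
    return SyntheticCohort(config=config, effects=effects, roster=roster,
                           metabolites=panel, behavior=behavior, gm_volumes=gm,
                           latents=latents, masks=masks)


def write_cohort(cohort: SyntheticCohort, out_dir, *, write_nifti: bool = True) -> list[str]:
    """Write the cohort to standard files; returns the paths written."""
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    written = []

    def _csv(df, name):
        path = os.path.join(out_dir, name)
        # full precision so invariants (e.g. tissue fractions summing to 1)
        # survive the round-trip through text
        df.to_csv(path, index=False, float_format="%.12g")
        written.append(path)

    _csv(cohort.metabolites, "metabolites.csv")
    _csv(cohort.behavior, "behavior.csv")
    _csv(cohort.gm_volumes, "gm_volumes.csv")
    if write_nifti:
        aff = np.diag([cohort.config.voxel_size] * 3 + [1.0])
        for name, mask in cohort.masks.items():
            path = os.path.join(out_dir, f"roi_{name}.nii.gz")
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), path)
            written.append(path)
        for sid in cohort.roster["subject_id"]:
            for condition, run in cohort.bold_runs(sid).items():
                path = os.path.join(out_dir, f"{sid}_{condition}.nii.gz")
                img = nib.Nifti1Image(run.data.astype(np.float32), aff)
                img.header.set_zooms((cohort.config.voxel_size,) * 3 + (cohort.config.tr,))
                nib.save(img, path)
                written.append(path)
    return written
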