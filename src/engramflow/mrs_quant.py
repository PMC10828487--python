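"""Tissue-corrected MRS quantification, quality control, and change scores.

Water-scaled metabolite estimates are converted to absolute (mM-scale)
concentrations from the voxel's gray-matter / white-matter / CSF composition,
assuming water concentrations of 43.3 M (GM), 35.88 M (WM) and 5.556 M (CSF),
no metabolites in CSF, a single T2 regime for GM and WM, and no T1 correction
(long-TR acquisition).  The unique correction factor consistent with these
assumptions is

    factor = (f_gm * 43.3 + f_wm * 35.88 + f_csf * 5.556) / (1 - f_csf)

Quality control excludes measurements whose concentration lies more than
3 SD from the mean over all time-point measurements of that metabolite
(within group by default), whose water linewidth exceeds 15 Hz FWHM, or
whose SNR is <= 30.  CRLB is carried through the audit table but is not an
exclusion criterion.  Change scores per subject and metabolite are the
immediate change (post0 - pre), the 30-min change (post30 - pre), the
averaged change (mean of unflagged post scans - pre), and the day-2 level.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import POST_TIMEPOINTS, WATER_CSF, WATER_GM, WATER_WM
from .errors import DegenerateVoxelError, InputError

logger = logging.getLogger(__name__)

LINEWIDTH_MAX_HZ = 15.0
SNR_MIN = 30.0
SD_RULE = 3.0


def tissue_correction_factor(f_gm: float, f_wm: float, f_csf: float) -> float:
    """Multiplicative water-scaling factor for a voxel's tissue composition.

    Monotone increasing in ``f_gm`` at fixed ``f_csf`` (GM water > WM water).
    Raises :class:`DegenerateVoxelError` for a (near-)pure-CSF voxel.
    """
    fractions = np.asarray([f_gm, f_wm, f_csf], dtype=float)
    if np.any(fractions < -1e-9):
        raise InputError(f"tissue fractions must be >= 0, got {fractions.tolist()}")
    if abs(fractions.sum() - 1.0) > 1e-6:
        raise InputError(f"tissue fractions must sum to 1, got sum={fractions.sum()!r}")
    if f_csf >= 1.0 - 1e-9:
        raise DegenerateVoxelError("voxel is (nearly) pure CSF; correction undefined")
    water = f_gm * WATER_GM + f_wm * WATER_WM + f_csf * WATER_CSF
    return water / (1.0 - f_csf)


def correct_concentration(raw: float, f_gm: float, f_wm: float, f_csf: float) -> float:
    """Tissue-corrected concentration: ``raw`` (water-scaled ratio) x factor."""
    return raw * tissue_correction_factor(f_gm, f_wm, f_csf)


def cr_referenced(metabolite_value: float, cr_value: float) -> float:
    """Creatine-referenced (dimensionless) measure: metabolite / Cr."""
    if cr_value <= 0:
        raise InputError(f"Cr reference must be > 0, got {cr_value}")
    return metabolite_value / cr_value


def quantify_panel(panel: pd.DataFrame, *, tissue_correction: bool = True,
                   cr_ref: bool = False) -> pd.DataFrame:
    """Add a ``conc`` column of analysis-ready concentrations to a long panel.

    ``panel`` follows the metabolites.csv schema (subject_id, group,
    timepoint, metabolite, conc_raw, crlb_pct, snr, linewidth_hz, f_gm,
    f_wm, f_csf).  With ``cr_ref`` the (corrected) concentration is divided
    by the same scan's Cr value; Cr rows keep their corrected value.
    """
    required = {"subject_id", "timepoint", "metabolite", "conc_raw",
                "f_gm", "f_wm", "f_csf"}
    missing = required - set(panel.columns)
    if missing:
        raise InputError(f"panel is missing columns: {sorted(missing)}")
    out = panel.copy()
    if tissue_correction:
        factors = np.array([
            tissue_correction_factor(g, w, c)
            for g, w, c in zip(out["f_gm"], out["f_wm"], out["f_csf"])
        ])
        out["conc"] = out["conc_raw"] * factors
    else:
        out["conc"] = out["conc_raw"].astype(float)
    if cr_ref:
        cr = (out[out["metabolite"] == "Cr"]
              .set_index(["subject_id", "timepoint"])["conc"])
        if (cr <= 0).any():
            raise InputError("non-positive Cr reference value in panel")
        idx = pd.MultiIndex.from_frame(out[["subject_id", "timepoint"]])
        ref = cr.reindex(idx).to_numpy()
        non_cr = (out["metabolite"] != "Cr").to_numpy()
        out.loc[non_cr, "conc"] = out.loc[non_cr, "conc"].to_numpy() / ref[non_cr]
    return out


def qc_flags(panel: pd.DataFrame, *, group_pooled: bool = False,
             value_col: str = "conc") -> pd.DataFrame:
    """Per-measurement exclusion flags with reasons (audit table).

    Returns ``panel`` with boolean columns ``flag_sd``, ``flag_linewidth``,
    ``flag_snr``, ``excluded`` and a semicolon-joined ``qc_reason``.  The
    3-SD rule pools all time-point measurements of a metabolite within group
    (across groups when ``group_pooled``); with fewer than 3 values the rule
    is skipped with a warning.  Boundary conventions: linewidth exactly 15 Hz
    is kept, SNR exactly 30 is excluded.
    """
    if panel.empty:
        raise InputError("empty metabolite panel")
    out = panel.copy()
    out["flag_linewidth"] = out["linewidth_hz"] > LINEWIDTH_MAX_HZ
    out["flag_snr"] = out["snr"] <= SNR_MIN
    out["flag_sd"] = False

    keys = ["metabolite"] if group_pooled or "group" not in out.columns else ["group", "metabolite"]
    for key, sub in out.groupby(keys, sort=False):
        vals = sub[value_col].to_numpy(dtype=float)
        if len(vals) < 3:
            logger.warning("3-SD rule skipped for %s: only %d values", key, len(vals))
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd > 0:
            out.loc[sub.index, "flag_sd"] = np.abs(vals - mu) > SD_RULE * sd
    out["excluded"] = out[["flag_sd", "flag_linewidth", "flag_snr"]].any(axis=1)

    parts = [np.where(out["flag_sd"], "3sd", ""),
             np.where(out["flag_linewidth"], "linewidth>15Hz", ""),
             np.where(out["flag_snr"], "snr<=30", "")]
    joined = [";".join(p for p in triple if p) for triple in zip(*parts)]
    out["qc_reason"] = joined
    return out


def delta_features(qc_panel: pd.DataFrame, *, value_col: str = "conc") -> pd.DataFrame:
    """Per subject x metabolite change scores from an audited panel.

    Uses only unflagged measurements.  A subject/metabolite without a usable
    baseline (or without any usable post scan) is dropped with a log entry.
    Columns: immediate_change, change_30min, averaged_change, overnight_level;
    individual deltas are NaN when their defining scan was excluded, while
    averaged_change uses whatever unflagged post scans remain.
    """
    usable = qc_panel[~qc_panel["excluded"]]
    wide = usable.pivot_table(index=["subject_id", "group", "metabolite"],
                              columns="timepoint", values=value_col, aggfunc="first")
    post_cols = [c for c in wide.columns if c in POST_TIMEPOINTS]
    for col in ("pre", "post0", "post30", "day2"):
        if col not in wide.columns:
            wide[col] = np.nan

    no_pre = wide["pre"].isna()
    no_post = wide[post_cols].isna().all(axis=1) if post_cols else pd.Series(True, wide.index)
    for sid, _, met in wide.index[no_pre]:
        logger.info("subject %s %s: baseline excluded/missing; dropped", sid, met)
    for sid, _, met in wide.index[~no_pre & no_post]:
        logger.info("subject %s %s: no usable post scan; dropped", sid, met)
    wide = wide[~no_pre & ~no_post]

    out = pd.DataFrame({
        "baseline": wide["pre"],
        "immediate_change": wide["post0"] - wide["pre"],
        "change_30min": wide["post30"] - wide["pre"],
        "averaged_change": wide[post_cols].mean(axis=1) - wide["pre"],
        "overnight_level": wide["day2"],
    }).reset_index()
    return out[["subject_id", "group", "metabolite", "baseline", "immediate_change",
                "change_30min", "averaged_change", "overnight_level"]]
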