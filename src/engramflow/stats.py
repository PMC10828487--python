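"""The statistical battery behind the consolidation analyses.

Implements the repeated-measures mixed-model contract
(``dv ~ Time*Group + (Time | ID)``), the excitation/inhibition coupling-change
test, residual-based partial correlations with covariate adjustment and
one- or two-tailed p-values, Fisher/Steiger comparisons of correlation
coefficients, Benjamini-Hochberg FDR within hypothesis families, and the
3 x IQR outlier rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    n: int
    df: int
    p: float
    tail: str
    controls: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    q: float | None = None
    stat: float = field(default=np.nan)


def _as_2d(arrs) -> np.ndarray:
    if arrs is None or len(arrs) == 0:
        return np.empty((0, 0))
    return np.column_stack([np.asarray(a, dtype=float) for a in arrs])


def partial_correlation(x, y, controls=None, covariates=None,
                        tail: str = "two-sided",
                        control_names: tuple[str, ...] = (),
                        covariate_names: tuple[str, ...] = ()) -> CorrelationResult:
    """Partial Pearson correlation of x and y given controls and covariates.

    Both sets of conditioning variables are regressed out of x and y; the
    distinction is purely book-keeping (controls are competing metabolites,
    covariates are nuisance terms such as day-1 performance).  Degrees of
    freedom are n - 2 - (number of conditioning variables).  ``tail`` is
    ``"two-sided"``, ``"greater"`` or ``"less"`` (one-tailed tests are used
    where a directional hypothesis is stated).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cond = []
    names = []
    for arrs, nm_list, prefix in ((controls, control_names, "control"),
                                  (covariates, covariate_names, "covariate")):
        if arrs is not None:
            for i, a in enumerate(arrs):
                cond.append(np.asarray(a, dtype=float))
                names.append(nm_list[i] if i < len(nm_list) else f"{prefix}{i}")
    k = len(cond)
    mask = np.isfinite(x) & np.isfinite(y)
    for a in cond:
        mask &= np.isfinite(a)
    x, y = x[mask], y[mask]
    cond = [a[mask] for a in cond]
    n = x.size
    if n <= 2 + k:
        raise DegenerateDataError(f"need n > {2 + k} complete cases, got {n}")

    design = np.column_stack([np.ones(n)] + cond)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
                collinear.append(names[j - 1])
        raise DegenerateDataError(f"collinear conditioning variables: {collinear}")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise DegenerateDataError("constant residual; correlation undefined")
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    if tail == "two-sided":
        p = 2.0 * sps.t.sf(abs(t), df)
    elif tail == "greater":
        p = sps.t.sf(t, df)
    elif tail == "less":
        p = sps.t.cdf(t, df)
    else:
        raise InputError(f"unknown tail {tail!r}")
    return CorrelationResult(r=r, n=n, df=df, p=float(min(p, 1.0)), tail=tail,
                             controls=tuple(control_names), covariates=tuple(covariate_names),
                             stat=float(t))


def fisher_ci(r: float, n: int, k: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a (partial) correlation.

    ``k`` conditioning variables reduce the effective sample size in the
    usual way (se = 1 / sqrt(n - 3 - k)).
    """
    if n - 3 - k <= 0:
        raise DegenerateDataError("insufficient n for a Fisher CI")
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3 - k)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


# ---------------------------------------------------------------------------
# comparing correlations
# ---------------------------------------------------------------------------

def compare_correlations_independent(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of correlations from two independent samples."""
    for r, n in ((r1, n1), (r2, n2)):
        if not -1.0 < r < 1.0:
            raise InputError(f"correlation must lie in (-1, 1), got {r}")
        if n <= 3:
            raise InputError(f"need n > 3, got {n}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def _check_pd_triplet(r_xy: float, r_xz: float, r_yz: float) -> None:
    det = 1.0 + 2.0 * r_xy * r_xz * r_yz - r_xy ** 2 - r_xz ** 2 - r_yz ** 2
    if any(not -1.0 < r < 1.0 for r in (r_xy, r_xz, r_yz)) or det <= 0:
        raise InputError(
            f"correlation triplet ({r_xy}, {r_xz}, {r_yz}) is not positive definite")


def compare_correlations_dependent(r_xy: float, r_xz: float, r_yz: float,
                                   n: int) -> tuple[float, float]:
    """Steiger's test for two dependent, overlapping correlations.

    Compares corr(x, y) against corr(x, z) measured on the same n subjects,
    accounting for corr(y, z), via Fisher z with the pooled-r covariance
    term (Steiger 1980, Z1*).
    """
    _check_pd_triplet(r_xy, r_xz, r_yz)
    if n <= 3:
        raise InputError(f"need n > 3, got {n}")
    rbar = (r_xy + r_xz) / 2.0
    rb2 = rbar * rbar
    cov = (r_yz * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - r_yz ** 2)) \
        / (1.0 - rb2) ** 2
    z = (np.arctanh(r_xy) - np.arctanh(r_xz)) * np.sqrt((n - 3) / (2.0 - 2.0 * cov))
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def compare_correlations_dependent_nonoverlapping(
        r12: float, r34: float, cross: tuple[float, float, float, float],
        n: int) -> tuple[float, float]:
    """Compare corr(1,2) with corr(3,4) measured on the same subjects.

    ``cross`` is (r13, r14, r23, r24).  Uses the Fisher-z statistic with the
    Pearson-Filon covariance (the ZPF* form of Raghunathan, Rosenthal &
    Rubin 1996).
    """
    if n <= 3:
        raise InputError(f"need n > 3, got {n}")
    r13, r14, r23, r24 = cross
    k = ((r13 - r12 * r23) * (r24 - r23 * r34)
         + (r14 - r13 * r34) * (r23 - r12 * r13)
         + (r13 - r14 * r34) * (r24 - r12 * r14)
         + (r14 - r12 * r24) * (r23 - r13 * r34))
    c = k / (2.0 * (1.0 - r12 ** 2) * (1.0 - r34 ** 2))
    c = float(np.clip(c, -0.999, 0.999))
    z = (np.arctanh(r12) - np.arctanh(r34)) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


def coupling_change(pre_glu, pre_gaba, post_glu, post_gaba) -> dict:
    """Change in the across-subject Glu-GABA coupling from pre to post.

    ``post_*`` are the averaged post-period concentrations.  Returns the two
    correlations and the dependent-groups (non-overlapping variables)
    r-to-z comparison, since the same subjects contribute both correlations.
    """
    arrs = [np.asarray(a, dtype=float) for a in (pre_glu, pre_gaba, post_glu, post_gaba)]
    mask = np.logical_and.reduce([np.isfinite(a) for a in arrs])
    arrs = [a[mask] for a in arrs]
    n = arrs[0].size
    if n < 5:
        raise DegenerateDataError(f"need >= 5 complete pre/post pairs, got {n}")
    R = np.corrcoef(np.vstack(arrs))
    r_pre, r_post = R[0, 1], R[2, 3]
    cross = (R[0, 2], R[0, 3], R[1, 2], R[1, 3])
    z, p = compare_correlations_dependent_nonoverlapping(r_pre, r_post, cross, n)
    return {"r_pre": float(r_pre), "r_post": float(r_post), "Z": z, "p": p, "n": n}


# ---------------------------------------------------------------------------
# multiplicity and outliers
# ---------------------------------------------------------------------------

def bh_fdr(p_values, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, computed within each family."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise InputError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if family_labels is None:
        family_labels = np.zeros(p.size)
    labels = np.asarray(family_labels)
    for fam in pd.unique(labels):
        idx = np.flatnonzero((labels == fam) & np.isfinite(p))
        m = idx.size
        if m == 0:
            continue
        order = np.argsort(p[idx], kind="mergesort")
        ranked = p[idx][order] / (np.arange(1, m + 1) / m)
        qvals = np.minimum.accumulate(ranked[::-1])[::-1]
        q[idx[order]] = np.minimum(qvals, 1.0)
    return q


def iqr_outliers(values) -> np.ndarray:
    """Flag values beyond 3 x IQR below Q1 or above Q3 (linear quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InputError(f"need >= 4 values, got {v.size}")
    q1, q3 = np.percentile(v[np.isfinite(v)], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    with np.errstate(invalid="ignore"):
        return (v < lo) | (v > hi)


# ---------------------------------------------------------------------------
# repeated-measures mixed model
# ---------------------------------------------------------------------------

@dataclass
class LmmResult:
    effects: pd.DataFrame
    posthoc: pd.DataFrame
    converged: bool
    random_structure: str  # "intercept+slope" or "intercept" (fallback)


def fit_time_group_lmm(panel: pd.DataFrame, dv: str, *,
                       time_col: str = "timepoint", group_col: str = "group",
                       subject_col: str = "subject_id",
                       time_order=None) -> LmmResult:
    """REML fit of ``dv ~ Time*Group + (Time | ID)`` with Wald F tests.

    Time enters the fixed effects as a categorical factor and the random
    effects as a numeric slope.  F statistics use balanced split-plot
    (containment) denominator degrees of freedom: subjects - groups for the
    between-subject effect, (subjects - groups) x (T - 1) for within-subject
    effects.  Post-hoc pairwise time contrasts within each group are BH-FDR
    corrected.  A singular random-slope fit triggers a random-intercept-only
    refit with a prominent warning.
    """
    import statsmodels.formula.api as smf

    data = panel[[subject_col, time_col, group_col, dv]].dropna().copy()
    if data[dv].nunique() <= 1:
        raise DegenerateDataError(f"dependent variable {dv!r} is constant")
    times = list(time_order) if time_order is not None else sorted(data[time_col].unique())
    if len(times) < 2:
        raise DegenerateDataError("need >= 2 time points")
    groups = sorted(data[group_col].unique())
    if len(groups) < 2:
        raise DegenerateDataError("both groups must be present")
    data["_time"] = pd.Categorical(data[time_col], categories=times)
    data["_tnum"] = data[time_col].map({t: float(i) for i, t in enumerate(times)})
    data["_grp"] = pd.Categorical(data[group_col], categories=groups)
    data = data.rename(columns={dv: "_dv"})

    def _fit(re_formula):
        last = None
        for method in ("lbfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = smf.mixedlm("_dv ~ C(_time) * C(_grp)", data,
                                    groups=data[subject_col], re_formula=re_formula)
                    return m.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError) as e:
                last = e
        raise DegenerateDataError(f"mixed-model fit failed: {last}")

    random_structure = "intercept+slope"
    fit = _fit("~_tnum")
    cov_re = fit.cov_re.to_numpy()
    eigs = np.linalg.eigvalsh(cov_re)
    singular = (not fit.converged) or eigs.min() < 1e-8 * max(1e-12, eigs.max())
    if singular:
        logger.warning("singular random-slope fit for %s; refitting random intercept only", dv)
        try:
            fit = _fit("1")
            random_structure = "intercept"
        except DegenerateDataError:
            logger.warning("random-intercept refit failed; keeping the slope fit")

    params = fit.fe_params
    names = list(params.index)
    cov = fit.cov_params().loc[names, names].to_numpy()
    n_subj = data[subject_col].nunique()
    T, G = len(times), len(groups)
    df_between = max(n_subj - G, 1)
    df_within = max((n_subj - G) * (T - 1), 1)

    def _wald(term_names, df2):
        sel = [names.index(nm) for nm in term_names]
        L = np.zeros((len(sel), len(names)))
        for i, j in enumerate(sel):
            L[i, j] = 1.0
        b = L @ params.to_numpy()
        V = L @ cov @ L.T
        stat = float(b @ np.linalg.solve(V, b))
        q = len(sel)
        F = stat / q
        return F, q, df2, float(sps.f.sf(F, q, df2))

    def _term(pattern_time: bool, pattern_group: bool):
        out = []
        for nm in names:
            has_t = "C(_time)" in nm
            has_g = "C(_grp)" in nm
            if has_t == pattern_time and has_g == pattern_group and nm != "Intercept":
                out.append(nm)
        return out

    eff_rows = []
    for term, t_flag, g_flag, df2 in (
            ("Time", True, False, df_within),
            ("Group", False, True, df_between),
            ("Time:Group", True, True, df_within)):
        F, q, d2, p = _wald(_term(t_flag, g_flag), df2)
        eff_rows.append({"term": term, "F": F, "df1": q, "df2": d2, "p": p})
    effects = pd.DataFrame(eff_rows)

    # post-hoc pairwise time contrasts within each group
    def _cell_vec(time, group):
        v = np.zeros(len(names))
        for nm in names:
            has_t = f"[T.{time}]" in nm and "C(_time)" in nm
            has_g = f"[T.{group}]" in nm and "C(_grp)" in nm
            if "C(_time)" in nm and "C(_grp)" in nm:
                if has_t and has_g:
                    v[names.index(nm)] = 1.0
            elif "C(_time)" in nm:
                if has_t:
                    v[names.index(nm)] = 1.0
            elif "C(_grp)" in nm:
                if has_g:
                    v[names.index(nm)] = 1.0
        return v

    ph_rows = []
    for g in groups:
        for i in range(T):
            for j in range(i + 1, T):
                L = _cell_vec(times[j], g) - _cell_vec(times[i], g)
                est = float(L @ params.to_numpy())
                se = float(np.sqrt(L @ cov @ L))
                z = est / se if se > 0 else 0.0
                ph_rows.append({"group": g, "time_a": times[i], "time_b": times[j],
                                "estimate": est, "se": se, "stat": z,
                                "p": 2.0 * sps.norm.sf(abs(z))})
    posthoc = pd.DataFrame(ph_rows)
    if not posthoc.empty:
        posthoc["q"] = bh_fdr(posthoc["p"].to_numpy(), posthoc["group"].to_numpy())
    return LmmResult(effects=effects, posthoc=posthoc, converged=bool(fit.converged),
                     random_structure=random_structure)
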