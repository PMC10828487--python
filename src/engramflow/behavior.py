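"""Key-press scoring, learning-phase segmentation, and overnight gains.

Skill is measured as the number of correct 4-1-3-2-4 sequences completed
within each 30-s block, a combined speed/accuracy count.  The learning
session is split into an early phase (fast improvement) and a late phase
(plateau) at the first block from which no block-to-block change in the
group-level counts is statistically detectable, judged by uncorrected
consecutive-block contrasts from a random-intercept and random-slope linear
mixed model.  Overnight (offline) gain is the percent change from the last
day-1 practice block to the day-2 test block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InputError, UndefinedGainError

logger = logging.getLogger(__name__)

TARGET_SEQUENCE = (4, 1, 3, 2, 4)


@dataclass(frozen=True)
class BlockScore:
    subject_id: str
    day: int
    block: int
    n_correct: int
    n_keypresses: int


@dataclass
class PhaseSegmentation:
    """Early/late split of the practice blocks.

    ``boundary_block`` is the first late-phase block (>= 2); early phase is
    every block before it.  ``no_plateau`` marks the b = n_blocks + 1
    convention when performance keeps changing through the last block.
    """
    boundary_block: int
    early_blocks: tuple[int, ...]
    late_blocks: tuple[int, ...]
    no_plateau: bool
    method: str
    contrasts: pd.DataFrame = field(repr=False, default=None)


def _failure_function(target: tuple[int, ...]) -> list[int]:
    fail = [0] * len(target)
    k = 0
    for i in range(1, len(target)):
        while k > 0 and target[i] != target[k]:
            k = fail[k - 1]
        if target[i] == target[k]:
            k += 1
        fail[i] = k
    return fail


def score_block(keystream, target_sequence: tuple[int, ...] = TARGET_SEQUENCE,
                *, strict_reset: bool = False) -> tuple[int, int]:
    """Count completed target sequences in a key-press stream.

    Returns ``(n_correct, n_keypresses)``.  The scan advances a cursor
    through the target on each matching press; on a mismatch the cursor
    falls back to the longest viable restart position (KMP failure links),
    so a stray press does not erase a partially valid continuation.  With
    ``strict_reset`` a mismatch instead resets the cursor fully (the
    mismatching press may still open a new attempt).  Completed sequences
    are counted disjointly: a full match resets the cursor.
    """
    if isinstance(keystream, str):
        try:
            presses = [int(c) for c in keystream]
        except ValueError as e:
            raise InputError(f"non-digit key symbol in stream: {e}")
    else:
        presses = [int(c) for c in keystream]
    alphabet = set(target_sequence) | {1, 2, 3, 4}
    bad = set(presses) - alphabet
    if bad:
        raise InputError(f"invalid key symbols {sorted(bad)}; expected {sorted(alphabet)}")

    fail = _failure_function(target_sequence)
    m = len(target_sequence)
    count = j = 0
    for c in presses:
        if strict_reset:
            if c == target_sequence[j]:
                j += 1
            else:
                j = 1 if c == target_sequence[0] else 0
        else:
            while j > 0 and c != target_sequence[j]:
                j = fail[j - 1]
            if c == target_sequence[j]:
                j += 1
        if j == m:
            count += 1
            j = 0
    return count, len(presses)


def score_table(behavior: pd.DataFrame, *, strict_reset: bool = False) -> pd.DataFrame:
    """Score every block of a behavior table (subject_id, day, block, keystream)."""
    rows = []
    for rec in behavior.itertuples(index=False):
        n_correct, n_presses = score_block(rec.keystream, strict_reset=strict_reset)
        rows.append({"subject_id": rec.subject_id, "day": int(rec.day),
                     "block": int(rec.block), "n_correct": n_correct,
                     "n_keypresses": n_presses})
    return pd.DataFrame(rows)


def overnight_gain(day1_last: float, day2_test: float) -> float:
    """Percent change in correct-sequence count from day-1 last block to day-2 test."""
    if day1_last <= 0:
        raise UndefinedGainError(f"day-1 reference count must be > 0, got {day1_last}")
    return 100.0 * (day2_test - day1_last) / day1_last


def gains_table(block_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-subject overnight gains from a scored block table."""
    day1 = block_scores[block_scores["day"] == 1]
    day2 = block_scores[block_scores["day"] == 2]
    last_block = day1["block"].max()
    d1 = day1[day1["block"] == last_block].set_index("subject_id")["n_correct"]
    d2 = day2.set_index("subject_id")["n_correct"]
    rows = []
    for sid in d1.index:
        if sid not in d2.index:
            continue
        rows.append({"subject_id": sid,
                     "day1_last": int(d1[sid]),
                     "day2_test": int(d2[sid]),
                     "overnight_gain_pct": overnight_gain(d1[sid], d2[sid])})
    return pd.DataFrame(rows)


def _consecutive_contrasts_lmm(scores: pd.DataFrame, blocks: np.ndarray) -> pd.DataFrame:
    import statsmodels.formula.api as smf

    df = scores.copy()
    df["block_c"] = pd.Categorical(df["block"], categories=blocks)
    df["block_num"] = df["block"].astype(float)
    import warnings

    model = smf.mixedlm("n_correct ~ C(block_c)", df, groups=df["subject_id"],
                        re_formula="~block_num")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs")
    if not fit.converged:
        raise DegenerateDataError("mixed model did not converge")
    params = fit.fe_params
    cov = fit.cov_params().loc[params.index, params.index].to_numpy()
    names = list(params.index)

    def _coef_vec(block) -> np.ndarray:
        v = np.zeros(len(names))
        label = f"C(block_c)[T.{block}]"
        if label in names:  # reference block contributes a zero vector
            v[names.index(label)] = 1.0
        return v

    rows = []
    for prev, cur in zip(blocks[:-1], blocks[1:]):
        L = _coef_vec(cur) - _coef_vec(prev)
        est = float(L @ params.to_numpy())
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else 0.0
        rows.append({"block_from": int(prev), "block_to": int(cur),
                     "estimate": est, "se": se, "stat": z,
                     "p": 2.0 * sps.norm.sf(abs(z))})
    return pd.DataFrame(rows)


def _consecutive_contrasts_paired(scores: pd.DataFrame, blocks: np.ndarray) -> pd.DataFrame:
    wide = scores.pivot_table(index="subject_id", columns="block", values="n_correct")
    rows = []
    for prev, cur in zip(blocks[:-1], blocks[1:]):
        a, b = wide[prev].to_numpy(), wide[cur].to_numpy()
        res = sps.ttest_rel(b, a)
        rows.append({"block_from": int(prev), "block_to": int(cur),
                     "estimate": float(np.mean(b - a)),
                     "se": float(sps.sem(b - a)),
                     "stat": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)


def segment_phases(block_scores: pd.DataFrame, *, alpha: float = 0.05,
                   require_all_subsequent: bool = False) -> PhaseSegmentation:
    """Split day-1 practice blocks into early and late learning phases.

    Fits a random-intercept + random-slope mixed model of the correct-
    sequence count on block and tests each consecutive pair of blocks with
    an uncorrected contrast.  The late phase starts at the first block whose
    step from the previous block is non-significant (with
    ``require_all_subsequent``, the first block from which *every* later
    step is also non-significant — a stricter reading whose recovery rate
    degrades with block count through sheer multiplicity).  Falls back to
    paired t-tests with a warning if the mixed model fails.
    """
    day1 = block_scores[block_scores.get("day", 1) == 1] if "day" in block_scores else block_scores
    blocks = np.sort(day1["block"].unique())
    n_subjects = day1["subject_id"].nunique()
    if len(blocks) < 3:
        raise InputError(f"need >= 3 blocks, got {len(blocks)}")
    if n_subjects < 5:
        raise InputError(f"need >= 5 subjects, got {n_subjects}")

    try:
        contrasts = _consecutive_contrasts_lmm(day1, blocks)
        method = "lmm"
    except Exception as e:  # non-convergence, singular fits
        logger.warning("mixed-model contrasts failed (%s); falling back to paired t-tests", e)
        contrasts = _consecutive_contrasts_paired(day1, blocks)
        method = "paired_t"

    p = contrasts["p"].to_numpy()
    n_last = int(blocks[-1])
    boundary = n_last + 1
    if require_all_subsequent:
        ns_from_here = np.flip(np.logical_and.accumulate(np.flip(p >= alpha)))
        idx = np.flatnonzero(ns_from_here)
    else:
        idx = np.flatnonzero(p >= alpha)
    if idx.size:
        boundary = int(contrasts["block_to"].iloc[idx[0]])
    no_plateau = boundary == n_last + 1
    early = tuple(int(b) for b in blocks if b < boundary)
    late = tuple(int(b) for b in blocks if b >= boundary)
    return PhaseSegmentation(boundary_block=boundary, early_blocks=early,
                             late_blocks=late, no_plateau=no_plateau,
                             method=method, contrasts=contrasts)
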