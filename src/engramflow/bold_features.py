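"""Task GLM, engram-conjunction ROI, integrated local correlation (ILC),
MVLC reactivation similarity, and ROI-to-ROI functional connectivity.

The ILC of a voxel is the Gaussian-weighted average Pearson correlation of
its time course with those of its spatial neighbors:

    ILC(v) = sum_{u != v} w(u, v) corr(x_v, x_u) / sum_{u != v} w(u, v)

with w = exp(-d^2 / (2 sigma^2)), distances in mm, neighbors truncated at
3 sigma, and the center voxel excluded.  At the default sigma = 1 mm on a
1.6 mm grid the neighborhood is exactly the 26 directly surrounding voxels.
The MVLC pattern is the Fisher-z transformed ILC over the ROI voxels in a
fixed (ascending linear index) ordering shared across conditions; the
similarity difference r(task, post-rest) - r(task, pre-rest) indexes offline
memory reactivation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, EmptyRoiError, InputError

logger = logging.getLogger(__name__)


@dataclass
class BoldRun:
    """A 4D BOLD acquisition (x, y, z, t) with its timing and geometry."""
    data: np.ndarray
    tr: float
    condition: str
    voxel_size: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise InputError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[-1] < 20:
            raise InputError(f"need >= 20 volumes, got {self.data.shape[-1]}")
        if not np.isfinite(self.data).all():
            raise InputError("BOLD data contain non-finite values")
        if self.voxel_size <= 0 or self.tr <= 0:
            raise InputError("voxel_size and tr must be > 0")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


@dataclass
class SimilarityResult:
    r_task_pre: float
    r_task_post: float
    similarity_difference: float = field(init=False)

    def __post_init__(self):
        self.similarity_difference = self.r_task_post - self.r_task_pre


# ---------------------------------------------------------------------------
# hemodynamics and the task GLM
# ---------------------------------------------------------------------------

def double_gamma_hrf(tr: float, duration: float = 32.0, peak: float = 6.0,
                     undershoot: float = 16.0, ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, sampled at the TR.

    Difference of two gamma densities (shape parameters ``peak`` and
    ``undershoot``, unit scale), undershoot scaled by ``ratio``; normalized
    to unit peak.
    """
    t = np.arange(0, duration + tr / 2, tr)
    h = sps.gamma.pdf(t, peak) - ratio * sps.gamma.pdf(t, undershoot)
    return h / h.max()


def _convolved_boxcar(onsets, durations, n_vols: int, tr: float) -> np.ndarray:
    box = np.zeros(n_vols)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / tr))
        i1 = int(round((onset + dur) / tr))
        box[max(i0, 0):min(i1, n_vols)] = 1.0
    return np.convolve(box, double_gamma_hrf(tr))[:n_vols]


def glm_activation(run: BoldRun, block_onsets, durations, *,
                   early_blocks=(0, 1, 2)) -> dict:
    """Voxelwise least-squares fit of the simplified task design.

    Design columns: early-phase regressor, late-phase regressor (boxcars
    convolved with the double-gamma HRF), the temporal derivative of the
    combined task regressor, an intercept, and a linear drift.  Returns
    z-statistic maps and beta maps for the early and late contrasts;
    zero-variance voxels get z = 0 by convention.
    """
    n_vols = run.data.shape[-1]
    onsets = list(block_onsets)
    durs = list(durations)
    if len(onsets) != len(durs):
        raise InputError("block_onsets and durations must have equal length")
    if any(o < 0 or o + d > n_vols * run.tr + 1e-9 for o, d in zip(onsets, durs)):
        raise InputError("block onsets/durations extend outside the run")
    early_set = set(early_blocks)
    early = _convolved_boxcar([o for i, o in enumerate(onsets) if i in early_set],
                              [d for i, d in enumerate(durs) if i in early_set],
                              n_vols, run.tr)
    late = _convolved_boxcar([o for i, o in enumerate(onsets) if i not in early_set],
                             [d for i, d in enumerate(durs) if i not in early_set],
                             n_vols, run.tr)
    deriv = np.gradient(early + late)
    drift = np.linspace(-1, 1, n_vols)
    names = ["early", "late", "derivative", "intercept", "drift"]
    X = np.column_stack([early, late, deriv, np.ones(n_vols), drift])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        collinear = [names[j] for j in range(X.shape[1])
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)]
        raise InputError(f"rank-deficient design; collinear columns: {collinear}")

    shape = run.data.shape[:3]
    Y = run.data.reshape(-1, n_vols).T.astype(float)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n_vols - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    out = {}
    for ci, name in ((0, "early"), (1, "late")):
        se = np.sqrt(sigma2 * xtx_inv[ci, ci])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[ci] / np.where(se > 0, se, 1.0), 0.0)
        # exact t -> z conversion, symmetric in sign
        z = np.sign(t) * sps.norm.isf(np.clip(sps.t.sf(np.abs(t), dof), 1e-300, 1.0))
        out[f"z_{name}"] = z.reshape(shape)
        out[f"beta_{name}"] = beta[ci].reshape(shape)
    return out


def conjunction_roi(zmap_a: np.ndarray, zmap_b: np.ndarray, *,
                    z_threshold: float = 3.1, min_cluster: int = 0,
                    anatomical_mask: np.ndarray | None = None) -> np.ndarray:
    """Voxels suprathreshold in both maps, small components removed.

    Operationalizes an engram-style ROI: significantly activated at the end
    of learning and again at next-day retrieval.  Connected components use
    26-connectivity; components smaller than ``min_cluster`` are dropped.
    Raises :class:`EmptyRoiError` (reporting each map's suprathreshold voxel
    count) when the conjunction is empty.
    """
    from scipy import ndimage

    if zmap_a.shape != zmap_b.shape:
        raise InputError("z-maps must share a grid")
    mask = (zmap_a > z_threshold) & (zmap_b > z_threshold)
    if anatomical_mask is not None:
        mask &= anatomical_mask.astype(bool)
    if min_cluster > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_cluster)
        mask = np.isin(labels, keep[keep > 0])
    if not mask.any():
        raise EmptyRoiError(
            f"empty conjunction: {int((zmap_a > z_threshold).sum())} voxels above "
            f"threshold in map A, {int((zmap_b > z_threshold).sum())} in map B")
    return mask


# ---------------------------------------------------------------------------
# integrated local correlation
# ---------------------------------------------------------------------------

def _ilc_offsets(voxel_size: float, kernel_mm: float):
    reach = int(np.floor(3.0 * kernel_mm / voxel_size))
    offsets = []
    for d in itertools.product(range(-reach, reach + 1), repeat=3):
        if d == (0, 0, 0):
            continue
        dist = voxel_size * np.sqrt(sum(x * x for x in d))
        if dist <= 3.0 * kernel_mm + 1e-12:
            offsets.append((d, float(np.exp(-dist ** 2 / (2.0 * kernel_mm ** 2)))))
    return offsets


def compute_ilc(run: BoldRun, kernel_mm: float = 1.0,
                roi: np.ndarray | None = None) -> np.ndarray:
    """Integrated local correlation map of a 4D run (see module docstring).

    Zero-variance voxels contribute correlation 0 to their neighbors (with a
    log entry) and receive ILC 0 themselves when isolated.  With ``roi`` the
    computation is restricted to the ROI's bounding box padded by the kernel
    reach — ROI voxels get exactly the same values as a full-grid pass, and
    everything outside the padded box is 0.
    """
    if kernel_mm <= 0:
        raise InputError(f"kernel_mm must be > 0, got {kernel_mm}")
    if roi is not None:
        roi = roi.astype(bool)
        if roi.shape != run.data.shape[:3] or not roi.any():
            raise InputError("roi must be a nonempty mask on the run grid")
        reach = int(np.floor(3.0 * kernel_mm / run.voxel_size))
        sl = []
        for ax in range(3):
            idx = np.flatnonzero(roi.any(axis=tuple(a for a in range(3) if a != ax)))
            sl.append(slice(max(idx[0] - reach, 0),
                            min(idx[-1] + reach + 1, roi.shape[ax])))
        sub = BoldRun(data=run.data[tuple(sl)], tr=run.tr,
                      condition=run.condition, voxel_size=run.voxel_size)
        out = np.zeros(run.data.shape[:3])
        out[tuple(sl)] = compute_ilc(sub, kernel_mm)
        return out
    data = run.data.astype(np.float64)
    t = data.shape[-1]
    mean = data.mean(axis=-1, keepdims=True)
    centered = data - mean
    norm = np.sqrt((centered ** 2).sum(axis=-1, keepdims=True))
    flat = (norm == 0)
    if flat.any():
        logger.warning("%d zero-variance voxels; their correlations set to 0", int(flat.sum()))
    z = np.where(flat, 0.0, centered / np.where(norm == 0, 1.0, norm))

    shape = data.shape[:3]
    num = np.zeros(shape, dtype=np.float64)
    den = np.zeros(shape, dtype=np.float64)
    for (dx, dy, dz), w in _ilc_offsets(run.voxel_size, kernel_mm):
        src = tuple(slice(max(d, 0), s + min(d, 0)) for d, s in zip((dx, dy, dz), shape))
        dst = tuple(slice(max(-d, 0), s + min(-d, 0)) for d, s in zip((dx, dy, dz), shape))
        corr = (z[dst] * z[src]).sum(axis=-1)
        num[dst] += w * corr
        den[dst] += w
    with np.errstate(invalid="ignore"):
        ilc = np.where(den > 0, num / np.where(den == 0, 1.0, den), 0.0)
    return ilc


def mvlc_pattern(ilc_map: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Fisher-z ILC vector over the ROI in canonical (ascending linear) order."""
    roi = roi.astype(bool)
    if roi.shape != ilc_map.shape:
        raise InputError("ROI and ILC map must share a grid")
    idx = np.flatnonzero(roi.ravel(order="C"))
    if idx.size < 10:
        raise EmptyRoiError(f"ROI has {idx.size} voxels; >= 10 required for patterns")
    vals = ilc_map.ravel(order="C")[idx]
    if not np.isfinite(vals).all():
        raise InputError("non-finite ILC values inside ROI")
    clip = 1.0 - 1e-6
    if np.any(np.abs(vals) >= clip):
        logger.warning("ILC values at |1| clipped before Fisher transform")
        vals = np.clip(vals, -clip, clip)
    return np.arctanh(vals)


def similarity_difference(task_pattern, pre_pattern, post_pattern) -> SimilarityResult:
    """Reactivation index: r(task, post-rest) - r(task, pre-rest).

    All three MVLC vectors must share the voxel ordering.  Invariant under
    any common permutation of the three vectors.
    """
    task = np.asarray(task_pattern, dtype=float)
    pre = np.asarray(pre_pattern, dtype=float)
    post = np.asarray(post_pattern, dtype=float)
    if not task.shape == pre.shape == post.shape or task.ndim != 1:
        raise InputError("patterns must be 1D vectors of equal length")
    for name, v in (("task", task), ("pre", pre), ("post", post)):
        if np.std(v) == 0:
            raise DegenerateDataError(f"constant {name} pattern; correlation undefined")
    r_pre = float(np.corrcoef(task, pre)[0, 1])
    r_post = float(np.corrcoef(task, post)[0, 1])
    return SimilarityResult(r_task_pre=r_pre, r_task_post=r_post)


# ---------------------------------------------------------------------------
# ROI-to-ROI functional connectivity
# ---------------------------------------------------------------------------

def roi_to_roi_fc(run: BoldRun, roi_a: np.ndarray, roi_b: np.ndarray) -> float:
    """Fisher-z correlation of the two ROIs' mean resting time courses."""
    a, b = roi_a.astype(bool), roi_b.astype(bool)
    if a.shape != run.data.shape[:3] or b.shape != run.data.shape[:3]:
        raise InputError("ROI masks must match the run grid")
    if not a.any() or not b.any():
        raise EmptyRoiError("both ROIs must be nonempty")
    ts_a = run.data[a].mean(axis=0)
    ts_b = run.data[b].mean(axis=0)
    if np.std(ts_a) == 0 or np.std(ts_b) == 0:
        raise DegenerateDataError("constant ROI mean time course")
    r = float(np.corrcoef(ts_a, ts_b)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        raise DegenerateDataError(
            "|r| = 1 between ROI time courses (identical/overlapping ROIs?); "
            "Fisher z undefined — use disjoint ROIs")
    return float(np.arctanh(r))


def fc_change(post_z: float, pre_z: float) -> float:
    """Connectivity change: post minus pre Fisher-z values."""
    return post_z - pre_z


def late_phase_data(run: BoldRun, block_onsets, durations, late_blocks,
                    *, drop_transition: int = 5) -> BoldRun:
    """Concatenated late-block volumes for the task MVLC pattern.

    ``drop_transition`` volumes at the start of each block are discarded to
    reduce block-boundary transients.
    """
    n_vols = run.data.shape[-1]
    keep = []
    onsets = list(block_onsets)
    durs = list(durations)
    for b in late_blocks:
        i0 = int(round(onsets[b] / run.tr)) + drop_transition
        i1 = int(round((onsets[b] + durs[b]) / run.tr))
        keep.extend(range(max(i0, 0), min(i1, n_vols)))
    if len(keep) < 20:
        raise InputError(f"late-phase selection keeps only {len(keep)} volumes")
    return BoldRun(data=run.data[..., keep], tr=run.tr,
                   condition=f"{run.condition}_late", voxel_size=run.voxel_size)
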