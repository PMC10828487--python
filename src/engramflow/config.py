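"""Configuration objects for the synthetic cohort and the analysis run.

Two dataclasses describe a simulated study: :class:`CohortConfig` fixes the
design (group sizes, scan schedule, BOLD grid) and :class:`EffectSpec` fixes
the planted statistical structure (baseline metabolite distributions,
regression-to-the-mean slopes, the post-learning excitation/inhibition
coupling, the Glu-change -> overnight-gain partial correlation, and so on).
:class:`RunConfig` bundles both with the analysis switches and is what the
end-to-end pipeline consumes; it serializes to a single YAML file.

Planted correlations are specified on the *measured* scale: the generator
inverts its own noise model so that, at large n, the correlation recovered
from the emitted (noisy) measurements converges to the stated value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigurationError

TIMEPOINTS = ("pre", "post0", "post10", "post20", "post30", "day2")
POST_TIMEPOINTS = ("post0", "post10", "post20", "post30")
METABOLITES = ("Glu", "GABA", "NAA", "Gln", "Cr")

#: water concentrations (molar) used for tissue correction
WATER_GM = 43.3
WATER_WM = 35.88
WATER_CSF = 5.556


@dataclass
class CohortConfig:
    """Design of the synthetic two-day cohort.

    Defaults follow the study design: a Learning group (n=36) and a passive
    Control group (n=21); six MRS time points (baseline, four post scans over
    ~30 min at 10-min spacing, and a day-2 baseline); 12 practice blocks of
    30 s on day 1 plus a single day-2 test block.  The BOLD grid and run
    lengths are scaled down (16^3 voxels, 120 rest volumes vs the acquired
    420) so a full cohort simulates in seconds on one CPU.
    """

    n_learning: int = 36
    n_control: int = 21
    n_post_scans: int = 4
    n_blocks_day1: int = 12
    block_duration: float = 30.0  # s, behavioral practice block
    tr: float = 1.0  # s
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size: float = 1.6  # mm, isotropic
    n_volumes_rest: int = 120  # scaled down; acquisition used 420
    # scaled-down task-run block design (s); acquisition used 30 s on / 30 s off
    task_on_duration: float = 15.0
    task_off_duration: float = 15.0
    master_seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_learning": self.n_learning,
            "n_control": self.n_control,
            "n_post_scans": self.n_post_scans,
            "n_blocks_day1": self.n_blocks_day1,
            "n_volumes_rest": self.n_volumes_rest,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.n_learning < 4 or self.n_control < 4:
            raise ConfigurationError("group sizes must be >= 4 (correlation df)")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be > 0")
        if self.tr <= 0 or self.block_duration <= 0:
            raise ConfigurationError("tr and block_duration must be > 0")
        if len(self.grid_shape) != 3 or any(int(s) != s or s < 1 for s in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be three positive ints, got {self.grid_shape!r}")

    @property
    def n_subjects(self) -> int:
        return self.n_learning + self.n_control

    @property
    def n_volumes_task(self) -> int:
        per_block = (self.task_on_duration + self.task_off_duration) / self.tr
        return int(round(self.n_blocks_day1 * per_block))


def _default_baseline_mean() -> dict[str, float]:
    # mM-scale concentrations typical of motor-cortex MRS at 7T
    return {"Glu": 9.6, "GABA": 1.5, "NAA": 12.0, "Gln": 3.0, "Cr": 7.5}


def _default_baseline_sd() -> dict[str, float]:
    return {"Glu": 0.8, "GABA": 0.22, "NAA": 1.0, "Gln": 0.45, "Cr": 0.55}


def _default_scan_noise_sd() -> dict[str, float]:
    # per-scan measurement noise (fit uncertainty), mM
    return {"Glu": 0.30, "GABA": 0.12, "NAA": 0.25, "Gln": 0.20, "Cr": 0.18}


def _default_post_innovation_sd() -> dict[str, float]:
    # subject-level physiological shift of the post-learning plateau, mM
    return {"Glu": 0.55, "GABA": 0.18, "NAA": 0.25, "Gln": 0.20, "Cr": 0.15}


@dataclass
class EffectSpec:
    """Planted effect structure of the synthetic cohort.

    All correlations are targets on the measured scale (see module
    docstring).  Defaults reproduce the reported study conditions: baseline
    Glu-GABA coupling r=0.18 rising to r=0.58 over the post-learning period
    in the Learning group, a mean overnight gain of 10.46% whose partial
    correlation with the averaged Glu change (given the GABA change) is 0.45,
    a -0.48 correlation between the 30-min GABA change and the overnight M1
    gray-matter change, and a 0.368 correlation between the immediate Glu
    change and the overnight M1 <-> right-putamen connectivity change.
    """

    baseline_mean: dict[str, float] = field(default_factory=_default_baseline_mean)
    baseline_sd: dict[str, float] = field(default_factory=_default_baseline_sd)
    scan_noise_sd: dict[str, float] = field(default_factory=_default_scan_noise_sd)
    post_innovation_sd: dict[str, float] = field(default_factory=_default_post_innovation_sd)

    # homeostatic (regression-to-the-mean) slope of the post-period change on
    # the baseline level; applies to GABA in both groups and to Glu in the
    # Learning group (scaled by control_glu_slope_factor in Controls)
    regression_to_mean_slope: float = -0.4
    control_glu_slope_factor: float = 0.35

    coupling_r_pre: float = 0.18
    coupling_r_post: float = 0.58

    glu_gain_partial_r: float = 0.45
    overnight_gain_mean: float = 10.46  # percent
    overnight_gain_sd: float = 10.8  # percent (SE 1.8 at n=36)
    day1_perf_gain_r: float = -0.30  # higher day-1 score -> smaller gain

    gaba_gm_r: float = -0.48  # 30-min GABA change vs overnight M1 dGM
    gm_change_sd: float = 0.04  # modulated-GM units
    gm_day1_mean: float = 0.60
    gm_day1_sd: float = 0.05

    fc_glu_r: float = 0.368  # immediate Glu change vs overnight M1-putamen_R dz
    fc_base_mean: float = 0.30  # session-level M1-putamen_R correlation
    fc_base_sd: float = 0.10
    fc_pcc_mean: float = 0.25
    fc_pcc_sd: float = 0.08
    fc_change_sd: float = 0.25  # planted spread of overnight dz
    fc_session_jitter_sd: float = 0.10  # pre -> post same-day z drift

    # behavior / learning curve
    changepoint_block: int = 4  # first late-phase block (plateau onset)
    asymptote_mean: float = 20.0  # correct sequences per 30-s block
    asymptote_sd: float = 3.5
    start_mean: float = 8.0
    start_sd: float = 2.0
    within_block_sd: float = 1.8
    keypress_error_rate: float = 0.05  # stray presses per correct keystroke

    # BOLD
    reactivation_fidelity: float = 0.3
    fidelity_glu_slope: float = 0.15  # per-SD immediate Glu change
    ar1_coef: float = 0.3
    bold_noise_sd: float = 1.0
    latent_strength: float = 1.0
    activation_amplitude_mean: float = 0.8  # task response, noise-sd units
    activation_amplitude_sd: float = 0.15

    qc_contamination_rate: float = 0.02

    def validate(self, n_blocks_day1: int = 12) -> None:
        for name in ("coupling_r_pre", "coupling_r_post", "glu_gain_partial_r",
                     "day1_perf_gain_r", "gaba_gm_r", "fc_glu_r"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (-1, 1), got {v}")
        if not 0.0 <= self.reactivation_fidelity <= 1.0:
            raise ConfigurationError("reactivation_fidelity must lie in [0, 1]")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ConfigurationError("ar1_coef must lie in [0, 1)")
        # zero sds are permitted as degenerate diagnostics (noise-free draws)
        for dct in (self.baseline_sd, self.scan_noise_sd, self.post_innovation_sd):
            if any(v < 0 for v in dct.values()):
                raise ConfigurationError("sd terms must be >= 0")
        if self.glu_gain_partial_r ** 2 + self.day1_perf_gain_r ** 2 >= 1.0:
            raise ConfigurationError(
                "glu_gain_partial_r^2 + day1_perf_gain_r^2 must be < 1 "
                "(residual gain variance would be negative)")
        if not 2 <= self.changepoint_block <= n_blocks_day1:
            raise ConfigurationError(
                f"changepoint_block must lie in 2..{n_blocks_day1}, got {self.changepoint_block}")
        if not 0.0 <= self.qc_contamination_rate < 1.0:
            raise ConfigurationError("qc_contamination_rate must lie in [0, 1)")


def null_effects() -> EffectSpec:
    """An :class:`EffectSpec` with every planted association switched off.

    Baseline distributions and noise terms are unchanged; only the planted
    couplings, slopes and cross-modal correlations are zeroed, so a pipeline
    run under this spec is a global null.
    """
    return EffectSpec(
        regression_to_mean_slope=0.0,
        control_glu_slope_factor=0.0,
        coupling_r_pre=0.0,
        coupling_r_post=0.0,
        glu_gain_partial_r=0.0,
        day1_perf_gain_r=0.0,
        gaba_gm_r=0.0,
        fc_glu_r=0.0,
        reactivation_fidelity=0.0,
        fidelity_glu_slope=0.0,
    )


@dataclass
class RunConfig:
    """Everything a full simulate -> quantify -> score -> bold -> stats run needs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    effects: EffectSpec = field(default_factory=EffectSpec)

    # analysis switches
    tissue_correction: bool = True
    cr_referenced: bool = False
    strict_reset_scoring: bool = False
    group_pooled_qc: bool = False
    ilc_kernel_mm: float = 1.0
    z_threshold: float = 3.1
    alpha: float = 0.05
    transition_volumes: int = 5  # task volumes dropped at block boundaries
    write_nifti: bool = False  # write 4D runs/masks to disk during run_all

    def validate(self) -> None:
        self.cohort.validate()
        self.effects.validate(self.cohort.n_blocks_day1)
        if self.ilc_kernel_mm <= 0:
            raise ConfigurationError("ilc_kernel_mm must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cohort"]["grid_shape"] = list(self.cohort.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        cohort = CohortConfig(**{**d.pop("cohort", {})})
        cohort.grid_shape = tuple(cohort.grid_shape)
        effects = EffectSpec(**d.pop("effects", {}))
        cfg = cls(cohort=cohort, effects=effects, **d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
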