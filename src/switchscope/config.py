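"""Configuration objects shared across the switchscope pipeline.

Every stochastic stage takes an explicit seed; pipeline-level seeds are
derived deterministically from a single global seed plus the stage name so
that a run is reproducible end to end from one integer.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np


class ConfigError(ValueError):
    """Raised for invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Raised for structurally invalid data (CLI exit code 3)."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from a global seed and a stage name."""
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {p!r}")


def _check_pos(name: str, x: float) -> None:
    if not (x > 0):
        raise ConfigError(f"{name} must be > 0, got {x!r}")


# ---------------------------------------------------------------------------
# Time-lapse switching model
# ---------------------------------------------------------------------------

#: Per-class log-length distributions (mean, sd of log length in pixels).
#: White and opaque references are round-to-slightly-elongated yeast cells;
#: switching daughters are frequently pseudohyphal (elongated), switching
#: mothers mostly resemble white cells.
DEFAULT_LENGTH_DISTS = {
    "white": (np.log(25.0), 0.08),
    "opaque": (np.log(30.0), 0.12),
    "switching-mother": (3.112, 0.22),
    "switching-daughter": (3.687, 0.40),
}


@dataclass
class SwitchModelConfig:
    """Parameters of the two-step stochastic switching generator.

    The model: at every cell division a newborn daughter may, with
    probability ``p_predispose``, found a *predisposed* clan whose members
    (for a heritable span of 1-4 divisions) activate the Wor1 reporter with
    per-division probability ``p_activate``.  Activation always captures the
    dividing mother-daughter pair jointly and is irreversibly inherited.

    ``p_predispose`` and ``p_activate`` defaults are a calibration, frozen so
    that the expected number of zero-event traps in a 168-trap experiment
    equals 134/168 while mixed-fate clans still produce multiple switching
    groups at a realistic rate.
    """

    frame_interval: float = 12.0          # minutes
    n_frames: int = 121                   # 24 h at 12-min cadence
    division_time_mean: float = 84.0      # minutes; ~400 cells per trap at 12 h
    division_time_sd: float = 20.0        # minutes
    p_predispose: float = 2.67e-3         # per division (calibrated, see docs)
    predispose_span: tuple[int, int] = (1, 4)
    p_activate: float = 0.25              # per division within predisposed clans
    birth_to_max_mean: float = 9.9        # hours
    birth_to_max_sd: float = 3.2          # hours
    birth_to_max_range: tuple[float, float] = (5.4, 17.2)
    rise_time_10_90: float = 3.0          # hours
    white_level: float = 1.0              # arbitrary fluorescence units
    opaque_level: float = 40.0            # 40-fold over white
    white_area: float = 1750.0            # pixels
    opaque_area: float = 2500.0           # pixels
    trap_capacity: int = 400              # cells; divisions arrest when full
    n_traps: int = 168
    noise_cv: float = 0.05                # lognormal cv on trace values
    length_dists: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_DISTS))
    rng_seed: int = 0

    def validate(self) -> "SwitchModelConfig":
        _check_prob("p_predispose", self.p_predispose)
        _check_prob("p_activate", self.p_activate)
        for name in ("frame_interval", "division_time_mean", "division_time_sd",
                     "birth_to_max_mean", "birth_to_max_sd", "rise_time_10_90",
                     "white_level", "opaque_level", "white_area", "opaque_area"):
            _check_pos(name, getattr(self, name))
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        lo, hi = self.predispose_span
        if not (1 <= lo <= hi):
            raise ConfigError(f"predispose_span must satisfy 1 <= lo <= hi, got {self.predispose_span}")
        a, b = self.birth_to_max_range
        if not (0 < a < b):
            raise ConfigError(f"birth_to_max_range must be increasing and positive, got {self.birth_to_max_range}")
        if self.trap_capacity < 1 or self.n_traps < 1:
            raise ConfigError("trap_capacity and n_traps must be >= 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        return self

    @property
    def movie_minutes(self) -> float:
        return (self.n_frames - 1) * self.frame_interval


# ---------------------------------------------------------------------------
# Flow-cytometry model
# ---------------------------------------------------------------------------

#: Construct identifiers used throughout the flow modules.
CONSTRUCT_MGFP = "Wor1-mGFP"   # monomeric fusion (non-dimerizing)
CONSTRUCT_GFP = "Wor1-GFP"     # dimerizing fusion; reporter declines at high hormone
CONSTRUCT_FREE_GFP = "GFP"     # free GFP: no reporter activation
CONSTRUCT_WOR1 = "Wor1"        # unlabeled Wor1: reporter active, GFP channel dark


@dataclass
class FlowModelConfig:
    """Parameters of the synthetic flow-cytometry plate generator.

    Protein induction follows a saturating Hill curve in hormone shared
    across strains; the Wor1 autoregulation reporter follows a 4-parameter
    log-logistic (Hill) response in per-cell protein level.  The dimerizing
    fusion has a 5-fold lower half-max and shows a reporter decline above
    ``gfp_decline_threshold`` nM; free GFP is induced 10-fold higher than
    the fusions but never activates the reporter.
    """

    hormone_concs: tuple = tuple(np.round(np.geomspace(0.02, 50.0, 10), 4))  # nM
    # protein induction vs hormone (relative units; basal white level = 1)
    protein_basal: float = 1.0
    protein_max: float = 100.0
    protein_hill: float = 1.5
    protein_halfmax_nM: float = 2.0
    free_gfp_scale: float = 10.0          # free GFP induced 10x over fusions
    # autoregulation response (log10 reporter units)
    reporter_log10_basal: float = 1.0     # c
    reporter_log10_max: float = 3.0       # d
    hill_mgfp: float = 3.2
    hill_gfp: float = 4.3
    halfmax_mgfp: float = 15.0            # protein units (K for Wor1-mGFP)
    halfmax_ratio: float = 5.0            # K_mGFP / K_GFP
    gfp_decline_threshold: float = 2.0    # nM; dimerizing fusion declines above
    decline_log10_per_decade: float = 0.5
    # noise / channels
    protein_cv: float = 0.40              # cell-to-cell lognormal spread
    meas_cv_gfp: float = 0.05             # GFP channel measurement noise
    meas_cv_mcherry: float = 0.15         # mCherry channel measurement noise
    fsc_median: float = 1.0e4
    fsc_cv: float = 0.25
    ssc_median: float = 8.0e3
    ssc_cv: float = 0.30
    v670_median: float = 200.0
    v670_cv: float = 0.30
    # subpopulations
    debris_frac: float = 0.10
    aggregate_frac: float = 0.05
    events_per_well: int = 5000
    rng_seed: int = 0

    @property
    def halfmax_gfp(self) -> float:
        return self.halfmax_mgfp / self.halfmax_ratio

    def validate(self) -> "FlowModelConfig":
        if len(self.hormone_concs) == 0:
            raise ConfigError("hormone_concs must be nonempty")
        if any(c < 0 for c in self.hormone_concs):
            raise ConfigError("hormone concentrations must be >= 0")
        _check_prob("debris_frac", self.debris_frac)
        _check_prob("aggregate_frac", self.aggregate_frac)
        if self.debris_frac + self.aggregate_frac >= 1.0:
            raise ConfigError("debris_frac + aggregate_frac must be < 1")
        for name in ("protein_basal", "protein_max", "protein_hill",
                     "protein_halfmax_nM", "hill_mgfp", "hill_gfp",
                     "halfmax_mgfp", "halfmax_ratio", "gfp_decline_threshold"):
            _check_pos(name, getattr(self, name))
        if self.reporter_log10_max <= self.reporter_log10_basal:
            raise ConfigError("reporter_log10_max must exceed reporter_log10_basal")
        if self.events_per_well < 1:
            raise ConfigError("events_per_well must be >= 1")
        return self


# ---------------------------------------------------------------------------
# Imaging
# ---------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    """Morphological segmentation parameters.

    The operators (bottom-hat, top-hat, dilation, erosion, property-based
    selection) are fixed; their scales are tunable.  Structuring elements
    are disks.  ``threshold`` is either "otsu" or an absolute response value.
    """

    bottomhat_radius: int = 6
    tophat_radius: int = 6
    dilation_radius: int = 3
    erosion_radius: int = 3
    area_range: tuple[float, float] = (300.0, 8000.0)
    perimeter_range: tuple[float, float] = (40.0, 600.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.97)
    threshold: object = "otsu"

    def validate(self) -> "SegmentationParams":
        for name in ("bottomhat_radius", "tophat_radius",
                     "dilation_radius", "erosion_radius"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("area_range", "perimeter_range", "eccentricity_range"):
            lo, hi = getattr(self, name)
            if not (lo < hi):
                raise ConfigError(f"{name} must be a nonempty (lo, hi) range")
        return self


# ---------------------------------------------------------------------------
# Flow gating
# ---------------------------------------------------------------------------

@dataclass
class GateSet:
    """Two rectangular gates on raw channels.

    Gate 1 is in (FSC, SSC) and removes debris (low scatter) and aggregates
    (high scatter); gate 2 is in (GFP, V670) and removes autofluorescent
    clumps/contaminants (high violet autofluorescence).  An event passes
    only if inside both gates.
    """

    fsc_range: tuple[float, float] = (3.0e3, 3.2e4)
    ssc_range: tuple[float, float] = (2.0e3, 3.0e4)
    gfp_range: tuple[float, float] = (0.0, np.inf)
    v670_range: tuple[float, float] = (0.0, 1.0e3)

    def validate(self) -> "GateSet":
        for name in ("fsc_range", "ssc_range", "gfp_range", "v670_range"):
            lo, hi = getattr(self, name)
            if not (lo < hi):
                raise ConfigError(f"{name} must be a nonempty (lo, hi) range")
        return self


# ---------------------------------------------------------------------------
# Lineage / event-stats options
# ---------------------------------------------------------------------------

@dataclass
class CallOptions:
    """Trace smoothing and switch-calling options."""

    smooth_window_frames: int = 7   # LOESS window used by classify_switch
    persistence_frames: int = 3     # frames above threshold required for opaque
    synchrony_frames: int = 2       # mother/daughter activation-offset bound


@dataclass
class EventStatsOptions:
    k_max: int = 4                  # tail classes k >= k_max pooled
    reps: int = 2000                # Monte-Carlo replicates
    schemes: tuple = (1, 2, 3)


@dataclass
class RunConfig:
    """Top-level pipeline configuration."""

    switch: SwitchModelConfig = field(default_factory=SwitchModelConfig)
    flow: FlowModelConfig = field(default_factory=FlowModelConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    gates: GateSet = field(default_factory=GateSet)
    call: CallOptions = field(default_factory=CallOptions)
    eventstats: EventStatsOptions = field(default_factory=EventStatsOptions)
    seed: int = 0
    outdir: str = "switchscope_out"
    log_level: str = "INFO"
    n_render_traps: int = 1         # demo traps rendered for the segment stage

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def validate(self) -> "RunConfig":
        self.switch.validate()
        self.flow.validate()
        self.segmentation.validate()
        self.gates.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuples -> lists for stable JSON round trips
        return d
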