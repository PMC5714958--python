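"""Study configuration for the simulated cue-anticipation paradigm.

The paradigm crosses four outcome categories (monetary gain, monetary loss,
pleasant face, electric shock) with four magnitude levels, yielding 16 cue
conditions.  A session consists of ``n_blocks`` blocks of ``trials_per_block``
trials; roughly one third of cues are actualized (the outcome is delivered).
Each 12 s trial is split into a 6 s cue (anticipation) period and a 6 s
outcome period, separated from the next trial by a jittered inter-trial
interval.  Only non-actualized cues enter the analyses downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

CATEGORIES: tuple[str, ...] = ("gain", "loss", "face", "shock")
LEVELS: tuple[int, ...] = (1, 2, 3, 4)
#: reward (positive valence) categories; the complement is punishment
REWARD_CATEGORIES: frozenset[str] = frozenset({"gain", "face"})
#: primary (non-monetary) modality categories; the complement is secondary
PRIMARY_CATEGORIES: frozenset[str] = frozenset({"face", "shock"})

#: canonical condition order used for 16-condition patterns and RDMs
CONDITIONS: tuple[tuple[str, int], ...] = tuple(
    (cat, lvl) for cat in CATEGORIES for lvl in LEVELS
)
CONDITION_NAMES: tuple[str, ...] = tuple(f"{c}{l}" for c, l in CONDITIONS)

NEUTRAL_RATING = 5.0


@dataclass
class NoiseSpec:
    """Additive noise model for synthetic BOLD data.

    sigma
        Marginal standard deviation of the noise, in the same (arbitrary)
        units as the injected signal amplitudes.
    ar1_rho
        Lag-1 temporal autocorrelation of the noise (AR(1) coefficient).
    smooth_fwhm_mm
        Spatial FWHM of the Gaussian correlation of the noise field, mm.
    """

    sigma: float = 1.0
    ar1_rho: float = 0.3
    smooth_fwhm_mm: float = 4.0

    def validate(self) -> None:
        if not self.sigma > 0:
            raise ValueError("noise sigma must be > 0")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be >= 0")


EFFECT_KINDS = ("value_linear", "saliency_quadratic", "category_pattern", "mean_offset")


@dataclass
class EffectSpec:
    """One injected ground-truth effect, confined to a boolean ROI.

    kind
        ``value_linear`` — voxel response scales with the trial's rating;
        ``saliency_quadratic`` — scales with (rating − 5)²;
        ``category_pattern`` — adds a fixed zero-mean, unit-norm multi-voxel
        pattern per category (invisible to the ROI mean by construction);
        ``mean_offset`` — constant cue response.
    roi
        Boolean voxel mask on the study grid.
    amplitude
        Signal amplitude in noise units.
    pattern_seed
        Extra seed component for drawing category patterns.
    shared_pattern
        When True, all subjects share the same category patterns (a
        group-consistent multi-voxel code, detectable by group-level fixed
        effects); when False (default) each subject draws independent
        patterns (an idiosyncratic code, detectable within subject only).
    orthogonalize_to_value
        category_pattern only: residualize the per-condition pattern weights
        (category indicators) against the subject's condition mean ratings,
        so the injected category code is exactly decorrelated from the value
        code at the condition level.  Without this, value and category are
        inherently correlated in the paradigm (rewards are rated high) and
        any condition-level decomposition mixes the two codes.
    """

    kind: str
    roi: np.ndarray
    amplitude: float
    pattern_seed: int = 0
    shared_pattern: bool = False
    orthogonalize_to_value: bool = False

    def validate(self, grid_shape: tuple[int, int, int]) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.roi.shape != tuple(grid_shape):
            raise ValueError(
                f"effect ROI shape {self.roi.shape} does not match grid {grid_shape}"
            )
        if not self.roi.any():
            raise ValueError("effect ROI is empty")


@dataclass
class StudyConfig:
    """Full description of a synthetic cohort; a cohort is a pure function of it."""

    n_subjects: int = 18
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0)
    tr_s: float = 2.0
    n_blocks: int = 4
    trials_per_block: int = 24
    actualized_fraction: float = 1.0 / 3.0
    iti_range_s: tuple[float, float] = (10.0, 12.0)
    trial_length_s: float = 12.0
    seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    effects: list[EffectSpec] = field(default_factory=list)
    # behavioural rating model: latent = 5 + slope[cat] * level + subject intercept + noise
    rating_slopes: dict[str, float] = field(
        default_factory=lambda: {"gain": 1.0, "loss": -1.0, "face": 1.0, "shock": -1.0}
    )
    rating_subject_sd: float = 0.3
    rating_noise_sd: float = 0.5
    missing_rate: float = 0.0
    lead_in_s: float = 12.0
    tail_s: float = 12.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)  # type: ignore[assignment]
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)  # type: ignore[assignment]
        self.iti_range_s = tuple(float(v) for v in self.iti_range_s)  # type: ignore[assignment]
        self.validate()

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def reps_per_condition(self) -> int:
        return self.n_trials // 16

    def validate(self) -> None:
        if self.n_trials % 16 != 0:
            raise ValueError(
                f"n_blocks * trials_per_block = {self.n_trials} must be divisible "
                "by 16 for a balanced 4-category x 4-level design"
            )
        if not (0.0 <= self.actualized_fraction <= 1.0):
            raise ValueError("actualized_fraction must lie in [0, 1]")
        if self.iti_range_s[0] > self.iti_range_s[1]:
            raise ValueError("iti_range_s must be (low, high) with low <= high")
        if self.tr_s <= 0 or self.trial_length_s <= 0:
            raise ValueError("tr_s and trial_length_s must be positive")
        self.noise.validate()
        for eff in self.effects:
            eff.validate(self.grid_shape)

    def subject_seeds(self) -> list[np.random.SeedSequence]:
        """Deterministic per-subject seed streams derived from the master seed."""
        return np.random.SeedSequence(self.seed).spawn(self.n_subjects)

    def affine(self) -> np.ndarray:
        """RAS+ affine built from the voxel size, origin at the grid corner."""
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff


# ---------------------------------------------------------------------------
# ROI constructors


def box_roi(grid_shape: Sequence[int], lo: Sequence[int], hi: Sequence[int]) -> np.ndarray:
    """Axis-aligned box mask with inclusive corners ``lo`` and ``hi`` (voxels)."""
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    mask[sl] = True
    return mask


def sphere_roi(
    grid_shape: Sequence[int],
    voxel_size_mm: Sequence[float],
    center_vox: Sequence[float],
    radius_mm: float,
) -> np.ndarray:
    """Sphere mask: voxels whose centers lie within ``radius_mm`` of the center.

    Distances are Euclidean in millimetres, using voxel-center coordinates.
    """
    grids = np.indices(tuple(grid_shape)).astype(float)
    d2 = np.zeros(tuple(grid_shape))
    for ax, (c, vs) in enumerate(zip(center_vox, voxel_size_mm)):
        d2 += ((grids[ax] - float(c)) * float(vs)) ** 2
    return d2 <= float(radius_mm) ** 2


# ---------------------------------------------------------------------------
# Declarative (YAML) config round-trip


def _roi_to_dict(mask: np.ndarray) -> dict:
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    box = box_roi(mask.shape, lo, hi)
    if np.array_equal(box, mask):
        return {"type": "box", "lo": lo.tolist(), "hi": hi.tolist()}
    return {"type": "voxels", "indices": idx.tolist()}


def _roi_from_dict(d: dict, grid_shape, voxel_size_mm) -> np.ndarray:
    kind = d["type"]
    if kind == "box":
        return box_roi(grid_shape, d["lo"], d["hi"])
    if kind == "sphere":
        return sphere_roi(grid_shape, voxel_size_mm, d["center_vox"], d["radius_mm"])
    if kind == "voxels":
        mask = np.zeros(tuple(grid_shape), dtype=bool)
        for ijk in d["indices"]:
            mask[tuple(ijk)] = True
        return mask
    raise ValueError(f"unknown roi type {kind!r}")


def to_yaml(config: StudyConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["noise"] = dataclasses.asdict(config.noise)
    d["effects"] = [
        {
            "kind": e.kind,
            "amplitude": e.amplitude,
            "pattern_seed": e.pattern_seed,
            "roi": _roi_to_dict(e.roi),
        }
        for e in config.effects
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def from_yaml(path) -> StudyConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    noise = NoiseSpec(**d.pop("noise", {}))
    effects = [
        EffectSpec(
            kind=e["kind"],
            amplitude=float(e["amplitude"]),
            pattern_seed=int(e.get("pattern_seed", 0)),
            roi=_roi_from_dict(e["roi"], d["grid_shape"], d["voxel_size_mm"]),
        )
        for e in d.pop("effects", [])
    ]
    d["grid_shape"] = tuple(d["grid_shape"])
    d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
    d["iti_range_s"] = tuple(d["iti_range_s"])
    return StudyConfig(noise=noise, effects=effects, **d)
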