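"""Synthetic cohorts of white-matter-segment-like volumes with planted effects.

The generator emulates the inputs of a voxel-based-morphometry outcome
study: per-subject 3-D tissue-probability volumes (continuous intensities
in [0, 1], spatially correlated noise from pre-smoothing Gaussian noise)
with spherical group-discriminative clusters planted at known locations,
plus a clinical covariate table with plausible marginals. Everything is
reproducible from a single integer seed.

Hemisphere convention: the first spatial axis is left-right; voxel
indices below the midpoint (``i < nx / 2``) are LEFT. The same convention
is used by :mod:`wmvpa.maps`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .volumes import SubjectVolume, smooth_array

__all__ = [
    "PlantedEffect",
    "CohortSpec",
    "ClinicalDistributions",
    "effect_mask",
    "generate_cohort",
    "generate_clinical_table",
]


@dataclass
class PlantedEffect:
    """A spherical cluster where the two outcome classes differ in mean intensity.

    ``delta`` is the signed difference between the positive- and
    negative-class mean intensity inside the sphere (dimensionless WM
    intensity units). The whole sphere must lie on the stated side of the
    midline plane of the first axis.
    """

    center: tuple[int, int, int]
    radius: int
    hemisphere: str
    delta: float
    shape: str = "sphere"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        if self.shape != "sphere":
            raise ValueError(f"only 'sphere' effects are supported, got {self.shape!r}")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")

    def validate_against_grid(self, grid_shape: tuple[int, int, int]) -> None:
        if len(self.center) != 3:
            raise ValueError("center must be a voxel coordinate triple")
        for c, n in zip(self.center, grid_shape):
            if not (0 <= c < n):
                raise ValueError(f"center {self.center} outside grid {grid_shape}")
        mid = grid_shape[0] / 2.0
        if self.hemisphere == "left" and not (self.center[0] + self.radius < mid):
            raise ValueError(f"effect at {self.center} (r={self.radius}) crosses the "
                             "midline but is declared 'left'")
        if self.hemisphere == "right" and not (self.center[0] - self.radius >= mid):
            raise ValueError(f"effect at {self.center} (r={self.radius}) crosses the "
                             "midline but is declared 'right'")


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_positive: int = 10
    n_negative: int = 10
    baseline: float = 0.55
    noise_sd: float = 0.05
    effects: list[PlantedEffect] = field(default_factory=list)
    smooth_fwhm_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 2 or self.n_negative < 2:
            raise ValueError("n_positive and n_negative must each be >= 2")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape components must be >= 8, got {self.grid_shape}")
        if not (0.0 <= self.baseline <= 1.0):
            raise ValueError(f"baseline must be in [0, 1], got {self.baseline}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.smooth_fwhm_mm < 0:
            raise ValueError(f"smooth_fwhm_mm must be non-negative, got {self.smooth_fwhm_mm}")
        for e in self.effects:
            e.validate_against_grid(self.grid_shape)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["effects"] = [PlantedEffect(**{**e, "center": tuple(e["center"])})
                        for e in d.get("effects", [])]
        for k in ("grid_shape", "voxel_size_mm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def effect_mask(effect: PlantedEffect, grid_shape) -> np.ndarray:
    """Boolean mask of the voxels inside a planted sphere."""
    grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, effect.center))
    return dist2 <= effect.radius ** 2


def mean_difference_field(spec: CohortSpec) -> np.ndarray:
    """Expected positive-minus-negative class mean at each voxel (before noise,
    smoothing and clipping)."""
    diff = np.zeros(spec.grid_shape)
    for e in spec.effects:
        diff[effect_mask(e, spec.grid_shape)] += e.delta
    return diff


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectVolume], pd.DataFrame]:
    """Generate one cohort of volumes plus its clinical table.

    Per subject: baseline intensity, plus ``delta`` inside every planted
    effect for positive-class subjects, plus white Gaussian noise, then
    Gaussian smoothing (so the noise acquires the spatial correlation of
    smoothed segments) and clipping to [0, 1].
    """
    ss = np.random.SeedSequence(spec.seed)
    vol_seed, clin_seed = ss.spawn(2)
    rng = np.random.default_rng(vol_seed)
    diff = mean_difference_field(spec)

    labels = [1] * spec.n_positive + [-1] * spec.n_negative
    volumes = []
    for i, label in enumerate(labels):
        data = np.full(spec.grid_shape, spec.baseline)
        if label == 1:
            data = data + diff
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
        data = smooth_array(data, spec.smooth_fwhm_mm, spec.voxel_size_mm)
        np.clip(data, 0.0, 1.0, out=data)
        volumes.append(SubjectVolume(
            data=data,
            voxel_size_mm=spec.voxel_size_mm,
            subject_id=f"S{i + 1:02d}",
            label=label,
        ))
    clinical = generate_clinical_table(
        spec.n_positive, spec.n_negative,
        seed=clin_seed,
    )
    return volumes, clinical


@dataclass
class ClinicalDistributions:
    """Marginal distribution parameters for the synthetic clinical table.

    Ages are drawn from discrete uniform ranges (inclusive, years),
    seizure frequency from a log-normal rounded up to a count per month,
    febrile-seizure history from a Bernoulli, and follow-up from a
    discrete uniform with a 12-month floor (the inclusion criterion of an
    outcome rating at least one year after surgery). Degenerate ranges
    (lo == hi) are allowed so fully constant tables can be built.
    """

    onset_range: tuple[int, int] = (1, 40)
    mri_delay_range: tuple[int, int] = (1, 30)
    surgery_delay_range: tuple[int, int] = (0, 2)
    febrile_p: float = 0.4
    freq_log_mean: float = np.log(4.0)
    freq_log_sd: float = 0.8
    followup_range: tuple[int, int] = (12, 48)

    def __post_init__(self) -> None:
        for name in ("onset_range", "mri_delay_range", "surgery_delay_range",
                     "followup_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        if self.onset_range[0] < 0 or self.mri_delay_range[0] < 0 \
                or self.surgery_delay_range[0] < 0:
            raise ValueError("age components must be non-negative")
        if self.followup_range[0] < 12:
            raise ValueError("followup_months must be >= 12 (inclusion criterion)")
        if not (0.0 <= self.febrile_p <= 1.0):
            raise ValueError(f"febrile_p must be a probability, got {self.febrile_p}")
        if self.freq_log_sd < 0:
            raise ValueError("freq_log_sd must be non-negative")


def generate_clinical_table(
    n_positive: int,
    n_negative: int,
    seed=0,
    params: ClinicalDistributions | None = None,
) -> pd.DataFrame:
    """Synthetic per-subject clinical covariates, one row per subject.

    Row order matches :func:`generate_cohort` (positives first). Ages obey
    onset <= MRI <= surgery and follow-up is at least 12 months.
    """
    if n_positive < 2 or n_negative < 2:
        raise ValueError("need at least 2 subjects per class")
    if params is None:
        params = ClinicalDistributions()
    rng = np.random.default_rng(seed)
    n = n_positive + n_negative
    onset = rng.integers(params.onset_range[0], params.onset_range[1] + 1, size=n)
    mri = onset + rng.integers(params.mri_delay_range[0],
                               params.mri_delay_range[1] + 1, size=n)
    surgery = mri + rng.integers(params.surgery_delay_range[0],
                                 params.surgery_delay_range[1] + 1, size=n)
    febrile = (rng.random(n) < params.febrile_p).astype(int)
    freq = np.maximum(1, np.round(rng.lognormal(
        params.freq_log_mean, params.freq_log_sd, size=n))).astype(int)
    fu = rng.integers(params.followup_range[0], params.followup_range[1] + 1, size=n)
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:02d}" for i in range(n)],
        "label": [1] * n_positive + [-1] * n_negative,
        "age_at_onset": onset,
        "age_at_mri": mri,
        "age_at_surgery": surgery,
        "febrile": febrile,
        "seizure_freq_per_month": freq,
        "followup_months": fu,
    })
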