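"""Discrimination maps: SVM weights back-projected into voxel space.

A positive weight marks a voxel where larger white-matter intensity
favours the positive (favorable-outcome) class; a negative weight the
converse. Lateralization of the weight distribution is quantified with
df=1 goodness-of-fit chi-square tests against an even 50/50 split,
computed on voxel counts by default or on summed absolute weight.

Hemisphere convention (shared with :mod:`wmvpa.synthetic`): the first
spatial axis is left-right and indices below the midpoint are LEFT. For
an odd first-axis size the exact midplane belongs to neither hemisphere
and is excluded from the lateralization counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .svm import SVMModel

__all__ = [
    "DiscriminationMap",
    "LateralizationSummary",
    "weights_to_volume",
    "fold_average_map",
    "lateralization_summary",
]


@dataclass
class DiscriminationMap:
    """Signed weight volume; zero outside the selected voxels."""

    volume: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    provenance: str  # {"final_refit", "fold_average"}


def _place(w: np.ndarray, columns: np.ndarray, voxel_index_map: np.ndarray,
           grid_shape) -> np.ndarray:
    columns = np.asarray(columns, dtype=int)
    coords = voxel_index_map[columns]
    if (coords < 0).any() or (coords >= np.asarray(grid_shape)).any():
        raise ValueError("selected voxel outside the grid")
    vol = np.zeros(grid_shape)
    vol[tuple(coords.T)] = w
    return vol


def weights_to_volume(
    model: SVMModel,
    voxel_index_map: np.ndarray,
    grid_shape,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> DiscriminationMap:
    """Back-project a trained model's weight vector into the 3-D grid."""
    cols = model.selected_columns
    if cols is None:
        cols = np.arange(model.w.shape[0])
    if len(cols) != model.w.shape[0]:
        raise ValueError("model weight length does not match its selected columns")
    return DiscriminationMap(
        volume=_place(model.w, cols, voxel_index_map, grid_shape),
        voxel_size_mm=tuple(voxel_size_mm),
        provenance="final_refit",
    )


def fold_average_map(
    folds,
    voxel_index_map: np.ndarray,
    grid_shape,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> DiscriminationMap:
    """Average the per-fold weight back-projections of a cross-validation run.

    Alternative to the all-data refit map: each outer fold's weight
    vector is placed in the grid and the mean across folds is returned.
    """
    acc = np.zeros(grid_shape)
    n = 0
    for rec in folds:
        if rec.w is None:
            raise ValueError("fold records carry no weight vectors")
        acc += _place(rec.w, rec.columns, voxel_index_map, grid_shape)
        n += 1
    if n == 0:
        raise ValueError("no folds given")
    return DiscriminationMap(volume=acc / n, voxel_size_mm=tuple(voxel_size_mm),
                             provenance="fold_average")


def _chisq_5050(n1: float, n2: float) -> tuple[float, float]:
    """df=1 goodness-of-fit chi-square against an even split, no continuity
    correction."""
    total = n1 + n2
    if total == 0:
        return 0.0, 1.0
    expected = total / 2.0
    chi2 = (n1 - expected) ** 2 / expected + (n2 - expected) ** 2 / expected
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class LateralizationSummary:
    """Hemisphere-by-sign breakdown of a discrimination map with chi-square tests.

    ``counts`` and ``weight_sums`` are keyed by (hemisphere, sign) with
    hemisphere in {"LH", "RH"} and sign in {"positive", "negative"}.
    ``tests`` maps each comparison name to (chi2, p):
    ``lh_vs_rh`` on hemisphere totals, ``pos_vs_neg`` on sign totals, and
    ``lh_vs_rh_positive`` / ``lh_vs_rh_negative`` within each sign.
    """

    counts: dict
    weight_sums: dict
    tests: dict
    unit: str

    @property
    def total_nonzero(self) -> int:
        return int(sum(self.counts.values()))


def lateralization_summary(dmap: DiscriminationMap, unit: str = "count") -> LateralizationSummary:
    """Quantify left/right and positive/negative weight asymmetry.

    ``unit`` chooses what enters the chi-square: "count" (number of
    non-zero voxels, default — the natural chi-square object) or
    "weight" (summed absolute weight).
    """
    if unit not in ("count", "weight"):
        raise ValueError(f"unit must be 'count' or 'weight', got {unit!r}")
    vol = dmap.volume
    if not np.any(vol != 0):
        raise ValueError("map has no non-zero voxels")
    nx = vol.shape[0]
    left = np.zeros_like(vol, dtype=bool)
    right = np.zeros_like(vol, dtype=bool)
    left[: nx // 2] = True
    right[-(nx // 2):] = True  # odd nx: midplane excluded from both

    counts, sums = {}, {}
    for hemi, hmask in (("LH", left), ("RH", right)):
        for sign, smask in (("positive", vol > 0), ("negative", vol < 0)):
            sel = hmask & smask
            counts[(hemi, sign)] = int(sel.sum())
            sums[(hemi, sign)] = float(np.abs(vol[sel]).sum())
    meas = counts if unit == "count" else sums
    lh = meas[("LH", "positive")] + meas[("LH", "negative")]
    rh = meas[("RH", "positive")] + meas[("RH", "negative")]
    pos = meas[("LH", "positive")] + meas[("RH", "positive")]
    neg = meas[("LH", "negative")] + meas[("RH", "negative")]
    tests = {
        "lh_vs_rh": _chisq_5050(lh, rh),
        "pos_vs_neg": _chisq_5050(pos, neg),
        "lh_vs_rh_positive": _chisq_5050(meas[("LH", "positive")],
                                         meas[("RH", "positive")]),
        "lh_vs_rh_negative": _chisq_5050(meas[("LH", "negative")],
                                         meas[("RH", "negative")]),
    }
    return LateralizationSummary(counts=counts, weight_sums=sums, tests=tests, unit=unit)
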