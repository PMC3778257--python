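"""Model/Results surface over the nested-CV outcome-prediction pipeline.

:class:`SurgicalOutcomeSVM` is built from a cohort (volumes plus clinical
table, a cohort directory, or a synthetic recipe); ``fit()`` runs the
nested leave-one-subject-out cross-validation and returns a
:class:`SurgicalOutcomeResults` carrying the out-of-fold decision values,
the confusion statistics with their balanced-posterior credible interval,
ROC/PR curves, discrimination maps and the clinical association tests —
with a ``summary()`` in the style of the study's performance table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clinical as clinical_stats
from .crossval import (CVResult, DEFAULT_GRID, HyperparameterGrid, final_model,
                       outer_loso)
from .maps import (DiscriminationMap, LateralizationSummary, fold_average_map,
                   lateralization_summary, weights_to_volume)
from .metrics import (ConfusionSummary, PosteriorInterval,
                      balanced_posterior_interval, confusion_from_decisions,
                      precision_recall_points, roc_points_and_auc, round_half_up)
from .svm import SVMModel
from .synthetic import CohortSpec, generate_cohort
from .volumes import CohortDataset, build_dataset, default_mask, gaussian_smooth

__all__ = ["SurgicalOutcomeSVM", "SurgicalOutcomeResults"]


class SurgicalOutcomeSVM:
    """Nested-LOSO linear-SVM outcome classifier for a cohort of WM volumes.

    Parameters
    ----------
    dataset : CohortDataset
        Flattened cohort (see :func:`wmvpa.volumes.build_dataset`).
    grid : HyperparameterGrid, optional
        Search grid over (C, k); defaults to the package grid.
    sd, denominator : str
        Fisher-score options (see :func:`wmvpa.features.fisher_scores`).
    """

    def __init__(self, dataset: CohortDataset,
                 grid: HyperparameterGrid = DEFAULT_GRID,
                 sd: str = "population", denominator: str = "sd") -> None:
        self.dataset = dataset
        self.grid = grid
        self.sd = sd
        self.denominator = denominator

    @classmethod
    def from_volumes(cls, volumes, clinical=None, smooth_fwhm_mm: float = 0.0,
                     mask_threshold: float = 0.05, **kwargs) -> "SurgicalOutcomeSVM":
        """Build from raw volumes: optional smoothing, masking, flattening."""
        if smooth_fwhm_mm > 0:
            volumes = [gaussian_smooth(v, smooth_fwhm_mm) for v in volumes]
        mask = default_mask(volumes, threshold=mask_threshold)
        return cls(build_dataset(volumes, mask, clinical), **kwargs)

    @classmethod
    def from_synthetic(cls, spec: CohortSpec, mask_threshold: float = 0.05,
                       **kwargs) -> "SurgicalOutcomeSVM":
        """Build from a synthetic-cohort recipe (volumes are already smoothed)."""
        volumes, clinical = generate_cohort(spec)
        return cls.from_volumes(volumes, clinical, smooth_fwhm_mm=0.0,
                                mask_threshold=mask_threshold, **kwargs)

    def fit(self, level: float = 0.95, draws: int = 10 ** 6, seed=0,
            refit: bool = True) -> "SurgicalOutcomeResults":
        """Run the nested cross-validation (and, optionally, the all-data refit)."""
        cv = outer_loso(self.dataset, self.grid, sd=self.sd,
                        denominator=self.denominator)
        confusion = confusion_from_decisions(cv.y_true, cv.decision_value)
        interval = balanced_posterior_interval(confusion, level=level,
                                               draws=draws, seed=seed)
        fm = cols = hyper = None
        if refit:
            fm, cols, hyper = final_model(self.dataset, self.grid, sd=self.sd,
                                          denominator=self.denominator)
        return SurgicalOutcomeResults(
            model=self, cv_result=cv, confusion=confusion, interval=interval,
            final_svm=fm, final_columns=cols, final_hyperparameters=hyper,
        )


@dataclass
class SurgicalOutcomeResults:
    """Fitted results: out-of-fold predictions, statistics, maps, diagnostics."""

    model: SurgicalOutcomeSVM
    cv_result: CVResult
    confusion: ConfusionSummary
    interval: PosteriorInterval
    final_svm: SVMModel | None = None
    final_columns: np.ndarray | None = field(default=None, repr=False)
    final_hyperparameters: tuple | None = None

    # -- per-subject table ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return self.cv_result.to_frame()

    # -- curves -----------------------------------------------------------
    def roc(self):
        return roc_points_and_auc(self.cv_result.y_true, self.cv_result.decision_value)

    def precision_recall(self):
        return precision_recall_points(self.cv_result.y_true,
                                       self.cv_result.decision_value)

    # -- maps -------------------------------------------------------------
    def discrimination_map(self, provenance: str = "final_refit") -> DiscriminationMap:
        ds = self.model.dataset
        if provenance == "final_refit":
            if self.final_svm is None:
                raise ValueError("fit(refit=True) is required for the refit map")
            return weights_to_volume(self.final_svm, ds.voxel_index_map,
                                     ds.grid_shape, ds.voxel_size_mm)
        if provenance == "fold_average":
            return fold_average_map(self.cv_result.folds, ds.voxel_index_map,
                                    ds.grid_shape, ds.voxel_size_mm)
        raise ValueError(f"unknown provenance {provenance!r}")

    def lateralization(self, unit: str = "count",
                       provenance: str = "final_refit") -> LateralizationSummary:
        return lateralization_summary(self.discrimination_map(provenance), unit=unit)

    # -- clinical associations -------------------------------------------
    def weighting_correlations(self, characteristics=("age_at_onset",
                                                      "followup_months",
                                                      "febrile",
                                                      "seizure_freq_per_month"),
                               weighting: str = "decision") -> pd.DataFrame:
        """Spearman correlation of per-subject weighting with covariates.

        ``weighting="decision"`` uses the out-of-fold decision-value
        magnitude (the printed per-subject quantity); ``"alpha"`` uses
        the final model's dual coefficients.
        """
        clin = self.model.dataset.clinical
        if clin is None:
            raise ValueError("dataset has no clinical table")
        if weighting == "decision":
            w = np.abs(self.cv_result.decision_value)
        elif weighting == "alpha":
            if self.final_svm is None:
                raise ValueError("fit(refit=True) is required for alpha weighting")
            w = self.final_svm.alpha
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        rows = []
        for char in characteristics:
            rho, p = clinical_stats.weighting_covariate_correlation(
                w, clin[char].to_numpy(dtype=float))
            rows.append({"characteristic": char, "rho": rho, "p": p})
        return pd.DataFrame(rows)

    def sv_vs_nonsv(self, **kwargs) -> pd.DataFrame:
        if self.final_svm is None:
            raise ValueError("fit(refit=True) is required for the SV partition")
        return clinical_stats.sv_vs_nonsv_comparison(
            self.final_svm.alpha, self.model.dataset.clinical, **kwargs)

    # -- plotting ----------------------------------------------------------
    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt
        points, auc = self.roc()
        fpr, tpr = zip(*points)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, drawstyle="steps-post", label=f"AUC = {auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax

    # -- summary -----------------------------------------------------------
    def summary(self) -> str:
        c, ci = self.confusion, self.interval
        _, auc = self.roc()
        pct = lambda x: f"{round_half_up(100 * x):.0f}%"
        lines = [
            "Nested LOSO outcome classification",
            "=" * 44,
            f"Subjects                    {len(self.cv_result.subject_ids):>8}"
            f"  ({c.TP + c.FN} FO / {c.TN + c.FP} Non-FO)",
            f"Sensitivity                 {pct(c.sensitivity):>8}",
            f"Specificity                 {pct(c.specificity):>8}",
            f"Balanced accuracy           {pct(c.balanced_accuracy):>8}",
            f"  {ci.level:.0%} credible interval     "
            f"[{pct(ci.lower)}, {pct(ci.upper)}]",
            f"Positive predictive value   {pct(c.ppv):>8}",
            f"Positive likelihood ratio   "
            f"{'inf' if np.isinf(c.positive_likelihood_ratio) else format(round_half_up(c.positive_likelihood_ratio, 2), '.2f'):>8}",
            f"F-measure                   {round_half_up(c.f_measure, 2):>8.2f}",
            f"Area under ROC curve        {round_half_up(auc, 2):>8.2f}",
        ]
        if self.final_hyperparameters is not None:
            C, k = self.final_hyperparameters
            lines.append(f"Final refit (C, k)          {C:>8g}, {k} voxels")
        return "\n".join(lines)
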