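"""Fisher-criterion voxel scoring and top-k selection.

The score of voxel v is the squared distance between the class means
relative to the summed intra-class standard deviations,

    f_v = (mu_pos - mu_neg)^2 / (sd_pos + sd_neg),

with the denominator a sum of standard deviations (not variances); the
conventional variance-sum ratio is available via ``denominator="variance"``.
Scores are always computed from a training subset only — the callers in
:mod:`wmvpa.crossval` enforce this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FisherScores", "fisher_scores", "rank_and_select"]


@dataclass
class FisherScores:
    """Per-voxel scores with the class means and standard deviations behind them."""

    scores: np.ndarray
    mu_pos: np.ndarray
    mu_neg: np.ndarray
    sd_pos: np.ndarray
    sd_neg: np.ndarray


def fisher_scores(
    X: np.ndarray,
    y: np.ndarray,
    sd: str = "population",
    denominator: str = "sd",
) -> FisherScores:
    """Fisher criterion per feature column.

    Parameters
    ----------
    X : (n_subjects, n_voxels) array
    y : (n_subjects,) array of +1 / -1 labels
    sd : {"population", "sample"}
        Divisor n (default) or n-1 for the class standard deviations. The
        score is only used for ranking, where the two rarely differ.
    denominator : {"sd", "variance"}
        Sum of standard deviations (default) or sum of variances.

    Zero-denominator columns get score 0 when the class means agree and
    otherwise the maximum finite score, keeping the ranking total.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if sd not in ("population", "sample"):
        raise ValueError(f"sd must be 'population' or 'sample', got {sd!r}")
    if denominator not in ("sd", "variance"):
        raise ValueError(f"denominator must be 'sd' or 'variance', got {denominator!r}")
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 members for Fisher scoring")
    ddof = 0 if sd == "population" else 1
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    sd_p, sd_n = pos.std(axis=0, ddof=ddof), neg.std(axis=0, ddof=ddof)
    num = (mu_p - mu_n) ** 2
    if denominator == "sd":
        den = sd_p + sd_n
    else:
        den = sd_p ** 2 + sd_n ** 2
    scores = np.zeros_like(num)
    ok = den > 0
    scores[ok] = num[ok] / den[ok]
    degenerate = ~ok & (num > 0)
    if degenerate.any():
        finite_max = scores[ok].max() if ok.any() and scores[ok].max() > 0 else 1.0
        scores[degenerate] = finite_max
    return FisherScores(scores=scores, mu_pos=mu_p, mu_neg=mu_n, sd_pos=sd_p, sd_neg=sd_n)


def rank_and_select(scores: FisherScores | np.ndarray, k: int) -> np.ndarray:
    """Column indices of the k largest scores, by descending score.

    Ties are broken by ascending column index, so selection is fully
    deterministic.
    """
    s = scores.scores if isinstance(scores, FisherScores) else np.asarray(scores)
    n = s.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = np.argsort(-s, kind="stable")
    return order[:k]
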