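"""ROI summaries and brain-behaviour correlation.

Significant clusters from the group comparison become region-of-interest
masks; each subject's mean metric inside an ROI is correlated (Pearson)
with the addiction-severity score.  Following the study design, the
correlation is computed within the patient group only and no multiplicity
adjustment is applied across ROIs — both facts are recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RoiSummary", "CorrelationResult", "roi_means", "pearson", "correlation_table"]


@dataclass
class RoiSummary:
    """Per-subject mean of one metric over one ROI."""

    roi_id: str
    metric: str
    values: np.ndarray  # one value per subject
    n_nan_voxels: int = 0


@dataclass
class CorrelationResult:
    """Pearson correlation with its two-tailed p-value."""

    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def roi_means(
    metric_volumes: np.ndarray,
    roi_mask: np.ndarray,
    roi_id: str = "roi",
    metric: str = "mk",
) -> RoiSummary:
    """Unweighted per-subject mean of a metric over an ROI.

    ``metric_volumes`` has shape (n_subjects,) + grid.  NaN voxels inside
    the mask (e.g. failed fits) are excluded from the mean; their count is
    reported.
    """
    vols = np.asarray(metric_volumes, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    if vols.shape[1:] != mask.shape:
        raise ValueError("metric volumes and ROI mask grids differ")
    vals = vols[:, mask]
    n_nan = int(np.isnan(vals).sum())
    means = np.nanmean(vals, axis=1)
    return RoiSummary(roi_id=roi_id, metric=metric, values=means, n_nan_voxels=n_nan)


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Sample Pearson correlation with the exact t-based two-tailed p.

    p is derived from ``t = r * sqrt((n-2)/(1-r^2))`` on n-2 degrees of
    freedom.  Requires n >= 3 and nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def correlation_table(
    summaries: list[RoiSummary], scores: np.ndarray
) -> pd.DataFrame:
    """Correlate every ROI summary against one score vector.

    Output columns: roi_id, metric, r, p, n (no multiple-comparison
    adjustment; judged at p < 0.05 as in the study design).
    """
    rows = []
    for s in summaries:
        res = pearson(np.asarray(scores, dtype=float), s.values)
        rows.append(
            {"roi_id": s.roi_id, "metric": s.metric, "r": res.r, "p": res.p, "n": res.n}
        )
    return pd.DataFrame(rows)
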