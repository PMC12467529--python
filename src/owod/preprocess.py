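"""Cohort cleaning: plausibility filtering, mode imputation, standardization,
class balancing.

Values outside a feature's plausible range are implausible data-entry
artifacts (e.g. body weights below 40 kg) and are masked to missing rather
than dropping the row; missing values are then imputed with the per-feature
mode.  The mode of a continuous feature is computed on values rounded to the
feature's bin width so that coarse clinical graining ("most people weigh
60 kg") wins over float noise; ties break to the smallest value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog
from .cohort import CohortTable


@dataclass
class PreprocessReport:
    filtered: dict[str, int] = field(default_factory=dict)
    imputed: dict[str, int] = field(default_factory=dict)
    imputation_value: dict[str, float] = field(default_factory=dict)
    standardized: bool = False

    def to_dict(self) -> dict:
        return {
            "filtered": dict(self.filtered),
            "imputed": dict(self.imputed),
            "imputation_value": dict(self.imputation_value),
            "standardized": self.standardized,
        }


def filter_outliers(
    cohort: CohortTable, catalog: FeatureCatalog
) -> tuple[CohortTable, PreprocessReport]:
    """Mask values strictly outside each feature's plausible range.

    Row count is preserved; out-of-range cells become missing.
    """
    out = cohort.copy()
    report = PreprocessReport()
    for col in out.features:
        if col not in catalog:
            raise KeyError(f"feature {col!r} present in cohort but not in catalog")
        spec = catalog[col]
        vals = out.data[col]
        bad = vals.notna() & ((vals < spec.plausible_min) | (vals > spec.plausible_max))
        report.filtered[col] = int(bad.sum())
        out.data.loc[bad, col] = np.nan
    return out, report


def feature_mode(values: pd.Series, bin_width: float | None = None) -> float:
    """Mode of the non-missing values, optionally on a rounded grid.

    Ties break to the smallest value so the result is deterministic.
    """
    v = values.dropna().to_numpy(dtype=float)
    if v.size == 0:
        raise ValueError("cannot take the mode of an all-missing column")
    if bin_width is not None and bin_width > 0:
        v = np.round(v / bin_width) * bin_width
    uniq, counts = np.unique(v, return_counts=True)
    return float(uniq[np.flatnonzero(counts == counts.max())[0]])


def impute_mode(
    cohort: CohortTable, bin_widths: dict[str, float] | None = None
) -> tuple[CohortTable, PreprocessReport]:
    """Fill missing cells with each feature's mode.

    ``bin_widths`` optionally maps acronyms to the rounding grid used for
    the mode of continuous features.
    """
    out = cohort.copy()
    report = PreprocessReport()
    for col in out.features:
        vals = out.data[col]
        missing = vals.isna()
        if vals.notna().sum() == 0:
            raise ValueError(f"feature {col!r} is entirely missing; cannot impute")
        width = None if bin_widths is None else bin_widths.get(col)
        mode = feature_mode(vals, width)
        report.imputed[col] = int(missing.sum())
        report.imputation_value[col] = mode
        out.data.loc[missing, col] = mode
    return out, report


def standardize(
    cohort: CohortTable,
) -> tuple[CohortTable, dict[str, tuple[float, float]]]:
    """Z-score every feature column (sample SD, n-1 denominator).

    Returns the fitted (mean, sd) pairs keyed by acronym so the transform
    can be inverted with :func:`destandardize`.
    """
    out = cohort.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in out.features:
        v = out.data[col]
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"feature {col!r} has zero standard deviation")
        out.data[col] = (v - mean) / sd
        params[col] = (mean, sd)
    return out, params


def destandardize(
    cohort: CohortTable, params: dict[str, tuple[float, float]]
) -> CohortTable:
    out = cohort.copy()
    for col, (mean, sd) in params.items():
        out.data[col] = out.data[col] * sd + mean
    return out


def balance_classes(cohort: CohortTable, seed: int) -> CohortTable:
    """Randomly down-sample the majority class to the minority class size."""
    if cohort.labels is None:
        raise ValueError("balancing requires labels")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(cohort.is_positive().to_numpy())
    neg_idx = np.flatnonzero((cohort.labels == cohort.negative_label).to_numpy())
    n = min(len(pos_idx), len(neg_idx))
    keep = np.sort(
        np.r_[
            rng.choice(pos_idx, size=n, replace=False),
            rng.choice(neg_idx, size=n, replace=False),
        ]
    )
    return cohort.subset(keep)


def drop_incomplete(cohort: CohortTable) -> CohortTable:
    """Optionally drop rows that still contain missing values."""
    mask = cohort.data.notna().all(axis=1)
    return cohort.subset(mask)
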