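"""Estimation of per-feature objective-class parameters.

For each feature the training data yields three anchors:

* target level ``Tmi`` — midpoint of the histogram bin where the
  positive-class count most exceeds the negative-class count (the peak of
  the class-histogram difference curve);
* acceptable level ``Ai`` — a tolerable value one (configurable ``k``)
  standard deviation from the feature average, or an explicit per-feature
  table entry; it also serves as the normalization divisor for distances;
* threshold value ``Tsmi`` — a 5 % (configurable) deviation from ``Tmi``;
  the record made of all thresholds is scored to obtain the classification
  cut-off.

Parameters are estimated on training data only and frozen for scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .catalog import BinRule, FeatureCatalog
from .cohort import CohortTable
from .config import RunConfig

# Cap on the number of auto (Freedman-Diaconis) bins; very long tails
# otherwise produce thousands of nearly empty bins.
_MAX_AUTO_BINS = 200


@dataclass
class ClassHistogramPair:
    """Positive- and negative-class counts over shared bin edges."""

    feature: str
    bin_edges: np.ndarray
    pos_counts: np.ndarray
    neg_counts: np.ndarray

    @property
    def n_pos(self) -> int:
        return int(self.pos_counts.sum())

    @property
    def n_neg(self) -> int:
        return int(self.neg_counts.sum())

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class FeatureParams:
    tmi: float
    ai: float
    tsmi: float

    @property
    def amax(self) -> float:
        """Normalization divisor; identified with the acceptable level."""
        return self.ai


@dataclass
class ObjectiveParams:
    per_feature: dict[str, FeatureParams] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.per_feature)

    def __getitem__(self, acronym: str) -> FeatureParams:
        return self.per_feature[acronym]

    def to_dict(self) -> dict:
        return {
            a: {"tmi": p.tmi, "ai": p.ai, "tsmi": p.tsmi}
            for a, p in self.per_feature.items()
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ObjectiveParams":
        return cls(
            {a: FeatureParams(d["tmi"], d["ai"], d["tsmi"]) for a, d in doc.items()}
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ObjectiveParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _resolve_edges(pooled: np.ndarray, rule: BinRule) -> np.ndarray:
    vmin, vmax = float(pooled.min()), float(pooled.max())
    if rule.kind == "fixed_width":
        w = float(rule.width)
        # Anchor edges so that bin midpoints fall on multiples of the width.
        kmin = int(np.floor(vmin / w + 0.5))
        kmax = int(np.ceil(vmax / w - 0.5))
        return (np.arange(kmin, kmax + 2) - 0.5) * w
    if rule.kind == "fixed_count":
        return np.linspace(vmin, vmax, int(rule.count) + 1)
    # auto: Freedman-Diaconis on the pooled sample
    if vmin == vmax:
        raise ValueError(
            "all values identical; auto binning impossible - use a fixed width"
        )
    edges = np.histogram_bin_edges(pooled, bins="fd")
    if len(edges) - 1 > _MAX_AUTO_BINS:
        edges = np.linspace(vmin, vmax, _MAX_AUTO_BINS + 1)
    return edges


def build_class_histograms(
    pos_values: np.ndarray,
    neg_values: np.ndarray,
    bin_rule: BinRule | None = None,
    feature: str = "",
) -> ClassHistogramPair:
    """Bin both classes on shared edges spanning the pooled range.

    Bins are half-open ``[e_j, e_{j+1})`` with the last bin closed, so each
    class's counts sum to its sample size.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(f"{feature or 'feature'}: both classes need values")
    edges = _resolve_edges(np.r_[pos, neg], bin_rule or BinRule())
    pos_counts, _ = np.histogram(pos, bins=edges)
    neg_counts, _ = np.histogram(neg, bins=edges)
    return ClassHistogramPair(feature, edges, pos_counts, neg_counts)


def target_value(hist: ClassHistogramPair) -> float:
    """Midpoint of the bin maximizing (positive - negative) counts.

    Ties break to the lowest qualifying bin.  If no bin has a positive
    difference the classes are indistinguishable in this feature.
    """
    diff = hist.pos_counts.astype(np.int64) - hist.neg_counts.astype(np.int64)
    best = int(np.argmax(diff))  # argmax returns the first (lowest) maximum
    if diff[best] <= 0:
        raise ValueError(
            f"{hist.feature or 'feature'}: no bin where the positive class "
            "exceeds the negative class; target level undefined"
        )
    return float(hist.midpoints[best])


def acceptable_level(
    values: np.ndarray,
    tmi: float,
    *,
    policy: str = "mean_sd",
    k: float = 1.0,
    reference_mean: float | None = None,
    table_value: float | None = None,
) -> float:
    """Acceptable level for one feature.

    ``table`` policy returns the supplied per-feature value.  ``mean_sd``
    places the level ``k`` standard deviations from the sample mean of
    ``values``, on the opposite side of ``reference_mean`` (default: the
    sample's own mean) from the target, so that target and acceptable
    anchors straddle the bulk of the data.
    """
    if policy == "table":
        if table_value is None:
            raise ValueError("table policy requires a table value")
        ai = float(table_value)
    elif policy == "mean_sd":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        if not sd > 0:
            raise ValueError("mean_sd policy requires SD > 0")
        ref = mean if reference_mean is None else float(reference_mean)
        sign = 1.0 if tmi <= ref else -1.0
        ai = mean + sign * k * sd
    else:
        raise ValueError(f"unknown acceptable-level policy: {policy!r}")
    if ai == tmi:
        raise ValueError("acceptable level equals the target level")
    if ai <= 0:
        raise ValueError("acceptable level must be positive (it divides distances)")
    return ai


def threshold_value(tmi: float, frac: float = 0.05, direction: str = "below") -> float:
    """Threshold ``Tsmi``: a ``frac`` deviation below (default) or above Tmi."""
    if not 0.0 < frac < 1.0:
        raise ValueError("threshold fraction must be in (0, 1)")
    if direction == "below":
        return (1.0 - frac) * tmi
    if direction == "above":
        return (1.0 + frac) * tmi
    raise ValueError("direction must be 'below' or 'above'")


def fit_objective_params(
    cohort: CohortTable,
    catalog: FeatureCatalog,
    config: RunConfig | None = None,
) -> ObjectiveParams:
    """Estimate target, acceptable, and threshold levels for every feature.

    Uses the labeled training cohort only; the acceptable level's ``mean_sd``
    policy takes the positive class as its sample and the pooled mean as the
    side reference.
    """
    config = config or RunConfig()
    if cohort.labels is None:
        raise ValueError("fitting objective parameters requires labels")
    features = config.features or cohort.features
    pos_mask = cohort.is_positive().to_numpy()

    params: dict[str, FeatureParams] = {}
    for feat in features:
        if feat not in cohort.features:
            raise KeyError(f"feature {feat!r} not present in cohort")
        col = cohort.data[feat].to_numpy(dtype=float)
        pos = col[pos_mask & np.isfinite(col)]
        neg = col[~pos_mask & np.isfinite(col)]
        rule = _bin_rule_for(feat, catalog, config)
        hist = build_class_histograms(pos, neg, rule, feature=feat)
        tmi = target_value(hist)
        if config.acceptable_policy == "table":
            if feat not in config.acceptable_table:
                raise KeyError(f"acceptable_table has no entry for {feat!r}")
            ai = acceptable_level(
                pos, tmi, policy="table", table_value=config.acceptable_table[feat]
            )
        else:
            pooled = col[np.isfinite(col)]
            ai = acceptable_level(
                pos,
                tmi,
                policy="mean_sd",
                k=config.acceptable_k,
                reference_mean=float(pooled.mean()),
            )
        tsmi = threshold_value(tmi, config.threshold_frac, config.threshold_direction)
        params[feat] = FeatureParams(tmi=tmi, ai=ai, tsmi=tsmi)
    return ObjectiveParams(params)


def _bin_rule_for(feat: str, catalog: FeatureCatalog, config: RunConfig) -> BinRule:
    if feat in config.bin_overrides:
        return BinRule(**config.bin_overrides[feat])
    if feat in catalog:
        return catalog[feat].bin_rule
    return BinRule()
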