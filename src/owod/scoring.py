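"""The optimized weighted objective distance (OWOD) scoring chain.

For one record with current values :math:`C_i`, target levels :math:`T_{mi}`
and acceptable levels :math:`A_i`:

1. raw distances ``dTC = |Tmi - Ci|``, ``dTA = |Tmi - Ai|``;
2. percent-normalized distances ``ndTC = 100*dTC/Ai``, ``ndTA = 100*dTA/Ai``;
3. distance ratios ``rTC = ndTC/(ndTC+ndTA)``, ``rTA`` complementary;
4. per-feature binary entropy ``H_i`` of ``(rTC, rTA)``; the balanced-class
   entropy is exactly 1, so the information gain is ``G = 1 - mean(H_i)``;
5. weights ``W_i`` proportional to the entropy/gain ratios ``H_i/G``
   (normalized to sum 1);
6. weighted components ``owoD_i = W_i * |ndTA - ndTC|``;
7. per-record min-max normalization of the components;
8. OWOD = mean of the normalized components, in [0, 1].

A record is classified positive when its OWOD does not exceed the cut-off
OWOD, which is the score of the pseudo-record whose current values are the
per-feature thresholds ``Tsmi``.

Weights are per-record quantities: they derive from the record's own
distance ratios, so no weight training takes place — "fitting" the model
means estimating the objective parameters only.  All arithmetic is carried
at full precision; nothing is rounded between steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .objective import ObjectiveParams

_EPS = 1e-12


# ---------------------------------------------------------------------------
# scalar / per-feature primitives


@dataclass
class DistanceEntry:
    """Distances and ratios of one feature for one record."""

    dtc: float
    dta: float
    ndtc: float
    ndta: float
    rtc: float
    rta: float


def feature_distances(ci: float, tmi: float, ai: float) -> DistanceEntry:
    """Raw and percent-normalized distances plus their ratios.

    The acceptable level doubles as the normalization divisor, so it must
    be positive.  When both normalized distances vanish the ratios default
    to (0.5, 0.5).
    """
    if ai <= 0:
        raise ValueError("acceptable level must be positive (normalization divisor)")
    dtc = abs(tmi - ci)
    dta = abs(tmi - ai)
    ndtc = 100.0 * dtc / ai
    ndta = 100.0 * dta / ai
    total = ndtc + ndta
    if total > 0:
        rtc = ndtc / total
        rta = ndta / total
    else:
        rtc = rta = 0.5
    return DistanceEntry(dtc, dta, ndtc, ndta, rtc, rta)


def binary_entropy(p: float, q: float) -> float:
    """Shannon entropy of a two-outcome distribution, in bits.

    ``p`` and ``q`` must be complementary probabilities; 0*log2(0) = 0.
    """
    if p < 0 or q < 0 or abs(p + q - 1.0) > 1e-9:
        raise ValueError("arguments must be non-negative and sum to 1")
    h = 0.0
    if p > 0:
        h -= p * np.log2(p)
    if q > 0:
        h -= q * np.log2(q)
    return float(h)


def balanced_class_entropy(na: int) -> tuple[float, float, float]:
    """Entropy of the balanced two-class prior over ``na`` attributes.

    Both class shares equal ``na/2`` out of ``na``, so the entropy is
    exactly 1 bit regardless of ``na``.  Returns (EPC, Oc+, Nc-).
    """
    if na < 1:
        raise ValueError("need at least one attribute")
    half = na / 2.0
    return 1.0, half, half


def information_gain(entropies: np.ndarray, epc: float = 1.0) -> tuple[float, float]:
    """Aggregate entropy ``IGCa`` (mean of the per-feature entropies, since
    each feature's ratio pair sums to 1) and the gain ``G = EPC - IGCa``."""
    h = np.asarray(entropies, dtype=float)
    if h.size < 1:
        raise ValueError("need at least one feature entropy")
    igca = float(h.mean())
    return igca, float(epc - igca)


def split_information(category_counts) -> float:
    """Entropy of a categorical split (bits); auxiliary, not in the chain."""
    counts = np.asarray(category_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("category counts must be positive")
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def gain_ratio(ig: float, split_info: float) -> float:
    """Information gain divided by split information; auxiliary."""
    if split_info <= 0:
        raise ValueError("split information must be positive (multiple categories)")
    return ig / split_info


def feature_weights(entropies: np.ndarray, gain: float) -> np.ndarray:
    """Normalized weights from entropy/gain ratios ``R_i = H_i / G``.

    The gain cancels in the normalization, but a non-positive gain means
    every feature sits at maximum entropy and carries no signal.
    """
    h = np.asarray(entropies, dtype=float)
    if gain <= 0:
        raise ValueError(
            "information gain is not positive: features carry no discriminative signal"
        )
    r = h / gain
    total = r.sum()
    if total <= 0:
        # every entropy is zero: all features sit exactly on an anchor
        return np.full(h.size, 1.0 / h.size)
    return r / total


def owod_components(weights: np.ndarray, ndtc: np.ndarray, ndta: np.ndarray) -> np.ndarray:
    """Weighted distance gaps ``owoD_i = W_i * |ndTA - ndTC|``."""
    return np.asarray(weights) * np.abs(np.asarray(ndta) - np.asarray(ndtc))


def normalize_components(components: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max normalize components within the record.

    Returns the normalized vector and a degeneracy flag: when all
    components are equal the normalization is undefined and every entry
    is set to the neutral 0.5.
    """
    c = np.asarray(components, dtype=float)
    if c.size < 2:
        raise ValueError("need at least two components to normalize")
    lo, hi = c.min(), c.max()
    if hi - lo <= _EPS:
        return np.full(c.size, 0.5), True
    return (c - lo) / (hi - lo), False


def aggregate(normalized: np.ndarray) -> float:
    """OWOD of the record: mean of the normalized components."""
    n = np.asarray(normalized, dtype=float)
    if n.size < 1:
        raise ValueError("need at least one component")
    return float(n.mean())


def classify(owod: float, owod_cutoff: float) -> bool:
    """True = positive class.  Ties are inclusive to the positive class."""
    if not (np.isfinite(owod) and np.isfinite(owod_cutoff)):
        raise ValueError("scores must be finite")
    return owod <= owod_cutoff


# ---------------------------------------------------------------------------
# record-level chain


@dataclass
class ScoreResult:
    """Full per-record breakdown of the scoring chain."""

    features: list[str]
    distances: dict[str, DistanceEntry]
    entropies: dict[str, float]
    epc: float
    igca: float
    gain: float
    weights: dict[str, float]
    components: dict[str, float]
    normalized: dict[str, float]
    owod: float
    degenerate: bool = False
    zero_gain: bool = False
    predicted_positive: bool | None = None


@dataclass
class Cutoff:
    """Cut-off OWOD with the threshold pseudo-record that produced it."""

    owod_c: float
    pseudo_record: dict[str, float] = field(default_factory=dict)


def score_record(
    values: dict[str, float],
    params: ObjectiveParams,
    feature_subset: list[str] | None = None,
) -> ScoreResult:
    """Score one record through the full chain.

    ``values`` must provide a finite value for every feature scored
    (impute beforehand).
    """
    feats = list(feature_subset or params.features)
    if len(feats) < 2:
        raise ValueError("scoring needs at least two features")
    dist: dict[str, DistanceEntry] = {}
    ent: dict[str, float] = {}
    for f in feats:
        if f not in values or not np.isfinite(values[f]):
            raise ValueError(f"record is missing a value for feature {f!r}")
        p = params[f]
        d = feature_distances(float(values[f]), p.tmi, p.ai)
        dist[f] = d
        ent[f] = binary_entropy(d.rtc, d.rta)

    h = np.array([ent[f] for f in feats])
    epc, _, _ = balanced_class_entropy(len(feats))
    igca, gain = information_gain(h, epc)
    # gain <= 0 happens only when every entropy is exactly 1 (all ratios at
    # 0.5), where the weight ratios H_i/G share a common factor and their
    # normalized limit is uniform; the record is flagged rather than rejected.
    zero_gain = gain <= 0
    w = np.full(h.size, 1.0 / h.size) if zero_gain else feature_weights(h, gain)
    ndtc = np.array([dist[f].ndtc for f in feats])
    ndta = np.array([dist[f].ndta for f in feats])
    comp = owod_components(w, ndtc, ndta)
    norm, degenerate = normalize_components(comp)
    owod = aggregate(norm)
    return ScoreResult(
        features=feats,
        distances=dist,
        entropies=ent,
        epc=epc,
        igca=igca,
        gain=gain,
        weights=dict(zip(feats, w.tolist())),
        components=dict(zip(feats, comp.tolist())),
        normalized=dict(zip(feats, norm.tolist())),
        owod=owod,
        degenerate=degenerate,
        zero_gain=zero_gain,
    )


def cutoff_owod(
    params: ObjectiveParams, feature_subset: list[str] | None = None
) -> Cutoff:
    """Score the threshold pseudo-record (Ci := Tsmi) to get the cut-off."""
    feats = list(feature_subset or params.features)
    pseudo = {f: params[f].tsmi for f in feats}
    for f in feats:
        if pseudo[f] == params[f].tmi:
            raise ValueError(
                f"threshold equals target for feature {f!r}; "
                "cut-off pseudo-record is degenerate"
            )
    result = score_record(pseudo, params, feats)
    return Cutoff(owod_c=result.owod, pseudo_record=pseudo)


# ---------------------------------------------------------------------------
# cohort-level vectorized chain


def score_cohort(
    cohort: CohortTable,
    params: ObjectiveParams,
    feature_subset: list[str] | None = None,
    cutoff: Cutoff | None = None,
) -> pd.DataFrame:
    """Vectorized scoring of a whole cohort.

    Returns a DataFrame indexed like the cohort with per-feature weight
    columns (``w_<acronym>``), the OWOD score, a degeneracy flag and, if a
    cut-off is given, the predicted class label.
    """
    feats = list(feature_subset or params.features)
    if len(feats) < 2:
        raise ValueError("scoring needs at least two features")
    C = cohort.data[feats].to_numpy(dtype=float)
    if not np.isfinite(C).all():
        bad = np.flatnonzero(~np.isfinite(C).all(axis=1))
        raise ValueError(
            f"{bad.size} records have missing values in the scored features "
            "(impute first); first offending row index: "
            f"{cohort.data.index[bad[0]]!r}"
        )
    T = np.array([params[f].tmi for f in feats])
    A = np.array([params[f].ai for f in feats])
    if np.any(A <= 0):
        raise ValueError("all acceptable levels must be positive")

    dtc = np.abs(T - C)
    dta = np.broadcast_to(np.abs(T - A), C.shape)
    ndtc = 100.0 * dtc / A
    ndta = 100.0 * dta / A
    total = ndtc + ndta
    safe = np.where(total > 0, total, 1.0)
    rtc = np.where(total > 0, ndtc / safe, 0.5)
    rta = 1.0 - rtc

    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(rtc > 0, rtc * np.log2(np.where(rtc > 0, rtc, 1.0)), 0.0) - np.where(
            rta > 0, rta * np.log2(np.where(rta > 0, rta, 1.0)), 0.0
        )
    h_sum = h.sum(axis=1, keepdims=True)
    gain = 1.0 - h.mean(axis=1)
    weights = np.where(h_sum > 0, h / np.where(h_sum > 0, h_sum, 1.0), 1.0 / len(feats))

    comp = weights * np.abs(ndta - ndtc)
    lo = comp.min(axis=1, keepdims=True)
    hi = comp.max(axis=1, keepdims=True)
    spread = hi - lo
    degenerate = (spread <= _EPS).ravel()
    norm = np.where(spread > _EPS, (comp - lo) / np.where(spread > 0, spread, 1.0), 0.5)
    owod = norm.mean(axis=1)

    out = pd.DataFrame(index=cohort.data.index)
    for j, f in enumerate(feats):
        out[f"w_{f}"] = weights[:, j]
    out["owod"] = owod
    out["zero_gain"] = gain <= 0
    out["degenerate"] = degenerate
    if cutoff is not None:
        positive = owod <= cutoff.owod_c
        out["predicted"] = np.where(
            positive, cohort.positive_label, cohort.negative_label
        )
    return out
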