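"""Packaged eight-feature reference example.

The reference fixture pairs target/acceptable levels for eight risk-factor
features with ten sample records; scoring record no. 1 through the chain is
the package's living regression example, and the same parameters drive the
cut-off pseudo-record.
"""

from __future__ import annotations

from .objective import FeatureParams, ObjectiveParams, threshold_value
from .scoring import ScoreResult, cutoff_owod, score_record

REFERENCE_FEATURES = ["W", "SBP", "DBP", "FBS", "TGS", "TC", "HDL", "LDL"]

# target level Tmi, acceptable level Ai per feature
REFERENCE_LEVELS: dict[str, tuple[float, float]] = {
    "W": (55.0, 90.0),
    "SBP": (150.0, 190.0),
    "DBP": (85.0, 110.0),
    "FBS": (130.0, 280.0),
    "TGS": (140.0, 160.0),
    "TC": (200.0, 260.0),
    "HDL": (55.0, 70.0),
    "LDL": (135.0, 165.0),
}

# ten sample records (current values per feature)
REFERENCE_RECORDS: list[dict[str, float]] = [
    dict(zip(REFERENCE_FEATURES, row))
    for row in [
        (65, 130, 75, 120, 115, 175, 35, 105),
        (70, 140, 80, 105, 95, 165, 50, 120),
        (55, 155, 90, 110, 110, 195, 60, 140),
        (65, 135, 75, 100, 100, 185, 40, 120),
        (50, 150, 75, 115, 155, 205, 50, 135),
        (60, 135, 85, 115, 100, 185, 60, 145),
        (92, 155, 85, 120, 125, 220, 50, 140),
        (77, 160, 80, 115, 100, 210, 50, 135),
        (47, 121, 82, 130, 85, 215, 55, 130),
        (45, 162, 77, 115, 120, 205, 60, 125),
    ]
]


def reference_params(threshold_frac: float = 0.05) -> ObjectiveParams:
    """ObjectiveParams for the reference example (thresholds 5 % below Tmi)."""
    return ObjectiveParams(
        {
            f: FeatureParams(
                tmi=t, ai=a, tsmi=threshold_value(t, threshold_frac, "below")
            )
            for f, (t, a) in REFERENCE_LEVELS.items()
        }
    )


def run_worked_example(record_index: int = 0) -> tuple[ScoreResult, float]:
    """Score one reference record; returns its breakdown and the cut-off."""
    params = reference_params()
    result = score_record(REFERENCE_RECORDS[record_index], params, REFERENCE_FEATURES)
    cut = cutoff_owod(params, REFERENCE_FEATURES)
    result.predicted_positive = result.owod <= cut.owod_c
    return result, cut.owod_c


def format_worked_example(record_index: int = 0) -> str:
    """Human-readable printout of every intermediate of the chain."""
    result, owod_c = run_worked_example(record_index)
    lines = [f"Reference scoring chain, record no. {record_index + 1}", ""]
    header = f"{'feat':>5} {'Ci':>7} {'Tmi':>7} {'Ai':>7} {'rTC':>6} {'rTA':>6} {'H':>6} {'W':>6} {'owoD':>7} {'nowoD':>6}"
    lines.append(header)
    record = REFERENCE_RECORDS[record_index]
    for f in result.features:
        d = result.distances[f]
        t, a = REFERENCE_LEVELS[f]
        lines.append(
            f"{f:>5} {record[f]:7.1f} {t:7.1f} {a:7.1f} "
            f"{d.rtc:6.2f} {d.rta:6.2f} {result.entropies[f]:6.2f} "
            f"{result.weights[f]:6.2f} {result.components[f]:7.2f} "
            f"{result.normalized[f]:6.2f}"
        )
    lines += [
        "",
        f"EPC  = {result.epc:.2f}   (balanced-class entropy)",
        f"IGCa = {result.igca:.4f} (mean feature entropy)",
        f"G    = {result.gain:.4f} (information gain)",
        f"OWOD = {result.owod:.4f}",
        f"OWODc = {owod_c:.4f} (threshold pseudo-record score)",
        f"class = {'positive' if result.predicted_positive else 'negative'}"
        f" (OWOD {'<=' if result.predicted_positive else '>'} OWODc)",
    ]
    return "\n".join(lines)
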