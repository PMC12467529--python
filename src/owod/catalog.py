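"""Feature vocabulary for blood-biomarker cohorts.

A :class:`FeatureCatalog` declares, for every clinical feature, its acronym,
group (``R`` = established risk factor, ``P`` = proposed blood-test feature),
unit, plausible physiological range, and the histogram binning policy used
when estimating per-feature target levels.  The default catalog covers the
21 routine check-up and blood-test features of the dementia / heart-failure
panel (body weight through serum carbon dioxide).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator


@dataclass(frozen=True)
class BinRule:
    """Histogram binning policy for one feature.

    kind
        ``"auto"`` — Freedman–Diaconis width on the pooled training values;
        ``"fixed_width"`` — bins of width ``width``, with edges anchored so
        that bin midpoints fall on multiples of ``width``;
        ``"fixed_count"`` — ``count`` equal-width bins over the pooled range.
    """

    kind: str = "auto"
    width: float | None = None
    count: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("auto", "fixed_width", "fixed_count"):
            raise ValueError(f"unknown bin rule kind: {self.kind!r}")
        if self.kind == "fixed_width" and (self.width is None or self.width <= 0):
            raise ValueError("fixed_width rule requires a positive width")
        if self.kind == "fixed_count" and (self.count is None or self.count < 1):
            raise ValueError("fixed_count rule requires count >= 1")


@dataclass(frozen=True)
class FeatureSpec:
    """Identity and constraints of one clinical feature."""

    acronym: str
    group: str  # "R" or "P"
    unit: str
    plausible_min: float
    plausible_max: float
    bin_rule: BinRule = field(default_factory=BinRule)

    def __post_init__(self) -> None:
        if self.group not in ("R", "P"):
            raise ValueError(f"{self.acronym}: group must be 'R' or 'P'")
        if not self.plausible_min < self.plausible_max:
            raise ValueError(
                f"{self.acronym}: plausible_min must be < plausible_max"
            )

    @property
    def span(self) -> float:
        return self.plausible_max - self.plausible_min


class FeatureCatalog:
    """Ordered, unique collection of :class:`FeatureSpec`."""

    def __init__(self, specs: list[FeatureSpec]):
        seen: set[str] = set()
        for s in specs:
            if s.acronym in seen:
                raise ValueError(f"duplicate feature acronym: {s.acronym}")
            seen.add(s.acronym)
        self._specs = {s.acronym: s for s in specs}

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._specs

    def __getitem__(self, acronym: str) -> FeatureSpec:
        try:
            return self._specs[acronym]
        except KeyError:
            raise KeyError(f"feature {acronym!r} not in catalog") from None

    def __iter__(self) -> Iterator[FeatureSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def acronyms(self) -> list[str]:
        return list(self._specs)

    def with_bin_rule(self, acronym: str, rule: BinRule) -> "FeatureCatalog":
        """Return a copy with one feature's bin rule replaced."""
        specs = [
            replace(s, bin_rule=rule) if s.acronym == acronym else s
            for s in self
        ]
        return FeatureCatalog(specs)


# acronym, group, unit, plausible range (panel data ranges)
_DEFAULT_FEATURES: list[tuple[str, str, str, float, float]] = [
    ("W", "R", "kg", 40.1, 116.3),
    ("H", "P", "cm", 150.1, 185.0),
    ("BMI", "R", "kg/m^2", 11.76, 39.57),
    ("SBP", "R", "mmHg", 76.0, 199.0),
    ("DBP", "R", "mmHg", 61.0, 126.0),
    ("FBS", "R", "mg/dL", 62.0, 495.0),
    ("TGS", "R", "mg/dL", 51.0, 199.0),
    ("TC", "R", "mg/dL", 101.0, 429.0),
    ("HDL", "R", "mg/dL", 31.0, 93.0),
    ("LDL", "R", "mg/dL", 51.0, 196.0),
    ("HB", "P", "g/dL", 10.10, 20.10),
    ("WBC", "P", "count/uL", 3100.0, 19900.0),
    ("NEUT", "P", "%", 30.20, 89.90),
    ("PLAT", "P", "count/uL", 101000.0, 585000.0),
    ("LYMP", "P", "%", 10.10, 59.00),
    ("CREA", "P", "mg/dL", 0.35, 2.99),
    ("BUN", "P", "mg/dL", 4.0, 49.0),
    ("TSH", "P", "mIU/L", 0.01, 5.97),
    ("K", "P", "mEq/L", 1.40, 7.80),
    ("NA", "P", "mEq/L", 109.0, 167.0),
    ("CO2", "P", "mEq/L", 11.0, 45.0),
]

# Fasting blood sugar is conventionally binned at width 10 anchored on
# multiples of 5 (so bin midpoints land on multiples of 10).
_DEFAULT_BIN_OVERRIDES: dict[str, BinRule] = {
    "FBS": BinRule(kind="fixed_width", width=10.0),
}


def default_catalog() -> FeatureCatalog:
    """The packaged 21-feature panel with default bin rules."""
    specs = [
        FeatureSpec(
            acronym=a,
            group=g,
            unit=u,
            plausible_min=lo,
            plausible_max=hi,
            bin_rule=_DEFAULT_BIN_OVERRIDES.get(a, BinRule()),
        )
        for a, g, u, lo, hi in _DEFAULT_FEATURES
    ]
    return FeatureCatalog(specs)
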