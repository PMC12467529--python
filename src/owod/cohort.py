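"""Labeled cohort tables and their CSV interchange format.

A cohort is one row per person, one column per feature acronym, an optional
``id`` column and an optional label column.  Missing values are empty cells;
the header string ``NA`` always means serum sodium, never "not available".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog

ID_COLUMN = "id"


@dataclass
class CohortTable:
    """Labeled records keyed by feature acronym.

    data
        float DataFrame, one column per feature; NaN marks a missing value.
        The index holds record ids (strings).
    labels
        optional Series aligned with ``data`` holding one of the two
        declared class labels (or NaN where unlabeled).
    """

    data: pd.DataFrame
    labels: pd.Series | None = None
    label_name: str = "label"
    positive_label: str = "dementia"
    negative_label: str = "heart failure"
    extra_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.labels is not None:
            bad = set(self.labels.dropna().unique()) - {
                self.positive_label,
                self.negative_label,
            }
            if bad:
                raise ValueError(f"unknown labels present: {sorted(bad)}")
            if not self.labels.index.equals(self.data.index):
                raise ValueError("labels index does not match data index")

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def copy(self) -> "CohortTable":
        return CohortTable(
            data=self.data.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            label_name=self.label_name,
            positive_label=self.positive_label,
            negative_label=self.negative_label,
            extra_columns=list(self.extra_columns),
        )

    def is_positive(self) -> pd.Series:
        """Boolean mask of positive-class records (labels required)."""
        if self.labels is None:
            raise ValueError("cohort has no labels")
        return self.labels == self.positive_label

    def subset(self, index) -> "CohortTable":
        """Row subset by positional indices or boolean mask."""
        out = self.copy()
        if isinstance(index, (pd.Series,)):
            out.data = out.data.loc[index]
            if out.labels is not None:
                out.labels = out.labels.loc[index]
        else:
            out.data = out.data.iloc[index]
            if out.labels is not None:
                out.labels = out.labels.iloc[index]
        return out


def read_cohort_csv(
    path,
    catalog: FeatureCatalog,
    *,
    label_name: str = "label",
    positive_label: str = "dementia",
    negative_label: str = "heart failure",
    require_labels: bool = False,
) -> CohortTable:
    """Read a cohort CSV.

    Empty cells become missing values.  The literal header token ``NA``
    is the sodium column; in cells only the empty string is treated as
    missing, so pandas' default NA sniffing is disabled.  Unknown columns
    are preserved in ``extra_columns``.  Non-numeric feature cells raise
    with the offending row and column named.
    """
    raw = pd.read_csv(
        path, dtype=str, keep_default_na=False, na_values=[], skipinitialspace=True
    )
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].tolist()
        raise ValueError(f"duplicate columns in header: {dupes}")

    feature_cols = [c for c in raw.columns if c in catalog]
    extra = [
        c
        for c in raw.columns
        if c not in catalog and c not in (ID_COLUMN, label_name)
    ]

    if ID_COLUMN in raw.columns:
        index = pd.Index(raw[ID_COLUMN].astype(str), name=ID_COLUMN)
    else:
        index = pd.Index([str(i) for i in range(len(raw))], name=ID_COLUMN)

    data = pd.DataFrame(index=index)
    for col in feature_cols:
        cells = raw[col].str.strip()
        blank = cells == ""
        try:
            values = pd.to_numeric(cells.where(~blank, other=np.nan))
        except (ValueError, TypeError):
            ok = blank | cells.apply(_is_number)
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {cells.iloc[row]!r} in column {col!r}, "
                f"row {row + 2} of {path}"
            ) from None
        data[col] = values.to_numpy(dtype=float)

    labels = None
    if label_name in raw.columns:
        lab = raw[label_name].str.strip()
        labels = pd.Series(
            lab.where(lab != "", other=np.nan).to_numpy(), index=index, name=label_name
        )
    elif require_labels:
        raise ValueError(f"label column {label_name!r} missing from {path}")

    return CohortTable(
        data=data,
        labels=labels,
        label_name=label_name,
        positive_label=positive_label,
        negative_label=negative_label,
        extra_columns=extra,
    )


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """Write a cohort back to CSV (missing values as empty cells)."""
    out = cohort.data.copy()
    if cohort.labels is not None:
        out[cohort.label_name] = cohort.labels
    out.to_csv(path, index=True, na_rep="")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
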