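"""Fit / score / persist glue: the train-then-apply protocol.

Fitting estimates the objective parameters on a labeled training cohort and
scores the threshold pseudo-record for the cut-off; the frozen model is then
applied to unseen records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .catalog import FeatureCatalog, default_catalog
from .cohort import CohortTable
from .config import RunConfig
from .objective import ObjectiveParams, fit_objective_params
from .scoring import Cutoff, cutoff_owod, score_cohort


@dataclass
class FittedModel:
    params: ObjectiveParams
    cutoff: Cutoff
    features: list[str]
    config: dict

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "params": self.params.to_dict(),
            "cutoff": {
                "owod_c": self.cutoff.owod_c,
                "pseudo_record": self.cutoff.pseudo_record,
            },
            "config": self.config,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedModel":
        return cls(
            params=ObjectiveParams.from_dict(doc["params"]),
            cutoff=Cutoff(
                owod_c=doc["cutoff"]["owod_c"],
                pseudo_record=doc["cutoff"]["pseudo_record"],
            ),
            features=list(doc["features"]),
            config=dict(doc.get("config", {})),
        )

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit(
    cohort: CohortTable,
    config: RunConfig | None = None,
    catalog: FeatureCatalog | None = None,
) -> FittedModel:
    """Estimate objective parameters and the cut-off on a training cohort."""
    config = config or RunConfig()
    catalog = catalog or default_catalog()
    params = fit_objective_params(cohort, catalog, config)
    features = config.features or cohort.features
    cutoff = cutoff_owod(params, features)
    return FittedModel(
        params=params, cutoff=cutoff, features=list(features), config=config.to_dict()
    )


def predict(model: FittedModel, cohort: CohortTable) -> pd.DataFrame:
    """Score a cohort against a fitted model (weights, OWOD, predicted class)."""
    missing = [f for f in model.features if f not in cohort.features]
    if missing:
        raise KeyError(f"cohort lacks model features: {missing}")
    return score_cohort(cohort, model.params, model.features, model.cutoff)
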