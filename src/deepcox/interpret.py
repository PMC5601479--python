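"""Risk backpropagation: gradient-based feature attribution for deep Cox models.

The chain rule that trains the network can also propagate the predicted risk
back to the inputs: the feature risk score of patient i is the gradient of
the linear risk output with respect to the input features, evaluated at that
patient's feature vector,

    dR/df = beta x prod_h J_h

with J_h the Jacobian of hidden layer h and beta the Cox output-layer
coefficients (no exponential — the scores are gradients of risk).  For a
linear model every patient's score vector is beta itself; for a nonlinear
network the gradients differ from patient to patient, tracing a curved risk
surface.  Cohort-level rankings take the median score per feature, ordered
by absolute value with the sign retained (positive = risk-increasing, i.e.
associated with poor prognosis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .network import DeepSurvivalModel, train

__all__ = ["RiskScoreMatrix", "feature_risk_scores", "rank_features",
           "export_preranked", "interpretation_model"]


@dataclass
class RiskScoreMatrix:
    """Per-patient x per-feature risk gradients."""

    scores: pd.DataFrame  # index = patient ids, columns = feature names
    model: DeepSurvivalModel | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("risk scores contain non-finite values")

    @property
    def feature_names(self):
        return list(self.scores.columns)

    @property
    def patient_ids(self):
        return self.scores.index.to_numpy()

    def write(self, path, delimiter="\t"):
        self.scores.to_csv(path, sep=delimiter, index_label="patient_id")


def feature_risk_scores(model: DeepSurvivalModel, ds: SurvivalDataset,
                        scale_record: pd.DataFrame | None = None) -> RiskScoreMatrix:
    """Evaluate the risk gradient at every patient's feature vector.

    Dropout is disabled — scores are exact gradients of the deterministic
    evaluation-mode risk.  Scores live in the model's (standardized) input
    space; passing the standardization record divides each column by its
    stored scale to express scores per original feature unit.
    """
    missing = [c for c in model.feature_names if c not in ds.features.columns]
    if missing:
        raise KeyError(f"dataset is missing model features: {missing}")
    X = ds.features[model.feature_names].to_numpy(dtype=float)
    G = model.input_gradients(X)
    if scale_record is not None:
        scales = scale_record.loc[model.feature_names, "scale"].to_numpy()
        G = G / scales
    scores = pd.DataFrame(G, index=ds.features.index,
                          columns=model.feature_names)
    return RiskScoreMatrix(scores=scores, model=model)


def rank_features(rsm: RiskScoreMatrix, method: str = "abs-of-median") -> pd.DataFrame:
    """Rank features by prognostic weight across the cohort.

    ``abs-of-median`` (default) ranks by |median of the signed per-patient
    scores| while displaying the signed median, so positive entries read as
    risk-increasing and negative as protective.  ``median-of-abs`` ranks by
    the median absolute score instead.  Ties break deterministically by
    feature name.
    """
    med_signed = rsm.scores.median(axis=0)
    if method == "abs-of-median":
        key = med_signed.abs()
    elif method == "median-of-abs":
        key = rsm.scores.abs().median(axis=0)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    table = pd.DataFrame({"feature": rsm.feature_names,
                          "median_score": med_signed.to_numpy(),
                          "rank_key": key.to_numpy()})
    table = table.sort_values(["rank_key", "feature"],
                              ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[["feature", "median_score", "rank"]]


def export_preranked(ranked, path):
    """Write a two-column tab-separated preranked list (feature, score).

    Rows are sorted by descending signed score, no header — the input format
    consumed by preranked gene-set enrichment tools.  Accepts either a
    :class:`RiskScoreMatrix` or the table from :func:`rank_features`.
    """
    if isinstance(ranked, RiskScoreMatrix):
        ranked = rank_features(ranked)
    if ranked["feature"].duplicated().any():
        dups = ranked.loc[ranked["feature"].duplicated(), "feature"].tolist()
        raise ValueError(f"duplicate feature names: {dups}")
    out = ranked.sort_values("median_score", ascending=False, kind="stable")
    out[["feature", "median_score"]].to_csv(path, sep="\t", header=False,
                                            index=False)


def interpretation_model(ds: SurvivalDataset, results,
                         config_overrides: dict | None = None) -> DeepSurvivalModel:
    """Retrain the best design from repeated evaluation on all samples.

    Picks the configuration of the repeat with the highest test c-index and
    fits a fresh model on the complete cohort — the model used for risk
    backpropagation.
    """
    from dataclasses import replace
    if not results:
        raise ValueError("no evaluation results")
    best = max(results, key=lambda r: r.c_index)
    if best.config is None:
        raise ValueError("evaluation results carry no configs")
    overrides = dict(config_overrides or {})
    overrides.setdefault("init_seed", (best.split_seed or 0) + 2000)
    cfg = replace(best.config, **overrides)
    return train(ds, cfg)
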