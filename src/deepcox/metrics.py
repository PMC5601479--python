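"""Harrell's concordance index and the randomized-repeat evaluation protocol.

The c-index is the fraction of permissible patient pairs in which the patient
with the shorter survival received the higher predicted risk: 1 is perfect
concordance, 0.5 is chance.  Permissibility follows Harrell's original rule
for right-censored data: a pair ordered by time counts when the earlier
patient's event was observed; pairs tied on time count only when exactly one
member is an event, in which case the event member is treated as the earlier
one.  Ties in predicted risk contribute 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalDataset, split_train_val_test

__all__ = ["EvaluationResult", "concordance_index",
           "repeated_holdout_evaluation", "summarize_results",
           "results_table", "rank_sum_comparison"]


@dataclass
class EvaluationResult:
    """One c-index measurement plus its pair bookkeeping."""

    c_index: float
    n_permissible_pairs: int
    n_concordant: float  # risk ties counted 0.5
    split_seed: int | None = None
    config: object | None = None

    def __post_init__(self):
        if not 0.0 <= self.c_index <= 1.0:
            raise ValueError("c-index out of [0, 1]")


def concordance_index(risk, times, events) -> EvaluationResult:
    """Harrell's c-index of predicted risks against observed survival.

    Vectorized over all ordered pairs; raises when no pair is permissible
    (for example when every patient is censored at the same time).
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float).astype(bool)
    n = len(risk)
    if n < 2:
        raise ValueError("need at least 2 patients")

    ti, tj = times[:, None], times[None, :]
    ei, ej = events[:, None], events[None, :]
    ri, rj = risk[:, None], risk[None, :]

    # ordered pair (i, j): i strictly earlier with event, or tied times with
    # exactly one event (the event member treated as earlier)
    permissible = ((ti < tj) & ei) | ((ti == tj) & ei & ~ej)
    np.fill_diagonal(permissible, False)

    n_perm = int(permissible.sum())
    if n_perm == 0:
        raise ValueError("no permissible pairs")
    concordant = float(((ri > rj) & permissible).sum())
    tied = float(((ri == rj) & permissible).sum())
    score = concordant + 0.5 * tied
    return EvaluationResult(c_index=score / n_perm,
                            n_permissible_pairs=n_perm,
                            n_concordant=score)


def repeated_holdout_evaluation(ds: SurvivalDataset, space, n_repeats: int = 20,
                                base_seed: int = 0, budget: int = 30,
                                config_overrides: dict | None = None,
                                objective=None):
    """Randomized train/validation/test repeats of the full design loop.

    For each repeat r the cohort is re-randomized 60/20/20 with seed
    ``base_seed + r``; Bayesian optimization selects a network design on
    train/validation, the best design is refit on train + validation, and its
    c-index is measured on the held-out test patients.  Repeating over
    (default) 20 randomizations accounts for variation due to sample
    assignment.  Returns a list of :class:`EvaluationResult` carrying the
    chosen configs and split seeds.

    ``config_overrides`` (for example ``{"max_epochs": 100}``) apply to every
    trained network — the knob used to scale the protocol to small budgets.
    """
    from .bayesopt import optimize_hyperparameters, refit_best
    from .network import predict_risk

    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    results = []
    for r in range(1, n_repeats + 1):
        seed = base_seed + r
        split = split_train_val_test(ds, seed)
        train_ds = ds.subset(split.train_idx)
        val_ds = ds.subset(split.val_idx)
        test_ds = ds.subset(split.test_idx)
        trace = optimize_hyperparameters(
            train_ds, val_ds, space, budget=budget, seed=seed,
            config_overrides=config_overrides, objective=objective)
        tv = ds.subset(np.concatenate([split.train_idx, split.val_idx]))
        model = refit_best(tv, trace, config_overrides=config_overrides)
        res = concordance_index(predict_risk(model, test_ds),
                                test_ds.times, test_ds.events)
        res.split_seed = seed
        res.config = trace.best_config
        results.append(res)
    return results


def summarize_results(results) -> dict:
    c = np.array([r.c_index for r in results])
    out = {"n_repeats": len(results), "median_c_index": float(np.median(c)),
           "mean_c_index": float(c.mean())}
    if len(results) > 1:
        out["sd_c_index"] = float(c.std(ddof=1))
    return out


def results_table(results) -> pd.DataFrame:
    """Tidy table: repeat, seed, config-id, c_index, n_pairs."""
    rows = []
    for k, r in enumerate(results, 1):
        cfg = r.config
        cfg_id = ("linear" if cfg is None else
                  f"H{cfg.n_hidden_layers}-w{cfg.layer_width}-"
                  f"{cfg.activation}-d{cfg.dropout_frac:.2f}")
        rows.append({"repeat": k, "seed": r.split_seed, "config_id": cfg_id,
                     "c_index": r.c_index, "n_pairs": r.n_permissible_pairs})
    return pd.DataFrame(rows)


def rank_sum_comparison(c_indexes_a, c_indexes_b) -> dict:
    """Two-sample Wilcoxon rank-sum comparison of c-index collections."""
    from scipy.stats import ranksums
    stat, p = ranksums(c_indexes_a, c_indexes_b)
    return {"statistic": float(stat), "p_value": float(p)}
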