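"""Hyperparameter search with percentile-based trial pruning.

The objective of a trial is the Matthews correlation coefficient averaged
over the inner cross-validation folds; per-fold MCCs are reported as
intermediate values. A trial is pruned at fold step ``s`` when at least
``min_history`` earlier trials reported a value at that step and the
candidate value falls strictly below the 80th percentile of those values
("survive only if in the top 20% so far"); the percentile uses the ceiling
convention (numpy ``method='higher'``), and no pruning fires during the
warm-up window. Configurations are suggested by a seeded random-search
suggester; repeated configurations reuse the cached objective, so a
single-point space costs one effective evaluation. Ties on the final
objective break toward the earliest trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import confusion, metrics
from .models import build_model, train, validate_hyperparams

__all__ = [
    "Trial",
    "PercentilePruner",
    "prune_decision",
    "suggest",
    "optimize",
    "retrain_best",
    "trials_to_tsv",
]


@dataclass
class Trial:
    trial_id: int
    params: dict
    intermediate: list[float] = field(default_factory=list)
    final_objective: float | None = None
    state: str = "running"  # running | pruned | complete


class PercentilePruner:
    """Prune trials whose per-step value falls below a percentile of history."""

    def __init__(self, percentile: float = 80.0, min_history: int = 5):
        self.percentile = percentile
        self.min_history = min_history

    def prune_decision(self, history: list[Trial], step: int, value: float) -> str:
        """``continue`` or ``prune`` for a candidate value at a fold step."""
        prior = [t.intermediate[step] for t in history if len(t.intermediate) > step]
        if len(prior) < self.min_history:
            return "continue"
        cutoff = float(np.percentile(prior, self.percentile, method="higher"))
        return "prune" if value < cutoff else "continue"


def prune_decision(history: list[Trial], step: int, value: float,
                   percentile: float = 80.0, min_history: int = 5) -> str:
    return PercentilePruner(percentile, min_history).prune_decision(history, step, value)


# ---------------------------------------------------------------------------
# random-search suggester over a declared space
# ---------------------------------------------------------------------------

def suggest(search_space: dict, rng: np.random.RandomState) -> dict:
    """Draw one configuration from a declared search space.

    Space entries: ``("log", lo, hi)``, ``("uniform", lo, hi)``,
    ``("int", lo, hi)`` or ``("cat", choices)``.
    """
    params = {}
    for name, spec in search_space.items():
        kind, *args = spec
        if kind == "cat":
            choices = args[0]
            params[name] = choices[rng.randint(len(choices))]
        elif kind == "int":
            params[name] = int(rng.randint(args[0], args[1] + 1))
        elif kind == "uniform":
            params[name] = float(rng.uniform(args[0], args[1]))
        elif kind == "log":
            params[name] = float(np.exp(rng.uniform(np.log(args[0]), np.log(args[1]))))
        else:
            raise ValueError(f"unknown search-space kind {kind!r} for {name!r}")
    return params


def _param_key(params: dict) -> str:
    return json.dumps(params, sort_keys=True, default=str)


def _mcc(labels, preds) -> float:
    return metrics(confusion(labels, preds)).mcc


def optimize(
    model_family: str,
    search_space: dict,
    fold_data: list[tuple],
    n_trials: int = 200,
    seed: int = 0,
    pruner: PercentilePruner | None = None,
    fixed_params: dict | None = None,
) -> tuple[Trial, list[Trial]]:
    """Random-search HPO over inner folds with percentile pruning.

    ``fold_data`` is a list of ``(X_train, y_train, X_val, y_val)`` tuples,
    one per inner fold. Returns the best complete trial (ties → earliest)
    and the full trial history. If every trial was pruned, the best pruned
    trial (by mean of its reported steps) is returned with a warning flag in
    its state.
    """
    if not search_space:
        raise ValueError("search space must be nonempty")
    if not fold_data:
        raise ValueError("optimize requires inner folds")
    pruner = pruner or PercentilePruner()
    rng = np.random.RandomState(seed)
    history: list[Trial] = []
    cache: dict[str, Trial] = {}
    for trial_id in range(n_trials):
        params = suggest(search_space, rng)
        validate_hyperparams(model_family, params)
        key = _param_key(params)
        if key in cache:
            continue  # configuration already evaluated; not a new effective trial
        trial = Trial(trial_id=trial_id, params=params)
        for step, (X_tr, y_tr, X_va, y_va) in enumerate(fold_data):
            model = build_model(model_family, **params, **(fixed_params or {}), seed=seed)
            train(model, X_tr, y_tr, X_va, y_va)
            value = _mcc(y_va, model.predict(X_va))
            if pruner.prune_decision(history, step, value) == "prune":
                trial.intermediate.append(value)
                trial.state = "pruned"
                break
            trial.intermediate.append(value)
        else:
            trial.state = "complete"
            trial.final_objective = float(np.mean(trial.intermediate))
        history.append(trial)
        cache[key] = trial
    complete = [t for t in history if t.state == "complete"]
    if complete:
        best = max(complete, key=lambda t: (t.final_objective, -t.trial_id))
        return best, history
    import warnings

    warnings.warn("all trials pruned; returning the best pruned-stage trial")
    best = max(history, key=lambda t: (np.mean(t.intermediate), -t.trial_id))
    return best, history


def retrain_best(
    best: Trial,
    model_family: str,
    X_all,
    y_all,
    seed: int = 0,
    fixed_params: dict | None = None,
):
    """Refit the winning configuration on the union of all inner-fold data.

    The returned model has seen every training/validation record exactly
    once per epoch and no held-out test record; leakage is the caller's
    responsibility to assert via id-set intersection.
    """
    model = build_model(model_family, **best.params, **(fixed_params or {}), seed=seed)
    return train(model, X_all, y_all)


def trials_to_tsv(history: list[Trial], path: str | Path) -> None:
    rows = [
        {
            "trial_id": t.trial_id,
            "state": t.state,
            "params": _param_key(t.params),
            "fold_mccs": ",".join(f"{v:.4f}" for v in t.intermediate),
            "objective": "" if t.final_objective is None else f"{t.final_objective:.4f}",
        }
        for t in history
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
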