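"""Subgroup bias audit: general vs population-specific model comparison.

A knowledgebase fitted on a general population can systematically
under-predict for a subgroup.  The audit fits a subgroup-specific model with
the same screening + stability-LASSO pipeline restricted to the subgroup's
episodes, compares both models by held-out McFadden pseudo-R² on subgroup
folds, and — when the specific model explains more variation than the margin
requires — updates the knowledgebase routing table so that subgroup members
are scored by the population-specific model.  Drugs with too few subgroup
trials are skipped rather than audited on noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from adrec.knowledgebase import (
    DrugModel,
    FeatureMatrix,
    Knowledgebase,
    KnowledgebaseError,
    _kfold_indices,
    _log_loss_sum,
    fit_lasso_stability,
    safe_screen,
)


@dataclass(frozen=True)
class AuditResult:
    """Outcome of auditing one drug for one subgroup."""

    drug: str
    subgroup: str
    r2_general: float
    r2_specific: float
    n_trials: int
    n_response: int
    decision: str  # "general" | "population_specific"
    margin: float
    status: str = "ok"  # "ok" | "insufficient_cases"


def decide(r2_general: float, r2_specific: float, decision_margin: float = 0.0) -> str:
    """Routing decision: specific model only if it clears the margin.

    Ties (and any improvement at or below the margin) keep the parsimonious
    general model.
    """
    if r2_specific - r2_general > decision_margin:
        return "population_specific"
    return "general"


def _cv_mcfadden(
    matrix: FeatureMatrix,
    drug: str,
    general_model: DrugModel,
    *,
    folds: int,
    seed: int,
    screen_k: int,
    **fit_kwargs,
) -> tuple[float, float]:
    """Held-out McFadden R² of the general and subgroup-specific models.

    Both models are scored on the same held-out folds against the same
    fold-specific null (training-fold base rate), so the comparison is
    apples-to-apples.  The general model is fixed; the specific model is
    refit on each training fold.  The L1 penalty is chosen once by
    cross-validated deviance on the full subgroup data and reused across
    folds.
    """
    fit_kwargs = dict(fit_kwargs)
    if "penalty_C" not in fit_kwargs:
        from adrec.knowledgebase import select_penalty

        full_selected = safe_screen(matrix, k=screen_k)
        fit_kwargs["penalty_C"] = select_penalty(
            matrix.events[full_selected].to_numpy(dtype=float),
            matrix.outcome, seed=seed,
        )
    rng = np.random.default_rng(seed)
    fold_idx = _kfold_indices(matrix.n, folds, rng)
    y = matrix.outcome
    ll_gen = ll_spec = ll_null = 0.0
    for f in range(folds):
        test = fold_idx[f]
        train = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
        if len(np.unique(y[train])) < 2:
            raise KnowledgebaseError("single-class training fold; too few cases")
        selected = safe_screen(matrix.take(train), k=screen_k)
        specific = fit_lasso_stability(
            matrix.take(train).restrict(selected), drug, seed=seed + f, **fit_kwargs
        )
        base = float(y[train].mean())
        y_test = y[test].astype(float)
        ll_null -= _log_loss_sum(y_test, np.full_like(y_test, base))
        ll_gen -= _log_loss_sum(
            y_test, np.asarray(general_model.predict_proba(matrix.events.iloc[test]))
        )
        ll_spec -= _log_loss_sum(
            y_test, np.asarray(specific.predict_proba(matrix.events.iloc[test]))
        )
    return 1.0 - ll_gen / ll_null, 1.0 - ll_spec / ll_null


def audit_drug(
    kb: Knowledgebase,
    subgroup_matrix: FeatureMatrix,
    drug: str,
    subgroup: str,
    *,
    min_cases: int = 68,
    decision_margin: float = 0.0,
    folds: int = 5,
    seed: int = 0,
    screen_k: int = 1000,
    **fit_kwargs,
) -> AuditResult:
    """Audit one drug's general model on a subgroup.

    ``subgroup_matrix`` holds the subgroup's episodes for this drug.  Drugs
    with fewer than ``min_cases`` trials return an ``insufficient_cases``
    status (keeping the general routing) instead of raising.
    """
    if drug not in kb.models:
        raise KnowledgebaseError(f"drug {drug!r} not in knowledgebase")
    n_trials = subgroup_matrix.n
    n_response = int(subgroup_matrix.outcome.sum())
    if n_trials < min_cases:
        return AuditResult(
            drug=drug, subgroup=subgroup,
            r2_general=float("nan"), r2_specific=float("nan"),
            n_trials=n_trials, n_response=n_response,
            decision="general", margin=float("nan"),
            status="insufficient_cases",
        )
    r2_gen, r2_spec = _cv_mcfadden(
        subgroup_matrix, drug, kb.models[drug],
        folds=folds, seed=seed, screen_k=screen_k, **fit_kwargs,
    )
    return AuditResult(
        drug=drug, subgroup=subgroup,
        r2_general=r2_gen, r2_specific=r2_spec,
        n_trials=n_trials, n_response=n_response,
        decision=decide(r2_gen, r2_spec, decision_margin),
        margin=r2_spec - r2_gen,
    )


def fit_subgroup_model(
    subgroup_matrix: FeatureMatrix,
    drug: str,
    subgroup: str,
    *,
    screen_k: int = 1000,
    seed: int = 0,
    **fit_kwargs,
) -> DrugModel:
    """Population-specific model fitted on all subgroup rows."""
    selected = safe_screen(subgroup_matrix, k=screen_k)
    model = fit_lasso_stability(
        subgroup_matrix.restrict(selected), drug, seed=seed,
        population_tag=f"subgroup:{subgroup}", **fit_kwargs,
    )
    return model


def apply_routing(kb: Knowledgebase, results: list[AuditResult]) -> Knowledgebase:
    """Update the routing table from audit results (idempotent, in place).

    Unaudited drugs keep (or get) general routing; conflicting duplicate
    results for one (drug, subgroup) pair are an error.  Results that choose
    the population-specific model require that model to be present in
    ``kb.subgroup_models``.
    """
    seen: dict[tuple[str, str], str] = {}
    for r in results:
        key = (r.drug, r.subgroup)
        if key in seen and seen[key] != r.decision:
            raise KnowledgebaseError(
                f"conflicting audit results for {key}: {seen[key]} vs {r.decision}"
            )
        seen[key] = r.decision
    for (drug, subgroup), decision in seen.items():
        if drug not in kb.models:
            raise KnowledgebaseError(f"audit result names unknown drug {drug!r}")
        tag = "general" if decision == "general" else f"subgroup:{subgroup}"
        kb.routing.setdefault(drug, {})[subgroup] = tag
    kb.validate()
    return kb


def audit_report(results: list[AuditResult]):
    """Audit results as a table mirroring the published comparison layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "drug": r.drug,
                "subgroup": r.subgroup,
                "ad_trials": r.n_trials,
                "remission": r.n_response,
                "general_model_r2": r.r2_general,
                "population_specific_r2": r.r2_specific,
                "decision": r.decision,
                "status": r.status,
            }
            for r in results
        ]
    )
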