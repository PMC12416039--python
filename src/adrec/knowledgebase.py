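"""Per-drug antidepressant-response models: screening, fitting, evaluation.

The knowledgebase is a catalog of sparse logistic models, one per
antidepressant, predicting the binary persistence surrogate for response
from binary medical-history events.  The pipeline is

1. *screening* — rank candidate events by normalized association with the
   outcome and keep the top ``k`` (default 1000), discarding constant
   columns;
2. *stability-selected LASSO* — L1-penalized logistic fits repeated over
   random subsamples, retaining events whose coefficient is nonzero in a
   configured fraction of subsamples, followed by a lightly ridged refit on
   the retained set;
3. *evaluation* — rank-statistic AUC, sensitivity/specificity at the 0.5
   threshold, and McFadden's pseudo-R², cross-validated when invoked through
   the build pipeline.

Models, the event schema, imputation models, and subgroup routing serialize
to a versioned JSON document.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

KB_FORMAT_VERSION = "1"

#: Event-schema vocabulary sizes of the full production catalog:
#: 700 diagnoses, 550 medications, 151 procedures, 98 prior responses.
FULL_SCHEMA_COUNTS = {"DX": 700, "RX": 550, "PX": 151, "ADR": 98}


class KnowledgebaseError(ValueError):
    """Raised when a knowledgebase fails validation or lookup."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureMatrix:
    """Binary event design matrix with the surrogate response outcome.

    ``events`` has one row per episode and one {0,1} column per medical
    history event; ``outcome`` is the binary response; ``subgroup`` optionally
    flags membership in a designated population subgroup.
    """

    events: pd.DataFrame
    outcome: np.ndarray
    subgroup: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=int)
        if len(self.events) != len(self.outcome):
            raise KnowledgebaseError("outcome length must equal row count")
        if self.events.columns.duplicated().any():
            raise KnowledgebaseError("event column ids must be unique")
        vals = self.events.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise KnowledgebaseError("event matrix entries must be binary")
        if self.subgroup is not None:
            self.subgroup = np.asarray(self.subgroup, dtype=bool)
            if len(self.subgroup) != len(self.outcome):
                raise KnowledgebaseError("subgroup flag length mismatch")

    @property
    def n(self) -> int:
        return len(self.outcome)

    def restrict(self, columns: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.events[list(columns)], self.outcome, self.subgroup)

    def take(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.events.iloc[rows],
            self.outcome[rows],
            None if self.subgroup is None else self.subgroup[rows],
        )


@dataclass
class DrugModel:
    """Sparse logistic response model for one antidepressant."""

    drug: str
    intercept: float
    coefficients: dict[str, float]
    retained_fraction: dict[str, float] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    population_tag: str = "general"

    def predict_proba(self, events: Mapping[str, float] | pd.DataFrame) -> np.ndarray | float:
        """Response probability from a completed event vector or table."""
        if isinstance(events, pd.DataFrame):
            lp = np.full(len(events), self.intercept)
            for ev, beta in self.coefficients.items():
                lp += beta * events[ev].to_numpy(dtype=float)
            return expit(lp)
        lp = self.intercept
        for ev, beta in self.coefficients.items():
            lp += beta * float(events.get(ev, 0.0))
        return float(expit(lp))


@dataclass
class ImputationModel:
    """Logistic model imputing one unreported medical-history event.

    Part of the linked-regression (structured-equation) network: each model
    predicts its target event from other events; the set of models must form
    an acyclic dependency graph, and ``topological_rank`` records the
    evaluation order.
    """

    target: str
    intercept: float
    coefficients: dict[str, float]
    topological_rank: int = 0

    def __post_init__(self) -> None:
        if self.target in self.coefficients:
            raise KnowledgebaseError(
                f"imputation model for {self.target!r} may not predict from itself"
            )

    def expected_value(self, values: Mapping[str, float]) -> float:
        lp = self.intercept
        for ev, beta in self.coefficients.items():
            lp += beta * float(values.get(ev, 0.0))
        return float(expit(lp))


@dataclass
class EventSchema:
    """Catalog of medical-history events grouped by vocabulary."""

    events: dict[str, str]  # event id -> vocabulary

    def __post_init__(self) -> None:
        bad = {v for v in self.events.values()} - {"DX", "RX", "PX", "ADR"}
        if bad:
            raise KnowledgebaseError(f"unknown vocabularies: {sorted(bad)}")

    @property
    def vocabulary_counts(self) -> dict[str, int]:
        counts = {"DX": 0, "RX": 0, "PX": 0, "ADR": 0}
        for v in self.events.values():
            counts[v] += 1
        return counts

    @property
    def total(self) -> int:
        return len(self.events)


@dataclass
class Knowledgebase:
    """All fitted models plus routing and provenance metadata."""

    schema: EventSchema
    models: dict[str, DrugModel]
    subgroup_models: dict[str, dict[str, DrugModel]] = field(default_factory=dict)
    imputation_models: list[ImputationModel] = field(default_factory=list)
    routing: dict[str, dict[str, str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    version: str = KB_FORMAT_VERSION

    def validate(self) -> None:
        if self.version != KB_FORMAT_VERSION:
            raise KnowledgebaseError(f"unknown knowledgebase version: {self.version!r}")
        schema_ids = set(self.schema.events)
        for drug, model in self.models.items():
            bad = set(model.coefficients) - schema_ids
            if bad:
                raise KnowledgebaseError(
                    f"model {drug!r} references events outside the schema: {sorted(bad)[:5]}"
                )
        for drug, by_subgroup in self.routing.items():
            if drug not in self.models:
                raise KnowledgebaseError(f"routing names unknown drug {drug!r}")
            for subgroup, tag in by_subgroup.items():
                if tag == "general":
                    continue
                if not tag.startswith("subgroup:"):
                    raise KnowledgebaseError(f"malformed population tag {tag!r}")
                name = tag.split(":", 1)[1]
                if drug not in self.subgroup_models.get(name, {}):
                    raise KnowledgebaseError(
                        f"routing for ({drug!r}, {subgroup!r}) targets missing model {tag!r}"
                    )
        targets = [m.target for m in self.imputation_models]
        if len(targets) != len(set(targets)):
            raise KnowledgebaseError("duplicate imputation targets")
        _check_acyclic(self.imputation_models)

    def resolve_model(self, drug: str, subgroup_tags: Iterable[str] = ()) -> DrugModel:
        """Routed model for a drug given the patient's subgroup tags."""
        if drug not in self.models:
            raise KnowledgebaseError(f"drug {drug!r} not in knowledgebase")
        for tag in sorted(subgroup_tags):
            chosen = self.routing.get(drug, {}).get(tag)
            if chosen and chosen != "general":
                name = chosen.split(":", 1)[1]
                try:
                    return self.subgroup_models[name][drug]
                except KeyError:
                    raise KnowledgebaseError(
                        f"routing for ({drug!r}, {tag!r}) targets missing model {chosen!r}"
                    ) from None
        return self.models[drug]


def _check_acyclic(models: Sequence[ImputationModel]) -> list[ImputationModel]:
    """Kahn toposort of the imputation network; raises on cycles.

    Returns models ordered so that every predictor that is itself an
    imputation target comes before its dependents.
    """
    by_target = {m.target: m for m in models}
    indeg = {t: 0 for t in by_target}
    dependents: dict[str, list[str]] = {t: [] for t in by_target}
    for m in models:
        for pred in m.coefficients:
            if pred in by_target:
                indeg[m.target] += 1
                dependents[pred].append(m.target)
    queue = sorted(t for t, d in indeg.items() if d == 0)
    order: list[str] = []
    while queue:
        t = queue.pop(0)
        order.append(t)
        for dep in sorted(dependents[t]):
            indeg[dep] -= 1
            if indeg[dep] == 0:
                queue.append(dep)
        queue.sort()
    if len(order) != len(by_target):
        cyclic = sorted(set(by_target) - set(order))
        raise KnowledgebaseError(f"imputation models form a cycle: {cyclic}")
    return [by_target[t] for t in order]


# ---------------------------------------------------------------------------
# screening


def safe_screen(matrix: FeatureMatrix, k: int = 1000) -> list[str]:
    """Rank events by normalized outcome association; keep the top ``k``.

    The score of column ``x`` is ``|<x - x̄, y - ȳ>| / ||x - x̄||`` — the
    strength of the univariate association on the scale used by
    penalized-regression screening rules, so events a LASSO at a loose
    penalty would pick first rank highest.  Zero-variance columns are always
    discarded; ties break by lexicographic event id.  An all-constant matrix
    yields an empty selection with a warning.
    """
    if k < 1:
        raise KnowledgebaseError("k must be at least 1")
    X = matrix.events.to_numpy(dtype=float)
    y = matrix.outcome.astype(float)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    live = norms > 0
    if not live.any():
        warnings.warn("all candidate events are constant; nothing to screen")
        return []
    scores = np.zeros(X.shape[1])
    scores[live] = np.abs(Xc[:, live].T @ yc) / norms[live]
    cols = matrix.events.columns.to_numpy()
    order = sorted(
        (i for i in range(X.shape[1]) if live[i]),
        key=lambda i: (-scores[i], cols[i]),
    )
    return [str(cols[i]) for i in order[: min(k, len(order))]]


def safe_discard(matrix: FeatureMatrix, penalty_fraction: float = 0.5) -> list[str]:
    """Exact screening-rule discard test at penalty ``λ = f·λ_max``.

    Keeps column ``x`` iff ``|<x_c, y_c>| ≥ λ - ||x_c||·||y_c||·(λ_max-λ)/λ_max``
    where ``λ_max = max_j |<x_j_c, y_c>|`` — the classical pre-fit discard
    inequality for L1 regression, applied to the centered binary problem.
    Columns failing the test provably carry zero coefficient at that penalty.
    """
    if not 0.0 < penalty_fraction <= 1.0:
        raise KnowledgebaseError("penalty_fraction must lie in (0, 1]")
    X = matrix.events.to_numpy(dtype=float)
    y = matrix.outcome.astype(float)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    inner = np.abs(Xc.T @ yc)
    lam_max = inner.max()
    if lam_max == 0:
        return []
    lam = penalty_fraction * lam_max
    bound = lam - np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc) * (lam_max - lam) / lam_max
    keep = inner >= bound
    cols = matrix.events.columns.to_numpy()
    return [str(c) for c in cols[keep]]


# ---------------------------------------------------------------------------
# fitting


def l1_logistic(
    X: np.ndarray, y: np.ndarray, C: float, *, tol: float = 1e-8,
    max_iter: int = 5000,
) -> tuple[float, np.ndarray]:
    """L1-penalized logistic fit minimizing ``C·Σ log-loss + ||β||₁``.

    The intercept is unpenalized.  Returns ``(intercept, coefficients)``.
    When the penalty shrinks every coefficient to zero, the intercept is the
    closed-form optimum (log-odds of the base rate), where the stochastic
    solver can stall short of full precision.
    """
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="saga", tol=tol, max_iter=max_iter,
        random_state=0,
    ).fit(X, y)
    b = clf.coef_[0].copy()
    if not np.any(b != 0.0):
        base = float(np.clip(np.mean(y), 1e-12, 1 - 1e-12))
        return float(np.log(base / (1 - base))), b
    return float(clf.intercept_[0]), b


def _log_loss_sum(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def _kfold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def _ridged_refit(
    X: np.ndarray, y: np.ndarray, keep: np.ndarray
) -> tuple[float, np.ndarray]:
    """Lightly ridged refit on a support; near-unpenalized, separation-safe."""
    if not keep.any():
        base = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        return float(np.log(base / (1 - base))), np.zeros(0)
    clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000).fit(X[:, keep], y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def select_penalty(
    X: np.ndarray,
    y: np.ndarray,
    *,
    Cs: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Choose the L1 penalty by cross-validated deviance on the full data.

    Because the pipeline's final coefficients come from a near-unpenalized
    refit on the selected support, each candidate penalty is scored
    end-to-end (relaxed-LASSO style): the L1 fit on the training folds picks
    a support, the refit on that support is evaluated by deviance on the
    held-out fold.  This scores support quality directly rather than the
    shrunken fit, and ties favor the stronger penalty (sparser support).
    """
    Cs = sorted(Cs) if Cs is not None else list(np.logspace(-2.5, 0.5, 8))
    rng = np.random.default_rng(seed)
    fold_idx = _kfold_indices(len(y), folds, rng)
    best_C, best_dev = Cs[0], np.inf
    for C in Cs:
        dev = 0.0
        for f in range(folds):
            test = fold_idx[f]
            train = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
            if len(np.unique(y[train])) < 2:
                dev = np.inf
                break
            _, b = l1_logistic(X[train], y[train], C, tol=1e-6)
            keep = np.abs(b) > 1e-8
            b0r, br = _ridged_refit(X[train], y[train], keep)
            p = expit(b0r + X[test][:, keep] @ br)
            dev += 2.0 * _log_loss_sum(y[test], p)
        if dev < best_dev:
            best_C, best_dev = C, dev
    return float(best_C)


def fit_lasso_stability(
    matrix: FeatureMatrix,
    drug: str,
    *,
    n_subsets: int = 40,
    subsample_fraction: float = 0.8,
    retain_threshold: float = 0.5,
    seed: int = 0,
    penalty_C: float | None = None,
    population_tag: str = "general",
) -> DrugModel:
    """Stability-selected sparse logistic model for one drug.

    L1 fits are repeated on ``n_subsets`` random subsamples (drawn without
    replacement) at a penalty chosen by cross-validated deviance on the full
    data (or fixed via ``penalty_C``).  An event is retained iff its
    coefficient is nonzero in at least ``retain_threshold`` of the
    subsamples; final coefficients come from a lightly ridged refit on the
    retained set.  ``retained_fraction`` records the selection frequency of
    every screened event.
    """
    if n_subsets < 2:
        raise KnowledgebaseError("n_subsets must be at least 2")
    if not 0.0 < subsample_fraction <= 1.0:
        raise KnowledgebaseError("subsample_fraction must lie in (0, 1]")
    y = matrix.outcome
    if len(np.unique(y)) < 2:
        raise KnowledgebaseError("outcome has a single class; cannot fit")
    X = matrix.events.to_numpy(dtype=float)
    cols = [str(c) for c in matrix.events.columns]
    n = len(y)

    C = penalty_C if penalty_C is not None else select_penalty(X, y, seed=seed)

    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_fraction * n)))
    nonzero = np.zeros(len(cols))
    used = 0
    for s in range(n_subsets):
        idx = rng.choice(n, size=min(m, n), replace=False)
        if len(np.unique(y[idx])) < 2:
            continue
        _, b = l1_logistic(X[idx], y[idx], C, tol=1e-6)
        nonzero += np.abs(b) > 1e-8
        used += 1
    if used == 0:
        raise KnowledgebaseError("no subsample contained both outcome classes")
    frac = nonzero / used
    retained = [c for c, f in zip(cols, frac) if f >= retain_threshold]

    keep = np.array([c in set(retained) for c in cols])
    intercept, betas = _ridged_refit(X, y, keep)
    coefficients = {c: float(b) for c, b in zip(retained, betas)}

    return DrugModel(
        drug=drug,
        intercept=intercept,
        coefficients=coefficients,
        retained_fraction={c: float(f) for c, f in zip(cols, frac)},
        population_tag=population_tag,
    )


# ---------------------------------------------------------------------------
# evaluation


def auc_score(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the rank statistic over all response/non-response pairs.

    Tied scores count one half.  Undefined (error) for single-class input.
    """
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise KnowledgebaseError("AUC undefined for single-class outcome")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def mcfadden_r2(y: np.ndarray, probs: np.ndarray) -> float:
    """McFadden pseudo-R²: ``1 - ℓ_model / ℓ_null``.

    The null is the intercept-only model on the same rows (base-rate
    prediction), so the null model itself scores exactly 0.
    """
    y = np.asarray(y, dtype=float)
    base = y.mean()
    if base in (0.0, 1.0):
        raise KnowledgebaseError("McFadden R² undefined for single-class outcome")
    ll_model = -_log_loss_sum(y, probs)
    ll_null = -_log_loss_sum(y, np.full_like(y, base))
    return float(1.0 - ll_model / ll_null)


def evaluate_model(
    model: DrugModel, matrix: FeatureMatrix, *, threshold: float = 0.5
) -> dict[str, float]:
    """AUC, sensitivity/specificity at ``threshold``, and McFadden R²."""
    y = matrix.outcome
    p = model.predict_proba(matrix.events)
    pred = p >= threshold
    pos, neg = y == 1, y == 0
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[neg]).mean()) if neg.any() else float("nan")
    return {
        "auc": auc_score(y, p),
        "sensitivity": sens,
        "specificity": spec,
        "mcfadden_r2": mcfadden_r2(y, p),
    }


def evaluate_cv(
    matrix: FeatureMatrix,
    drug: str,
    *,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    **fit_kwargs,
) -> dict[str, float]:
    """Cross-validated metrics: fit on train folds, pool held-out scores."""
    rng = np.random.default_rng(seed)
    fold_idx = _kfold_indices(matrix.n, folds, rng)
    y_all, p_all = [], []
    for f in range(folds):
        test = fold_idx[f]
        train = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
        model = fit_lasso_stability(matrix.take(train), drug, seed=seed + f,
                                    **fit_kwargs)
        y_all.append(matrix.outcome[test])
        p_all.append(model.predict_proba(matrix.events.iloc[test]))
    y = np.concatenate(y_all)
    p = np.concatenate(p_all)
    pred = p >= threshold
    pos, neg = y == 1, y == 0
    return {
        "auc": auc_score(y, p),
        "sensitivity": float(pred[pos].mean()) if pos.any() else float("nan"),
        "specificity": float((~pred[neg]).mean()) if neg.any() else float("nan"),
        "mcfadden_r2": mcfadden_r2(y, p),
    }


def build_drug_model(
    matrix: FeatureMatrix,
    drug: str,
    *,
    screen_k: int = 1000,
    seed: int = 0,
    cv_folds: int = 5,
    **fit_kwargs,
) -> DrugModel:
    """Full pipeline for one drug: screen, stability-fit, CV-evaluate."""
    selected = safe_screen(matrix, k=screen_k)
    if not selected:
        raise KnowledgebaseError("screening discarded every candidate event")
    sub = matrix.restrict(selected)
    model = fit_lasso_stability(sub, drug, seed=seed, **fit_kwargs)
    model.metrics = evaluate_cv(sub, drug, folds=cv_folds, seed=seed, **fit_kwargs)
    return model


# ---------------------------------------------------------------------------
# serialization


def _model_to_dict(m: DrugModel) -> dict:
    return asdict(m)


def _model_from_dict(d: dict) -> DrugModel:
    return DrugModel(**d)


def save_kb(kb: Knowledgebase, path: str | Path) -> None:
    """Serialize a validated knowledgebase to versioned JSON."""
    kb.validate()
    doc = {
        "version": kb.version,
        "schema": kb.schema.events,
        "models": {d: _model_to_dict(m) for d, m in kb.models.items()},
        "subgroup_models": {
            s: {d: _model_to_dict(m) for d, m in by_drug.items()}
            for s, by_drug in kb.subgroup_models.items()
        },
        "imputation_models": [asdict(m) for m in kb.imputation_models],
        "routing": kb.routing,
        "provenance": kb.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_kb(path: str | Path) -> Knowledgebase:
    """Load and validate a knowledgebase JSON document."""
    doc = json.loads(Path(path).read_text())
    for key in ("version", "schema", "models"):
        if key not in doc:
            raise KnowledgebaseError(f"knowledgebase document lacks field {key!r}")
    kb = Knowledgebase(
        schema=EventSchema(doc["schema"]),
        models={d: _model_from_dict(m) for d, m in doc["models"].items()},
        subgroup_models={
            s: {d: _model_from_dict(m) for d, m in by_drug.items()}
            for s, by_drug in doc.get("subgroup_models", {}).items()
        },
        imputation_models=[ImputationModel(**m) for m in doc.get("imputation_models", [])],
        routing=doc.get("routing", {}),
        provenance=doc.get("provenance", {}),
        version=doc["version"],
    )
    kb.validate()
    return kb


def coefficient_export(kb: Knowledgebase) -> pd.DataFrame:
    """Flat coefficient table: drug, population, event, beta, retention."""
    rows = []
    pools = [("general", kb.models)]
    pools += [(f"subgroup:{s}", ms) for s, ms in sorted(kb.subgroup_models.items())]
    for tag, models in pools:
        for drug in sorted(models):
            m = models[drug]
            for ev in sorted(m.coefficients):
                rows.append(
                    {
                        "drug": drug,
                        "population": tag,
                        "event": ev,
                        "coefficient": m.coefficients[ev],
                        "retained_fraction": m.retained_fraction.get(ev, float("nan")),
                    }
                )
    return pd.DataFrame(rows, columns=["drug", "population", "event",
                                       "coefficient", "retained_fraction"])
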