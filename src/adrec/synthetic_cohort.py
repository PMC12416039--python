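"""Synthetic claims-like cohorts with known ground-truth response models.

Real antidepressant-response knowledgebases are built from proprietary claims
and EHR sources.  This module emulates those sources: binary medical-history
events with configurable prevalence and (optional block-equicorrelated)
correlation, per-drug ground-truth logistic response models with optional
subgroup-specific coefficient shifts, and dispensing streams constructed so
that episode building recovers the intended four-way disposition exactly.
Everything is reproducible from a single integer seed, so downstream fitting,
auditing, and advice stages can be tested against known truth.

Conventions: days are integer offsets with day 0 = cohort start and all
intervals half-open ``[start, end)``; history-event dates fall in the year
before day 365 of follow-up and carry no semantics beyond reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import rankdata

from adrec.episodes import DISPOSITIONS, EpisodeWindows

#: The four medical-history vocabularies: diagnoses, medications, procedures,
#: and prior antidepressant responses.
VOCABULARIES = ("DX", "RX", "PX", "ADR")

_FILL_SUPPLY = 30  # days per synthetic fill


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


def event_ids(n_events: int) -> list[str]:
    """Synthetic event identifiers, cycling through the four vocabularies."""
    return [f"{VOCABULARIES[i % 4]}_{i:04d}" for i in range(n_events)]


def event_vocabulary(event_id: str) -> str:
    return event_id.split("_", 1)[0]


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth logistic response model for one drug.

    ``P(response | x) = expit(intercept + sum_j coefficients[j] * x_j)``.
    """

    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)


def _default_nonresponse_mix() -> dict[str, float]:
    # Conditional disposition split among non-responders matching the
    # 46.3 / 12.8 / 35.1 / 5.9 four-way cohort split.
    return {"discontinued": 0.652, "switched": 0.238, "augmented": 0.110}


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort.

    Parameters
    ----------
    n_patients:
        Cohort size; each patient contributes one treatment episode.
    drugs:
        Antidepressants dispensed; each patient is assigned one uniformly.
    n_events:
        Number of candidate binary medical-history events.
    event_prevalence:
        Marginal probability of each event, scalar or one value per event.
    true_models:
        Ground-truth logistic model per drug; coefficient keys must name
        declared events.
    subgroup_fraction:
        Proportion of patients assigned to the designated subgroup.
    subgroup_shifts:
        Per-drug coefficient deltas added to the linear predictor inside the
        subgroup (keys: drug -> event -> delta; ``"__intercept__"`` shifts
        the intercept).
    event_correlation:
        Equicorrelation of the latent Gaussian within consecutive blocks of
        ``correlation_block_size`` events; 0 = independent sampling.
    nonresponse_mix:
        Conditional disposition probabilities for non-responders
        (responders always continue).
    """

    n_patients: int
    drugs: Sequence[str]
    n_events: int
    event_prevalence: float | Sequence[float] = 0.3
    true_models: Mapping[str, TrueModel] = field(default_factory=dict)
    subgroup_fraction: float = 0.0
    subgroup_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    event_correlation: float = 0.0
    correlation_block_size: int = 1
    nonresponse_mix: Mapping[str, float] = field(default_factory=_default_nonresponse_mix)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if not self.drugs:
            raise ConfigurationError("drug list must be nonempty")
        if self.n_events < 1:
            raise ConfigurationError("n_events must be positive")
        prev = np.atleast_1d(np.asarray(self.event_prevalence, dtype=float))
        if prev.size not in (1, self.n_events):
            raise ConfigurationError(
                "event_prevalence must be scalar or one value per event"
            )
        if np.any((prev < 0) | (prev > 1)):
            raise ConfigurationError("event prevalences must lie in [0, 1]")
        if not 0.0 <= self.subgroup_fraction <= 1.0:
            raise ConfigurationError("subgroup_fraction must lie in [0, 1]")
        if not 0.0 <= self.event_correlation < 1.0:
            raise ConfigurationError("event_correlation must lie in [0, 1)")
        ids = set(event_ids(self.n_events))
        for drug in self.drugs:
            if drug not in self.true_models:
                raise ConfigurationError(f"no true model declared for {drug!r}")
        for drug, model in self.true_models.items():
            bad = set(model.coefficients) - ids
            if bad:
                raise ConfigurationError(
                    f"model for {drug!r} references undeclared events: {sorted(bad)}"
                )
        for drug, shifts in self.subgroup_shifts.items():
            bad = set(shifts) - ids - {"__intercept__"}
            if bad:
                raise ConfigurationError(
                    f"subgroup shift for {drug!r} references undeclared events: "
                    f"{sorted(bad)}"
                )
        mix = dict(self.nonresponse_mix)
        if set(mix) - {"discontinued", "switched", "augmented"}:
            raise ConfigurationError("nonresponse_mix keys must be non-continued dispositions")
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("nonresponse_mix must be a probability distribution")

    @property
    def event_ids(self) -> list[str]:
        return event_ids(self.n_events)

    def prevalence_vector(self) -> np.ndarray:
        prev = np.atleast_1d(np.asarray(self.event_prevalence, dtype=float))
        if prev.size == 1:
            prev = np.repeat(prev, self.n_events)
        return prev


def _sample_events(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Binary event matrix (patients x events) honoring marginal prevalence."""
    n, m = config.n_patients, config.n_events
    prev = config.prevalence_vector()
    rho = config.event_correlation
    if rho == 0.0:
        return (rng.random((n, m)) < prev).astype(np.int8)
    # Latent equicorrelated Gaussian per block, thresholded at the marginal
    # quantile so prevalence is preserved under correlation.
    bs = max(1, config.correlation_block_size)
    z = np.empty((n, m))
    for start in range(0, m, bs):
        width = min(bs, m - start)
        common = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, width))
        z[:, start:start + width] = np.sqrt(rho) * common + np.sqrt(1 - rho) * noise
    with np.errstate(divide="ignore"):
        thresh = ndtri(prev)
    return (z < thresh).astype(np.int8)


def linear_predictor(
    X: pd.DataFrame, model: TrueModel, shift: Mapping[str, float] | None = None
) -> np.ndarray:
    """Ground-truth linear index for every row of a binary event table."""
    lp = np.full(len(X), float(model.intercept))
    coefs: dict[str, float] = dict(model.coefficients)
    if shift:
        for key, delta in shift.items():
            if key == "__intercept__":
                lp += delta
            else:
                coefs[key] = coefs.get(key, 0.0) + delta
    for ev, beta in coefs.items():
        lp += beta * X[ev].to_numpy()
    return lp


def _disposition_fills(
    disposition: str, pid: str, index_drug: str, alt_drug: str,
    windows: EpisodeWindows,
) -> list[tuple[str, str, int, int]]:
    """Dispensing stream realizing one disposition for one patient.

    Streams are designed so that :func:`adrec.episodes.build_episodes`
    recovers the disposition exactly under the given windows.
    """
    s = _FILL_SUPPLY
    D = windows.disposition_window_days
    gap = windows.gap_tolerance_days
    if disposition == "continued":
        return [(pid, index_drug, day, s) for day in range(0, D, s)]
    if disposition == "discontinued":
        if s + gap >= D:
            raise ConfigurationError("disposition window too short for planted lapse")
        return [(pid, index_drug, 0, s)]
    if disposition == "switched":
        t = s + gap + 5
        if t >= D:
            raise ConfigurationError("disposition window too short for planted switch")
        return [(pid, index_drug, 0, s), (pid, alt_drug, t, s)]
    if disposition == "augmented":
        # Second index fill keeps coverage alive when the other drug starts.
        return [
            (pid, index_drug, 0, s),
            (pid, index_drug, s - 2, s),
            (pid, alt_drug, s + 10, s),
        ]
    raise ConfigurationError(f"unknown disposition: {disposition!r}")


def _alt_drug(index_drug: str, drugs: Sequence[str]) -> str:
    if index_drug != "other":
        return "other"
    for d in drugs:
        if d != index_drug:
            return d
    return "alt_antidepressant"


def generate_cohort(
    config: CohortConfig,
    windows: EpisodeWindows | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate event records, dispensing records, and ground-truth labels.

    Returns
    -------
    events:
        Long table ``(patient_id, vocabulary, code, date)`` of the binary
        medical-history events present for each patient.
    dispensings:
        Long table ``(patient_id, drug, fill_date, days_supply)`` whose
        episode construction reproduces each patient's planted disposition.
    truth:
        One row per patient: assigned drug, subgroup flag, ground-truth
        linear predictor, response probability, realized binary response,
        and planted disposition.
    """
    windows = windows or EpisodeWindows()
    rng = np.random.default_rng(config.seed)
    ids = config.event_ids
    n = config.n_patients
    width = max(5, len(str(n - 1)))
    pids = [f"P{i:0{width}d}" for i in range(n)]

    X = _sample_events(config, rng)
    Xdf = pd.DataFrame(X, index=pids, columns=ids)
    in_subgroup = rng.random(n) < config.subgroup_fraction
    drug_idx = rng.integers(0, len(config.drugs), size=n)
    assigned = np.asarray(config.drugs, dtype=object)[drug_idx]

    lp = np.empty(n)
    for drug in config.drugs:
        mask = assigned == drug
        if not mask.any():
            continue
        model = config.true_models[drug]
        shift = config.subgroup_shifts.get(drug)
        base = linear_predictor(Xdf.loc[mask], model)
        lp[mask] = base
        if shift is not None and in_subgroup[mask].any():
            shifted = linear_predictor(Xdf.loc[mask], model, shift)
            lp[mask] = np.where(in_subgroup[mask], shifted, base)
    prob = expit(lp)
    response = (rng.random(n) < prob).astype(int)

    mix_labels = sorted(config.nonresponse_mix)
    mix_p = np.array([config.nonresponse_mix[k] for k in mix_labels])
    nonresp_draw = rng.choice(len(mix_labels), size=n, p=mix_p)
    disposition = np.where(
        response == 1,
        "continued",
        np.asarray(mix_labels, dtype=object)[nonresp_draw],
    )

    # Long event records: one row per present (patient, event) pair.
    pat_pos, ev_pos = np.nonzero(X)
    dates = rng.integers(0, 365, size=pat_pos.size)
    events = pd.DataFrame(
        {
            "patient_id": [pids[i] for i in pat_pos],
            "vocabulary": [event_vocabulary(ids[j]) for j in ev_pos],
            "code": [ids[j] for j in ev_pos],
            "date": dates,
        }
    )

    fills: list[tuple[str, str, int, int]] = []
    for i, pid in enumerate(pids):
        drug = assigned[i]
        fills.extend(
            _disposition_fills(
                str(disposition[i]), pid, drug, _alt_drug(drug, config.drugs),
                windows,
            )
        )
    dispensings = pd.DataFrame(
        fills, columns=["patient_id", "drug", "fill_date", "days_supply"]
    )

    truth = pd.DataFrame(
        {
            "patient_id": pids,
            "drug": assigned,
            "subgroup": in_subgroup,
            "linear_predictor": lp,
            "response_prob": prob,
            "response": response,
            "disposition": disposition,
        }
    )
    return events, dispensings, truth


def feature_table(
    events: pd.DataFrame, patient_ids: Sequence[str], schema_ids: Sequence[str]
) -> pd.DataFrame:
    """Wide binary event table (patients x events) from long event records."""
    wide = pd.DataFrame(0, index=list(patient_ids), columns=list(schema_ids),
                        dtype=np.int8)
    present = events[events["code"].isin(schema_ids)
                     & events["patient_id"].isin(wide.index)]
    for pid, code in zip(present["patient_id"], present["code"]):
        wide.at[pid, code] = 1
    return wide


def largest_remainder(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Apportion ``n`` units across categories by largest-remainder rounding.

    Quotas ``w_k * n`` are floored; leftover units go to the categories with
    the largest fractional remainders (ties broken by category name).
    """
    keys = sorted(weights)
    quotas = {k: weights[k] * n for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    leftover = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_remainder[:leftover]:
        counts[k] += 1
    return counts


def plant_disposition_mix(
    proportions: Mapping[str, float],
    n: int,
    seed: int,
    *,
    drugs: Sequence[str] = ("sertraline",),
    windows: EpisodeWindows | None = None,
) -> pd.DataFrame:
    """Dispensing records realizing an exact planted disposition mix.

    Disposition counts follow largest-remainder apportionment of the target
    proportions, so episode building recovers them exactly.  Proportions must
    be nonnegative and sum to 1; sums off by at most 0.01 (as happens when
    targets are copied from percentages printed to one decimal) are
    renormalized, larger deviations are an error.  The seed shuffles patient
    order so dispositions are interleaved.
    """
    windows = windows or EpisodeWindows()
    props = dict(proportions)
    unknown = set(props) - set(DISPOSITIONS)
    if unknown:
        raise ConfigurationError(f"unknown dispositions: {sorted(unknown)}")
    if any(v < 0 for v in props.values()):
        raise ConfigurationError("proportions must be nonnegative")
    total = sum(props.values())
    if abs(total - 1.0) > 0.01:
        raise ConfigurationError(f"proportions sum to {total!r}, not 1")
    props = {k: v / total for k, v in props.items()}

    counts = largest_remainder(props, n)
    labels = [d for d in DISPOSITIONS if d in counts for _ in range(counts[d])]
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)

    width = max(5, len(str(max(n - 1, 1))))
    fills: list[tuple[str, str, int, int]] = []
    for i, disposition in enumerate(labels):
        pid = f"P{i:0{width}d}"
        drug = drugs[i % len(drugs)]
        fills.extend(
            _disposition_fills(disposition, pid, drug, _alt_drug(drug, drugs),
                               windows)
        )
    return pd.DataFrame(
        fills, columns=["patient_id", "drug", "fill_date", "days_supply"]
    )


def theoretical_auc(
    model: TrueModel,
    config: CohortConfig,
    n_sim: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo AUC of the generating model against its own labels.

    Simulates event vectors under the cohort's prevalence/correlation
    settings, draws labels from the true response probabilities, and scores
    the true probabilities by the rank (Mann-Whitney) statistic with ties
    counted one half.  This is the ceiling any fitted model can reach.
    """
    sim = CohortConfig(
        n_patients=n_sim,
        drugs=["_sim"],
        n_events=config.n_events,
        event_prevalence=config.event_prevalence,
        true_models={"_sim": model},
        event_correlation=config.event_correlation,
        correlation_block_size=config.correlation_block_size,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    X = _sample_events(sim, rng)
    Xdf = pd.DataFrame(X, columns=sim.event_ids)
    p = expit(linear_predictor(Xdf, model))
    y = (rng.random(n_sim) < p).astype(int)
    n_pos = int(y.sum())
    n_neg = n_sim - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate simulation: single-class labels")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
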