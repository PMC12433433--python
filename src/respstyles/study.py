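"""Monte-Carlo study driver: condition grids, replication loops, accuracy
tables, and the empirical resampling design.

A study cell crosses sample size N ∈ {250, 500, 1000}, test length
J ∈ {10, 20} and substantive dimensionality D ∈ {1, 2}; response-style
regimes add the trait SD σ_RS ∈ {0.6, 1, 1.5} and, for the two-dimensional
regime, the ERS–MRS trait correlation r_RS ∈ {-.5, 0, .5} and the item-slope
correlation ∈ {0, 1} — 12, 36 and 216 cells for the three regimes.  Each
replication generates a dataset, fits all three candidate models, and records
which model the AIC, the BIC and the combined BIC-then-AIC rule select.
Classification accuracy is the percentage of replications in which a
criterion selects the data-generating model.

Every replication is reproducible in isolation: its random seed is a stable
hash of (base seed, condition content, replication index), so scheduling and
parallelism cannot change results.
"""

from __future__ import annotations

import itertools
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datagen import GenCondition, ResponseMatrix, generate_dataset
from .estimation import FitOptions, fit_mnrm, fitted_model_battery
from .model import MISSING, ModelSpec
from .selection import (
    combined_select,
    information_criteria,
    select_by_criterion,
)

__all__ = ["StudyConfig", "default_conditions", "derive_seed",
           "run_replication", "run_study", "classification_accuracy",
           "factor_marginals", "slash_table", "resample_study"]

DEFAULT_N = (250, 500, 1000)
DEFAULT_J = (10, 20)
DEFAULT_D = (1, 2)
DEFAULT_SIGMA_RS = (0.6, 1.0, 1.5)
DEFAULT_R_RS = (-0.5, 0.0, 0.5)
DEFAULT_SLOPE_CORR = (0, 1)

#: Design-factor columns a study record carries.
FACTOR_COLUMNS = ("n_persons", "n_items", "n_substantive", "sigma_rs",
                  "r_rs", "slope_corr")

#: Estimator settings for Monte-Carlo runs: a slightly looser stopping rule
#: than the library default.  Classification decisions rest on AIC/BIC
#: differences of whole units, far above what the final crawl of the EM
#: contributes, and selections were checked to agree with tight-tolerance
#: fits across regimes.
STUDY_FIT_OPTIONS = FitOptions(tol_loglik=2e-3, tol_param=2e-3,
                               stall_window=15, stall_tol=0.15,
                               max_cycles=120)


@dataclass(frozen=True)
class StudyConfig:
    """Scope and scale of a simulation study.

    Defaults reproduce the full factorial design (264 cells, 250
    replications each) — a long-running batch job.  Reduced runs override the
    factor levels and replication count; derived seeds make any subset
    consistent with the full run.
    """

    regimes: tuple[str, ...] = ("null", "ers_mrs", "ers_plus_mrs")
    n_levels: tuple[int, ...] = DEFAULT_N
    j_levels: tuple[int, ...] = DEFAULT_J
    d_levels: tuple[int, ...] = DEFAULT_D
    sigma_levels: tuple[float, ...] = DEFAULT_SIGMA_RS
    r_levels: tuple[float, ...] = DEFAULT_R_RS
    slope_corr_levels: tuple[int, ...] = DEFAULT_SLOPE_CORR
    replications: int = 250
    base_seed: int = 0
    workers: int = 1
    fit_options: FitOptions = field(default_factory=lambda: STUDY_FIT_OPTIONS)

    def conditions(self) -> list[GenCondition]:
        out: list[GenCondition] = []
        for regime in self.regimes:
            out.extend(default_conditions(
                regime, self.n_levels, self.j_levels, self.d_levels,
                self.sigma_levels, self.r_levels, self.slope_corr_levels))
        return out


def default_conditions(kind: str,
                       n_levels=DEFAULT_N, j_levels=DEFAULT_J,
                       d_levels=DEFAULT_D, sigma_levels=DEFAULT_SIGMA_RS,
                       r_levels=DEFAULT_R_RS,
                       slope_corr_levels=DEFAULT_SLOPE_CORR) -> list[GenCondition]:
    """The factorial grid of one generating regime (seeds filled later)."""
    base = list(itertools.product(n_levels, j_levels, d_levels))
    cells: list[GenCondition] = []
    if kind == "null":
        for N, J, D in base:
            cells.append(GenCondition("null", N, J, D))
    elif kind == "ers_mrs":
        for (N, J, D), s in itertools.product(base, sigma_levels):
            cells.append(GenCondition("ers_mrs", N, J, D, sigma_rs=s))
    elif kind == "ers_plus_mrs":
        for (N, J, D), s, r, sc in itertools.product(
                base, sigma_levels, r_levels, slope_corr_levels):
            cells.append(GenCondition("ers_plus_mrs", N, J, D, sigma_rs=s,
                                      r_rs=r, slope_corr=sc))
    else:
        raise ValueError(f"unknown regime {kind!r}")
    return cells


def derive_seed(base_seed: int, condition: GenCondition, rep_index: int) -> int:
    """Stable 31-bit seed for one (condition, replication) pair.

    Hashes the condition content (not its position in any grid), so a cell
    re-run in isolation reproduces its records from the full study.
    """
    key = (f"{condition.kind}|{condition.n_persons}|{condition.n_items}|"
           f"{condition.n_substantive}|{condition.sigma_rs}|{condition.r_rs}|"
           f"{condition.slope_corr}|{condition.n_categories}")
    cell_hash = zlib.crc32(key.encode())
    mixed = np.random.SeedSequence((int(base_seed), cell_hash, int(rep_index)))
    return int(mixed.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def _condition_record(condition: GenCondition) -> dict:
    return {
        "kind": condition.kind,
        "n_persons": condition.n_persons,
        "n_items": condition.n_items,
        "n_substantive": condition.n_substantive,
        "sigma_rs": condition.sigma_rs,
        "r_rs": condition.r_rs,
        "slope_corr": condition.slope_corr,
    }


def run_replication(condition: GenCondition, rep_index: int, base_seed: int = 0,
                    options: FitOptions = STUDY_FIT_OPTIONS) -> dict:
    """Generate one dataset, fit the three candidate models, select.

    Estimation failures are recorded in the returned record rather than
    raised, so a study always completes.
    """
    seed = derive_seed(base_seed, condition, rep_index)
    cell = GenCondition(**{**_condition_record(condition),
                           "n_categories": condition.n_categories, "seed": seed})
    record = _condition_record(condition)
    record.update(rep=rep_index, seed=seed)
    start = time.perf_counter()
    try:
        data, _, _, n_redraws = generate_dataset(cell)
        fits = fitted_model_battery(data, condition.n_substantive, options)
        pairs = [information_criteria(f) for f in fits.values()]
        record.update(
            n_redraws=n_redraws,
            selected_aic=select_by_criterion(pairs, "aic"),
            selected_bic=select_by_criterion(pairs, "bic"),
            selected_combined=combined_select(pairs),
            all_converged=all(f.converged for f in fits.values()),
            error="",
        )
    except Exception as exc:  # a failed replication must not kill the study
        record.update(n_redraws=np.nan, selected_aic=None, selected_bic=None,
                      selected_combined=None, all_converged=False,
                      error=f"{type(exc).__name__}: {exc}")
    record["runtime_s"] = time.perf_counter() - start
    return record


def run_study(config: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run every cell x replication of a study; one tidy record per fit.

    Replications are independent given their derived seeds, so the joblib
    scheduling (``config.workers``) cannot change any result.
    """
    tasks = [(condition, rep)
             for condition in config.conditions()
             for rep in range(config.replications)]
    runner = Parallel(n_jobs=config.workers, verbose=10 if progress else 0)
    records = runner(
        delayed(run_replication)(condition, rep, config.base_seed,
                                 config.fit_options)
        for condition, rep in tasks)
    return pd.DataFrame.from_records(records)


def _correct(results: pd.DataFrame, criterion: str) -> pd.Series:
    column = f"selected_{criterion}"
    if column not in results.columns:
        raise ValueError(f"unknown criterion {criterion!r}")
    return (results[column] == results["kind"]).astype(float)


def classification_accuracy(results: pd.DataFrame, group_by=(),
                            criterion: str = "bic") -> pd.DataFrame:
    """Percentage of replications whose selected model matches the
    generating model, per group (or overall for no grouping factors)."""
    if results.empty:
        raise ValueError("no study records")
    unknown = [g for g in group_by if g not in results.columns]
    if unknown:
        raise ValueError(f"unknown factor name(s): {unknown}")
    frame = results.assign(correct=_correct(results, criterion))
    if not group_by:
        return pd.DataFrame({"accuracy": [100.0 * frame["correct"].mean()],
                             "n": [len(frame)]})
    grouped = frame.groupby(list(group_by), dropna=False)["correct"]
    out = grouped.agg(["mean", "size"]).reset_index()
    out["accuracy"] = 100.0 * out.pop("mean")
    return out.rename(columns={"size": "n"})


def factor_marginals(results: pd.DataFrame, criterion: str = "bic") -> pd.DataFrame:
    """Classification accuracy marginal to each applicable design factor.

    Marginals are record-weighted means of cell accuracies, i.e. the accuracy
    over all records at each factor level.
    """
    if results.empty:
        raise ValueError("no study records")
    rows = []
    for factor in FACTOR_COLUMNS:
        if factor not in results.columns or results[factor].isna().all():
            continue
        acc = classification_accuracy(results, (factor,), criterion)
        for _, row in acc.iterrows():
            rows.append({"factor": factor, "level": row[factor],
                         "accuracy": row["accuracy"], "n": int(row["n"])})
    return pd.DataFrame(rows)


def slash_table(results: pd.DataFrame, criterion: str = "bic",
                group_by=("sigma_rs", "r_rs", "n_substantive", "n_persons",
                          "n_items")) -> pd.DataFrame:
    """Two-dimensional-regime table with the 'slope corr 1 / slope corr 0'
    cell convention used for reporting."""
    acc = classification_accuracy(results, tuple(group_by) + ("slope_corr",),
                                  criterion)
    wide = acc.pivot_table(index=list(group_by), columns="slope_corr",
                           values="accuracy")
    out = wide.apply(
        lambda row: f"{row.get(1, float('nan')):.0f}/{row.get(0, float('nan')):.0f}",
        axis=1).rename("accuracy_corr1/corr0").reset_index()
    return out


def _fix_unendorsed(responses: np.ndarray, n_categories: int) -> tuple[np.ndarray, list]:
    """Replace one missing value per unendorsed (item, category) pair.

    For each category of each item that nobody endorsed in a subsample, the
    item's first missing entry is set to that category so every fitted model
    sees all K categories.  Items with no missing entry left are logged and
    returned unchanged.
    """
    out = responses.copy()
    unfixable = []
    for j in range(out.shape[1]):
        for k in range(n_categories):
            if np.any(out[:, j] == k):
                continue
            missing_rows = np.nonzero(out[:, j] == MISSING)[0]
            if missing_rows.size == 0:
                unfixable.append((j, k))
                continue
            out[missing_rows[0], j] = k
    return out, unfixable


def resample_study(data: ResponseMatrix, n_people: int, item_subset_size: int,
                   n_resamples: int = 100, assumed_true_model: str = "ers_plus_mrs",
                   item_scales=None, seed: int = 0,
                   options: FitOptions = STUDY_FIT_OPTIONS) -> pd.DataFrame:
    """Resampling-based study on one (typically large, real) dataset.

    Each resample draws ``n_people`` persons and ``item_subset_size`` items,
    both without replacement (matching the structure of the source data),
    applies the unendorsed-category fix, fits the three candidate models and
    records each criterion's selection.  ``assumed_true_model`` plays the
    role of the generating model when scoring accuracy; it is a user input
    because with real data the truth is taken from the full-sample selection.

    ``item_scales`` optionally maps each column to a substantive scale; the
    fitted dimensionality is then the number of scales present in each
    subsample (resamples are redrawn, with a derived sub-seed, until every
    scale contributes at least one item).
    """
    if n_people > data.n_persons or item_subset_size > data.n_items:
        raise ValueError("subsample sizes exceed the data")
    if item_scales is not None and len(item_scales) != data.n_items:
        raise ValueError("item_scales must label every column")
    scales = None if item_scales is None else np.asarray(item_scales)
    records = []
    for b in range(n_resamples):
        rng = np.random.default_rng(np.random.SeedSequence((seed, b)))
        people = np.sort(rng.choice(data.n_persons, size=n_people, replace=False))
        for _ in range(100):
            items = np.sort(rng.choice(data.n_items, size=item_subset_size,
                                       replace=False))
            if scales is None or np.unique(scales[items]).size == np.unique(scales).size:
                break
        sub = data.responses[np.ix_(people, items)]
        fixed, unfixable = _fix_unendorsed(sub, data.n_categories)
        subsample = ResponseMatrix(
            fixed, n_categories=data.n_categories,
            item_labels=tuple(data.item_labels[j] for j in items),
            person_ids=tuple(data.person_ids[p] for p in people))
        record = {"resample": b, "n_persons": n_people,
                  "n_items": item_subset_size, "kind": assumed_true_model,
                  "n_unfixable": len(unfixable)}
        try:
            if scales is None:
                assignment = None
                n_sub = 1
            else:
                _, assignment = np.unique(scales[items], return_inverse=True)
                n_sub = int(assignment.max()) + 1
            fits = {}
            for kind in ("null", "ers_mrs", "ers_plus_mrs"):
                if assignment is None:
                    spec = ModelSpec.create(kind, item_subset_size, n_sub,
                                            data.n_categories)
                else:
                    spec = ModelSpec(kind, n_sub, data.n_categories,
                                     tuple(int(a) for a in assignment))
                fits[kind] = fit_mnrm(subsample, spec, options)
            pairs = [information_criteria(f) for f in fits.values()]
            record.update(
                selected_aic=select_by_criterion(pairs, "aic"),
                selected_bic=select_by_criterion(pairs, "bic"),
                selected_combined=combined_select(pairs),
                all_converged=all(f.converged for f in fits.values()),
                error="")
        except Exception as exc:
            record.update(selected_aic=None, selected_bic=None,
                          selected_combined=None, all_converged=False,
                          error=f"{type(exc).__name__}: {exc}")
        records.append(record)
    return pd.DataFrame.from_records(records)
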