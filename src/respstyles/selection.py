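"""Information criteria and model choice.

Three candidate models are compared on the same data: ``null`` (no response
style), ``ers_mrs`` (one bipolar response-style dimension) and
``ers_plus_mrs`` (separate ERS and MRS dimensions).  The criteria are the
standard AIC = -2l + 2p and BIC = -2l + p ln N; the model with the lowest
value wins.  A combined rule uses the conservative BIC as a gate for the
presence of any response style and, if the gate opens, the more liberal AIC
to pick between the two response-style conceptualizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult

__all__ = ["CriterionPair", "information_criteria", "select_by_criterion",
           "combined_select", "criterion_table"]

#: Fixed comparison order, most parsimonious first (used for tie-breaking).
MODEL_ORDER = ("null", "ers_mrs", "ers_plus_mrs")


@dataclass(frozen=True)
class CriterionPair:
    """AIC and BIC of one fitted model."""

    model: str
    aic: float
    bic: float
    loglik: float = float("nan")
    n_params: int = 0
    n_persons: int = 0


def information_criteria(fit: FitResult) -> CriterionPair:
    """AIC and BIC of a fit: ``-2l + 2p`` and ``-2l + p ln N``."""
    if fit.n_persons < 1:
        raise ValueError("information criteria need at least one person")
    if not np.isfinite(fit.loglik):
        raise ValueError("log-likelihood must be finite")
    aic = -2.0 * fit.loglik + 2.0 * fit.n_params
    bic = -2.0 * fit.loglik + fit.n_params * np.log(fit.n_persons)
    return CriterionPair(fit.spec.kind, aic, bic, fit.loglik,
                         fit.n_params, fit.n_persons)


def _ordered(pairs) -> list[CriterionPair]:
    by_model = {p.model: p for p in pairs}
    if set(by_model) != set(MODEL_ORDER):
        raise ValueError(f"expected one pair per model in {MODEL_ORDER}")
    return [by_model[m] for m in MODEL_ORDER]


def select_by_criterion(pairs, criterion: str) -> str:
    """Label of the model with the lowest AIC or BIC.

    Exact ties go to the more parsimonious model (the earlier one in the
    null < ers_mrs < ers_plus_mrs order).  Non-finite values exclude a model
    with a warning; if none is finite, an error is raised.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    best, best_value = None, np.inf
    for pair in _ordered(pairs):
        value = getattr(pair, criterion)
        if not np.isfinite(value):
            warnings.warn(f"non-finite {criterion} for model {pair.model!r}; "
                          "excluded from selection", RuntimeWarning, stacklevel=2)
            continue
        if value < best_value:  # strict: ties keep the more parsimonious model
            best, best_value = pair.model, value
    if best is None:
        raise ValueError("no model has a finite criterion value")
    return best


def combined_select(pairs) -> str:
    """BIC-gated selection: BIC decides whether any response style is present;
    if it prefers moving away from the null model, the AIC picks between the
    bipolar and the two-dimensional response-style model."""
    null, ers_mrs, ers_plus = _ordered(pairs)
    best_rs_bic = min(ers_mrs.bic, ers_plus.bic)
    if not np.isfinite(best_rs_bic) or null.bic <= best_rs_bic:
        return "null"
    # gate open: the AIC arbitrates between the two response-style models,
    # ties going to the more parsimonious bipolar model
    return ers_mrs.model if ers_mrs.aic <= ers_plus.aic else ers_plus.model


def criterion_table(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Tidy comparison table with per-criterion selection flags."""
    pairs = [information_criteria(fits[m]) for m in MODEL_ORDER]
    aic_choice = select_by_criterion(pairs, "aic")
    bic_choice = select_by_criterion(pairs, "bic")
    combined_choice = combined_select(pairs)
    return pd.DataFrame({
        "model": [p.model for p in pairs],
        "loglik": [p.loglik for p in pairs],
        "n_params": [p.n_params for p in pairs],
        "aic": [p.aic for p in pairs],
        "bic": [p.bic for p in pairs],
        "selected_aic": [p.model == aic_choice for p in pairs],
        "selected_bic": [p.model == bic_choice for p in pairs],
        "selected_combined": [p.model == combined_choice for p in pairs],
    })
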