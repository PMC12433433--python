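"""Reading and writing Likert response tables and fit results.

Files use 1-based category codes (1..K) in a plain comma-separated table with
a header row of item labels; an empty field is a missing response.  Internally
categories are 0-based (0..K-1) with -1 for missing, so the linear scoring row
(0, 1, ..., K-1) doubles as the internal code list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import ResponseMatrix
from .estimation import FitResult
from .model import MISSING

__all__ = ["read_responses", "write_responses", "validate_for_fitting",
           "ValidationReport", "write_fit_json"]


def read_responses(path, n_categories: int = 5) -> ResponseMatrix:
    """Read a response table from CSV.

    Codes must be integers in 1..K; blanks are missing.  Out-of-range or
    non-integer codes are rejected with the offending row and column named.
    """
    frame = pd.read_csv(path, dtype="float64")
    values = frame.to_numpy()
    responses = np.full(values.shape, MISSING, dtype=np.int64)
    observed = ~np.isnan(values)
    if np.any(observed & (values != np.floor(values))):
        r, c = np.argwhere(observed & (values != np.floor(values)))[0]
        raise ValueError(
            f"non-integer response code {values[r, c]!r} at row {r + 1}, "
            f"column {frame.columns[c]!r} in {path}")
    out_of_range = observed & ((values < 1) | (values > n_categories))
    if np.any(out_of_range):
        r, c = np.argwhere(out_of_range)[0]
        raise ValueError(
            f"response code {int(values[r, c])} outside 1..{n_categories} at "
            f"row {r + 1}, column {frame.columns[c]!r} in {path}")
    responses[observed] = values[observed].astype(np.int64) - 1
    return ResponseMatrix(responses, n_categories=n_categories,
                          item_labels=tuple(frame.columns))


def write_responses(data: ResponseMatrix, path) -> None:
    """Write a response table to CSV with 1..K codes and blank missing."""
    values = data.responses.astype("float64")
    values[data.responses == MISSING] = np.nan
    frame = pd.DataFrame(values + 1, columns=list(data.item_labels))
    frame.to_csv(path, index=False, float_format="%.0f")


@dataclass
class ValidationReport:
    """Per-item category coverage and fit-readiness flags."""

    category_counts: np.ndarray                 # (J, K)
    unendorsed: list[tuple[int, int]] = field(default_factory=list)
    unfittable_items: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.unendorsed and not self.unfittable_items


def validate_for_fitting(data: ResponseMatrix,
                         n_categories: int | None = None) -> ValidationReport:
    """Check that every item can support a fit.

    Flags every (item, category) pair that nobody endorsed and every item
    with fewer than two distinct observed categories (which cannot be fitted
    at all).
    """
    K = n_categories or data.n_categories
    counts = data.category_counts()[:, :K]
    report = ValidationReport(category_counts=counts)
    for j in range(data.n_items):
        observed = np.count_nonzero(counts[j])
        if observed < 2:
            report.unfittable_items.append(j)
        for k in range(K):
            if counts[j, k] == 0:
                report.unendorsed.append((j, k))
    return report


def write_fit_json(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2))


def write_generating_parameters(condition, items, path) -> None:
    """Sidecar YAML with the generating condition and item parameters,
    so parameter-recovery analyses can compare estimates to truth."""
    import yaml

    payload = {
        "condition": {
            "kind": condition.kind,
            "n_persons": condition.n_persons,
            "n_items": condition.n_items,
            "n_substantive": condition.n_substantive,
            "sigma_rs": condition.sigma_rs,
            "r_rs": condition.r_rs,
            "slope_corr": condition.slope_corr,
            "seed": condition.seed,
            "n_categories": condition.n_categories,
        },
        "items": [{"slopes": it.slopes.tolist(),
                   "intercepts": it.intercepts.tolist()} for it in items],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_generating_parameters(path):
    """Load a sidecar written by :func:`write_generating_parameters`."""
    import yaml

    from .datagen import GenCondition
    from .model import ItemParameters

    payload = yaml.safe_load(Path(path).read_text())
    condition = GenCondition(**payload["condition"])
    items = [ItemParameters(np.asarray(it["slopes"]),
                            np.asarray(it["intercepts"]))
             for it in payload["items"]]
    return condition, items
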