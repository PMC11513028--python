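"""Validation metrics for the surrogate models: R^2, SOSE, relative and
residual errors, and tidy parity/residual tables."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "r_squared",
    "sose",
    "relative_error",
    "residuals",
    "FitReport",
    "fit_report",
]


def _pair(measured, predicted) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if m.shape != p.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {p.shape}")
    return m, p


def r_squared(measured, predicted, variant: str = "standard") -> float:
    """Coefficient of determination.

    ``standard``: 1 - SOSE / sum((m - mean(m))^2).  ``as_printed`` keeps
    the source's literal denominator sum((p - mean(m))^2), a nonstandard
    form that can exceed 1 and is retained only for fidelity.  Returns NaN
    (undefined) for a constant measured vector.
    """
    m, p = _pair(measured, predicted)
    if m.size < 2:
        raise ValueError("need at least 2 points")
    ss_res = float(np.sum((p - m) ** 2))
    if variant == "standard":
        denom = float(np.sum((m - m.mean()) ** 2))
    elif variant == "as_printed":
        denom = float(np.sum((p - m.mean()) ** 2))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom == 0.0:
        return math.nan
    return 1.0 - ss_res / denom


def sose(measured, predicted) -> float:
    """Sum of squared errors, sum((m - p)^2), in squared target units."""
    m, p = _pair(measured, predicted)
    return float(np.sum((m - p) ** 2))


def relative_error(measured, predicted,
                   aggregate: str = "mean_abs") -> tuple[np.ndarray, float, int]:
    """Per-point relative errors (m - p)/m and an aggregate summary.

    Points with m = 0 are excluded from both vector and summary; their
    count is returned.  ``aggregate``: mean_abs (default), median_abs or
    max_abs over |RE|.  The summary is NaN when every point is excluded.
    """
    m, p = _pair(measured, predicted)
    keep = m != 0.0
    n_excluded = int((~keep).sum())
    re = (m[keep] - p[keep]) / m[keep]
    if re.size == 0:
        return re, math.nan, n_excluded
    if aggregate == "mean_abs":
        summary = float(np.mean(np.abs(re)))
    elif aggregate == "median_abs":
        summary = float(np.median(np.abs(re)))
    elif aggregate == "max_abs":
        summary = float(np.max(np.abs(re)))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return re, summary, n_excluded


def residuals(measured, predicted) -> np.ndarray:
    """Elementwise residual error m - p, order-preserving."""
    m, p = _pair(measured, predicted)
    return m - p


@dataclass(frozen=True)
class FitReport:
    """Train/test metrics for one target plus tidy parity/residual data."""

    target: str
    r2_train: float
    r2_test: float
    sose_train: float
    sose_test: float
    re_train: float
    re_test: float
    re_median_train: float
    re_median_test: float
    re_max_train: float
    re_max_test: float
    parity: pd.DataFrame  # columns: case, partition, measured, predicted, residual

    def summary_row(self) -> dict:
        return {
            "target": self.target,
            "r2_train": self.r2_train, "r2_test": self.r2_test,
            "sose_train": self.sose_train, "sose_test": self.sose_test,
            "re_train": self.re_train, "re_test": self.re_test,
        }


def fit_report(target: str, case_ids, measured, predicted,
               partition_labels) -> FitReport:
    """Assemble a :class:`FitReport` from aligned measured/predicted vectors.

    ``partition_labels`` marks each case ``train`` or ``test``.  Metrics are
    computed per partition; the parity table carries one row per case for
    downstream parity/residual plotting.
    """
    m, p = _pair(measured, predicted)
    labels = np.asarray(partition_labels)
    ids = np.asarray(case_ids)
    if not (m.size == labels.size == ids.size):
        raise ValueError("case_ids, values and partition_labels must align")
    parts: dict[str, dict[str, float]] = {}
    for part in ("train", "test"):
        sel = labels == part
        mm, pp = m[sel], p[sel]
        _, re_mean, _ = relative_error(mm, pp, "mean_abs")
        _, re_med, _ = relative_error(mm, pp, "median_abs")
        _, re_max, _ = relative_error(mm, pp, "max_abs")
        parts[part] = {
            "r2": r_squared(mm, pp) if mm.size >= 2 else math.nan,
            "sose": sose(mm, pp),
            "re": re_mean, "re_median": re_med, "re_max": re_max,
        }
    parity = pd.DataFrame({
        "case": ids, "partition": labels,
        "measured": m, "predicted": p, "residual": m - p,
    })
    return FitReport(
        target=target,
        r2_train=parts["train"]["r2"], r2_test=parts["test"]["r2"],
        sose_train=parts["train"]["sose"], sose_test=parts["test"]["sose"],
        re_train=parts["train"]["re"], re_test=parts["test"]["re"],
        re_median_train=parts["train"]["re_median"],
        re_median_test=parts["test"]["re_median"],
        re_max_train=parts["train"]["re_max"], re_max_test=parts["test"]["re_max"],
        parity=parity,
    )
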