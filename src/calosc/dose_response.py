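"""Four-parameter logistic (4PL) dose-response fitting and EC50 estimation.

Model (variable slope, four parameters), on the log10-dose axis:

    y(d) = bottom + (top - bottom) / (1 + 10**((log10(EC50) - log10(d)) * hill))

Fits are least-squares on per-dose means; EC50 is reported in molar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .metrics import _mean_sem

__all__ = [
    "FourPLFit",
    "four_pl",
    "fit_four_pl",
    "fit_log_auc_curve",
    "percent_responsive_by_dose",
]

HILL_BOUNDS = (0.1, 10.0)


def four_pl(
    log10_dose: np.ndarray | float,
    bottom: float,
    top: float,
    log10_ec50: float,
    hill: float,
):
    """Evaluate the 4PL curve at log10-molar dose(s)."""
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** ((log10_ec50 - np.asarray(log10_dose, dtype=float)) * hill)
    )


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with diagnostics."""

    bottom: float
    top: float
    log10_ec50: float
    hill: float
    residual_ss: float = float("nan")
    converged: bool = True

    @property
    def ec50(self) -> float:
        return float(10.0 ** self.log10_ec50)

    def predict(self, doses_molar: np.ndarray) -> np.ndarray:
        return four_pl(
            np.log10(np.asarray(doses_molar, dtype=float)),
            self.bottom,
            self.top,
            self.log10_ec50,
            self.hill,
        )


def fit_four_pl(doses: Sequence[float], responses: Sequence[float]) -> FourPLFit:
    """Least-squares 4PL fit of responses against log10 dose.

    ``doses`` are molar; zero doses are excluded from the log-axis fit (their
    responses only inform the bottom initialization). Requires >= 4 distinct
    positive doses. Non-convergence is flagged on the returned fit with a
    warning, never silently hidden.
    """
    doses = np.asarray(list(doses), dtype=float)
    responses = np.asarray(list(responses), dtype=float)
    if len(doses) != len(responses):
        raise ValueError("doses and responses must have equal length")
    zero_mask = doses == 0
    x = np.log10(doses[~zero_mask])
    y = responses[~zero_mask]
    if len(np.unique(x)) < 4:
        raise ValueError("4PL fitting requires at least 4 distinct positive doses")
    if np.ptp(responses) == 0:
        raise ValueError("all responses identical; 4PL fit is degenerate")

    b0 = float(np.min(responses))  # zero-dose responses may set the floor
    t0 = float(np.max(y))
    half = (b0 + t0) / 2.0
    ec50_init = float(x[np.argmin(np.abs(y - half))])
    p0 = [b0, t0, ec50_init, 1.0]
    span = float(np.ptp(y)) or 1.0
    lower = [b0 - 10 * span, b0 - 10 * span, x.min() - 3.0, HILL_BOUNDS[0]]
    upper = [t0 + 10 * span, t0 + 10 * span, x.max() + 3.0, HILL_BOUNDS[1]]
    converged = True
    try:
        popt, _ = curve_fit(
            four_pl, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as err:
        warnings.warn(f"4PL fit did not converge: {err}", stacklevel=2)
        popt = np.asarray(p0, dtype=float)
        converged = False
    rss = float(np.sum((four_pl(x, *popt) - y) ** 2))
    return FourPLFit(
        bottom=float(popt[0]),
        top=float(popt[1]),
        log10_ec50=float(popt[2]),
        hill=float(popt[3]),
        residual_ss=rss,
        converged=converged,
    )


def fit_log_auc_curve(table: pd.DataFrame) -> FourPLFit:
    """Fit the 4PL to per-dose mean log10 AUC.

    ``table`` is a long per-cell table with columns ``dose_molar`` and
    ``log10_auc`` (as produced by the synthetic generator or exported from
    per-cell metrics merged with a dose map).
    """
    means = table.groupby("dose_molar", sort=True)["log10_auc"].mean()
    return fit_four_pl(means.index.to_numpy(), means.to_numpy())


def percent_responsive_by_dose(
    table: pd.DataFrame,
    replicate_labels: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Percentage of responsive cells per dose, mean +- SEM.

    ``table`` needs columns ``dose_molar`` and boolean ``responsive`` (and
    optionally ``replicate``). With replicate structure the SEM is across
    replicate means, otherwise across cells.
    """
    df = table.copy()
    if replicate_labels is not None:
        df["replicate"] = list(replicate_labels)
    rows = []
    for dose, sub in df.groupby("dose_molar", sort=True):
        if len(sub) == 0:
            raise ValueError(f"no cells at dose {dose}")
        if "replicate" in df.columns:
            per_rep = sub.groupby("replicate")["responsive"].mean() * 100.0
            mean, sem = _mean_sem(per_rep.to_numpy())
        else:
            mean, sem = _mean_sem(100.0 * sub["responsive"].astype(float).to_numpy())
        rows.append({"dose_molar": dose, "pct_responsive": mean, "sem": sem})
    return pd.DataFrame(rows)
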