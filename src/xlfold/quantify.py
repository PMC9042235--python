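"""Immunoblot band quantification: cleavage ratios, cross-linked complex
fractions, and time-course trend fitting.

Band intensities are inputs (densitometry happens upstream); all ratios are
scale-invariant, so arbitrary intensity units are fine.

* ``cleavage_ratio`` — product / (substrate + product), the fraction of
  substrate converted by the protease.
* ``complex_fraction`` — cross-linked complex / (monomer + dimer + complex),
  the fraction of the enzyme captured in a disulfide-linked complex.
* ``fit_trend`` — ordinary least squares straight line over pooled replicate
  points of a time course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _check_band(name: str, value: float) -> float:
    value = float(value)
    if value < 0 or not np.isfinite(value):
        raise ValueError(f"band intensity {name!r} must be finite and >= 0")
    return value


def cleavage_ratio(substrate: float, product: float) -> float:
    """Fraction of substrate cleaved: product / (substrate + product)."""
    substrate = _check_band("substrate", substrate)
    product = _check_band("product", product)
    total = substrate + product
    if total == 0:
        raise ValueError("substrate and product intensities are both zero")
    return product / total


def complex_fraction(monomer: float, dimer: float, complex_: float) -> float:
    """Cross-linked complex abundance over monomer + dimer + complex."""
    monomer = _check_band("monomer", monomer)
    dimer = _check_band("dimer", dimer)
    complex_ = _check_band("complex", complex_)
    total = monomer + dimer + complex_
    if total == 0:
        raise ValueError("all band intensities are zero")
    return complex_ / total


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    residuals: np.ndarray
    stderr_slope: float
    stderr_intercept: float
    r_value: float


def fit_trend(times, ratios) -> TrendFit:
    """Best-fit straight trend line (OLS) through pooled replicate points.

    ``times`` and ``ratios`` are flat, parallel sequences; replicates simply
    appear as repeated time points and receive equal weight.
    """
    t = np.asarray(times, float).ravel()
    y = np.asarray(ratios, float).ravel()
    if t.shape != y.shape:
        raise ValueError("times and ratios must have the same length")
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct time points")
    fit = stats.linregress(t, y)
    residuals = y - (fit.slope * t + fit.intercept)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residuals=residuals,
        stderr_slope=float(fit.stderr),
        stderr_intercept=float(fit.intercept_stderr),
        r_value=float(fit.rvalue),
    )


def two_tailed_ttest(a, b) -> tuple[float, float]:
    """Two-tailed two-sample Student's t-test (equal variances); returns
    (t statistic, p value)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def quantify_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``ratio`` column to an intensity table.

    Cleavage tables carry ``substrate``/``product`` columns; cross-linking
    tables carry ``monomer``/``dimer``/``complex``.
    """
    out = df.copy()
    if {"substrate", "product"} <= set(df.columns):
        out["ratio"] = [
            cleavage_ratio(s, p) for s, p in zip(df["substrate"], df["product"])
        ]
    elif {"monomer", "dimer", "complex"} <= set(df.columns):
        out["ratio"] = [
            complex_fraction(m, d, c)
            for m, d, c in zip(df["monomer"], df["dimer"], df["complex"])
        ]
    else:
        raise ValueError(
            "table needs either substrate/product or monomer/dimer/complex columns"
        )
    return out
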