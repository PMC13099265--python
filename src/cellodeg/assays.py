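"""Isolate cellulolytic-assay quantification and oxygen-gradient statistics.

Covers the DNS reducing-sugar assay (glucose standard curve at A540, glucose
released from CMC-Na hydrolysis), the gravimetric residual-CMC assay
(m = m1 - m0, corrected for recovery), TPM normalization for paired
expression contrasts, and paired Wilcoxon signed-rank comparisons across
oxygen levels with BH adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, paired_signed_rank

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "GlucoseResult",
    "glucose_released",
    "residual_cmc",
    "tpm",
    "oxygen_gradient_report",
]

DEFAULT_O2_LEVELS = (0.0, 2.0, 4.0, 6.0, 21.0)  # % O2


@dataclass
class StandardCurve:
    """OLS fit of A540 on glucose concentration (mg/ml)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fit_standard_curve(concentrations: Sequence[float],
                       a540: Sequence[float]) -> StandardCurve:
    """Ordinary least squares of absorbance on concentration."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(a540, dtype=float)
    if c.size < 3:
        raise ValueError("standard curve requires >= 3 points")
    if np.ptp(c) == 0:
        raise ValueError("standard concentrations have zero variance")
    if np.ptp(a) == 0:
        raise ValueError("constant absorbance: no usable standard curve")
    res = sps.linregress(c, a)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2), n_points=c.size)


@dataclass
class GlucoseResult:
    mg_per_ml: float
    below_blank: bool


def glucose_released(a540_sample: float, a540_blank: float,
                     curve: StandardCurve,
                     dilution_factor: float = 1.0) -> GlucoseResult:
    """Glucose concentration from blank-corrected absorbance.

    concentration = (dA540 - intercept) / slope * dilution_factor, floored
    at 0 with a below-blank flag.
    """
    if curve.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    delta = a540_sample - a540_blank
    conc = (delta - curve.intercept) / curve.slope * dilution_factor
    if conc < 0:
        return GlucoseResult(0.0, True)
    return GlucoseResult(float(conc), False)


def residual_cmc(m1: float, m0: float, recovery: float = 1.0
                 ) -> tuple[float, bool]:
    """Recovery-corrected residual CMC mass: (m1 - m0) / recovery.

    Returns (mass, negative_flag); negative corrected masses are flagged
    rather than floored, since they signal a blank exceeding the sample.
    """
    if not 0 < recovery <= 1:
        raise ValueError("recovery must be in (0, 1]")
    m = (m1 - m0) / recovery
    return float(m), m < 0


def tpm(counts: Sequence[float], effective_lengths: Sequence[float]
        ) -> np.ndarray:
    """Transcripts per million: (count/length) / sum(count/length) * 1e6."""
    c = np.asarray(counts, dtype=float)
    ln = np.asarray(effective_lengths, dtype=float)
    if (ln <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = c / ln
    total = rate.sum()
    if total <= 0:
        raise ValueError("zero total expression; TPM undefined")
    return rate / total * 1e6


def oxygen_gradient_report(assay_table: pd.DataFrame,
                           value_col: str = "value",
                           strain_col: str = "strain_id",
                           o2_col: str = "o2_level") -> pd.DataFrame:
    """All pairwise oxygen-level comparisons with paired signed-rank tests.

    Measurements are paired by strain within each pair of O2 levels (strains
    missing either member are dropped from that comparison with a warning).
    BH adjustment is applied across comparisons; unadjusted p-values are
    kept alongside for comparability with unadjusted reporting conventions.
    """
    levels = sorted(assay_table[o2_col].unique())
    wide = assay_table.pivot_table(index=strain_col, columns=o2_col,
                                   values=value_col, aggfunc="mean")
    rows = []
    for lo, hi in combinations(levels, 2):
        pair = wide[[lo, hi]].dropna()
        dropped = len(wide) - len(pair)
        if dropped:
            warnings.warn(
                f"{dropped} strain(s) missing a member of the {lo}% vs {hi}% "
                "pair; dropped from that comparison", UserWarning, stacklevel=2)
        if len(pair) == 0:
            continue
        res = paired_signed_rank(pair[lo].to_numpy(), pair[hi].to_numpy())
        diff_median = float(np.median(pair[hi] - pair[lo]))
        rows.append({
            "o2_low": lo, "o2_high": hi, "n_pairs": len(pair),
            "median_low": float(pair[lo].median()),
            "median_high": float(pair[hi].median()),
            "median_diff": diff_median,
            "direction": int(np.sign(diff_median)),
            "statistic": res.statistic, "p": res.p_value,
            "method": res.method,
        })
    rep = pd.DataFrame(rows)
    if not rep.empty:
        rep["p_adj"] = bh_adjust(rep["p"].to_numpy())
    return rep
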