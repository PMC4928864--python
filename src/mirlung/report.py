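"""Report formatting: table rounding and percentage arithmetic.

Rounding conventions follow the study's table style: slopes and confidence
bounds to 2 decimals, p-values to 4 decimals, percentages to 1 decimal, and
FDR estimates to the whole percent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage of a count ratio, rounded for display (e.g. 9/22 -> 40.9)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def format_percent(numerator: float, denominator: float, decimals: int = 1) -> str:
    value = percent(numerator, denominator, decimals)
    return f"{value:.{decimals}f}%"


def format_fdr(fdr_fraction: float) -> str:
    """Whole-percent FDR display: 0.1818... -> '18%', 0.2545... -> '25%'."""
    if not np.isfinite(fdr_fraction):
        return "NA"
    return f"{round(100.0 * fdr_fraction):d}%"


def format_beta_ci(beta: float, ci_low: float, ci_high: float) -> str:
    """Slope with its CI in the tables' '1.23 (0.56, 1.91)' style."""
    return f"{beta:.2f} ({ci_low:.2f}, {ci_high:.2f})"


def round_association_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Apply table rounding to an association result frame."""
    out = frame.copy()
    for col in ("beta", "ci_low", "ci_high"):
        if col in out:
            out[col] = out[col].round(2)
    for col in ("p_value", "p_adjusted"):
        if col in out:
            out[col] = out[col].round(4)
    return out
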