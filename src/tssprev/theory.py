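"""Expected TSS for continuous predictions and its theoretical optimum.

With binarization at cutoff xc (presence called when the score strictly
exceeds xc), the expected sensitivity is 1 - F1(xc) and the expected
specificity F0(xc), so

    E[TSS](xc) = F0(xc) - F1(xc),

maximal where the conditional densities cross, f0(xc) = f1(xc).  For the
mirror-symmetric scenarios (f0(x) = f1(1-x)) the crossing is at xc = 0.5;
the root is nonetheless located numerically so the machinery generalizes.

When the cutoff is instead chosen from the data (the "maximum TSS" rule),
the mean of the realized maxima over-estimates this theoretical value at
small samples; :func:`bias_table` quantifies that gap for a simulation
result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .simulator import ModelScenario, cdf, density, get_scenario

__all__ = ["TheoreticalOptimum", "expected_tss", "theoretical_optimum", "bias_table"]

#: cutoff root-finding tolerance
_XTOL = 1e-9


@dataclass(frozen=True)
class TheoreticalOptimum:
    """Cutoff where f0 = f1 and the expected TSS attained there."""

    scenario: ModelScenario
    cutoff_star: float
    tss_star: float


def expected_tss(scenario, cutoff) -> float:
    """E[TSS] at a fixed cutoff: F0(cutoff) - F1(cutoff)."""
    sc = get_scenario(scenario)
    return cdf(sc, cutoff, "absence") - cdf(sc, cutoff, "presence")


def theoretical_optimum(scenario) -> TheoreticalOptimum:
    """Locate the density crossing f0 = f1 and evaluate E[TSS] there.

    Uses bracketed root-finding on f0 - f1 over (0, 1); a symmetric
    scenario yields cutoff_star = 0.5 to within the 1e-9 tolerance.
    """
    sc = get_scenario(scenario)

    def gap(x: float) -> float:
        return float(density(sc, x, "absence") - density(sc, x, "presence"))

    lo, hi = 1e-6, 1.0 - 1e-6
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            f"densities of scenario {sc.name!r} do not cross in (0, 1)"
        )
    x_star = brentq(gap, lo, hi, xtol=_XTOL)
    return TheoreticalOptimum(
        scenario=sc, cutoff_star=float(x_star),
        tss_star=float(expected_tss(sc, x_star)),
    )


def bias_table(result: pd.DataFrame) -> pd.DataFrame:
    """Join a simulation result to theory: bias = mean max TSS - TSS*.

    ``result`` is the long-format table produced by the experiment runner
    (columns ``scenario``, ``n_total``, ``prevalence``, ``mean_max_tss``,
    ``sd_max_tss``, ``n_reps``).  Returns the same rows with ``tss_star``,
    ``bias`` and the Monte Carlo standard error of the mean appended, so
    downstream checks can express tolerances in SE units.
    """
    required = {"scenario", "n_total", "prevalence", "mean_max_tss"}
    missing = required - set(result.columns)
    if missing:
        raise ValueError(f"result table lacks columns {sorted(missing)}")
    stars = {}
    for name in result["scenario"].unique():
        stars[name] = theoretical_optimum(name).tss_star  # raises on unknown
    out = result.copy()
    out["tss_star"] = out["scenario"].map(stars)
    out["bias"] = out["mean_max_tss"] - out["tss_star"]
    if {"sd_max_tss", "n_reps"} <= set(out.columns):
        out["se_mean"] = out["sd_max_tss"] / np.sqrt(out["n_reps"])
    return out
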