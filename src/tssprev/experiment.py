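"""Maximum-TSS over a cutoff grid and the factorial Monte Carlo study.

The study crosses four discrimination-quality scenarios with total sample
sizes {100, 1000, 10000} and prevalences 0.05, 0.10, ..., 0.95.  For each
cell, many labeled prediction sets are drawn, TSS is evaluated at 19 evenly
spaced cutoffs (0.05-0.95), and the per-replicate maximum is recorded; the
cell is summarized by the mean and standard deviation of those maxima.  At
small N the data-driven choice of cutoff inflates the mean maximum above
the theoretical expected TSS, and the inflation is U-shaped in prevalence.

Also included is the fixed-rate construction that holds TPR and TNR
constant while varying prevalence: with real-valued cells TSS is exactly
TPR + TNR - 1 at every prevalence, and with integer cells it deviates only
by rounding — the design whose apparent prevalence-independence motivated
this study.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import ConfusionMatrix, UndefinedRateError, tss as _tss
from .simulator import (
    SCENARIO_NAMES,
    LabeledPredictions,
    allocate_presences,
    get_scenario,
    sample_labeled_predictions,
)

__all__ = [
    "CutoffGrid",
    "SimulationConfig",
    "tss_curve",
    "max_tss",
    "run_experiment",
    "fixed_rate_confusion",
    "allouche_replication",
    "DEFAULT_SAMPLE_SIZES",
    "DEFAULT_PREVALENCES",
    "DEFAULT_N_REPS",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZES: Tuple[int, ...] = (100, 1000, 10000)
#: 0.05 .. 0.95 in steps of 0.05 (19 values)
DEFAULT_PREVALENCES: Tuple[float, ...] = tuple(
    np.round(np.arange(1, 20) * 0.05, 10)
)
DEFAULT_N_REPS = 1000


@dataclass(frozen=True)
class CutoffGrid:
    """Ordered probability cutoffs at which TSS is evaluated."""

    values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1, 20) * 0.05, 10)
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("cutoff grid must be a non-empty vector")
        if np.any((v <= 0) | (v >= 1)):
            raise ValueError("cutoffs must lie strictly inside (0, 1)")
        if np.any(np.diff(v) <= 0):
            raise ValueError("cutoffs must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SimulationConfig:
    """Factorial design of the Monte Carlo study.

    Defaults reproduce the full study: all four scenarios, sample sizes
    100/1000/10000, the 19-point prevalence grid, 1000 replicates per cell.
    """

    scenarios: Tuple[str, ...] = SCENARIO_NAMES
    sample_sizes: Tuple[int, ...] = DEFAULT_SAMPLE_SIZES
    prevalence_grid: Tuple[float, ...] = DEFAULT_PREVALENCES
    n_reps: int = DEFAULT_N_REPS
    cutoff_grid: CutoffGrid = field(default_factory=CutoffGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for s in self.scenarios:
            get_scenario(s)  # raises on unknown names
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))
        object.__setattr__(self, "prevalence_grid", tuple(float(p) for p in self.prevalence_grid))

    @property
    def n_cells(self) -> int:
        return len(self.scenarios) * len(self.sample_sizes) * len(self.prevalence_grid)


def tss_curve(data: LabeledPredictions, grid: Optional[CutoffGrid] = None) -> np.ndarray:
    """TSS at every cutoff of the grid; returns an (k, 2) array of
    (cutoff, tss) rows.

    Rates condition on the observed labels, so a cutoff where one
    *predicted* class vanishes still yields a defined TSS; only a
    single-class label vector is an error.
    """
    if grid is None:
        grid = CutoffGrid()
    pres = data.probs[data.labels == 1]
    absn = data.probs[data.labels == 0]
    if pres.size == 0 or absn.size == 0:
        raise UndefinedRateError("both classes must be present in labels")
    cuts = grid.values
    # strict ">" binarization at all cutoffs at once
    tpr = np.mean(pres[:, None] > cuts[None, :], axis=0)
    tnr = np.mean(absn[:, None] <= cuts[None, :], axis=0)
    return np.column_stack([cuts, tpr + tnr - 1.0])


def max_tss(data: LabeledPredictions, grid: Optional[CutoffGrid] = None) -> Tuple[float, float]:
    """Maximum TSS over the cutoff grid and its cutoff.

    Ties are broken toward the smallest cutoff (a deterministic rule; only
    the maximum value itself matters for the study).
    """
    curve = tss_curve(data, grid)
    idx = int(np.argmax(curve[:, 1]))  # argmax takes the first maximum
    return float(curve[idx, 1]), float(curve[idx, 0])


def _cell_seed_sequence(seed: int, scenario_name: str, n_total: int, prevalence: float) -> np.random.SeedSequence:
    """Per-cell seed stream, stable under subsetting of the factorial."""
    scen_idx = SCENARIO_NAMES.index(scenario_name) if scenario_name in SCENARIO_NAMES else 99
    key = (np.uint32(scen_idx), np.uint32(n_total), np.uint32(round(prevalence * 1000)))
    return np.random.SeedSequence(entropy=seed, spawn_key=key)


def run_experiment(config: SimulationConfig) -> pd.DataFrame:
    """Run the full factorial Monte Carlo study.

    For every (scenario, N, prevalence) cell, ``n_reps`` independent
    datasets are drawn and the maximum TSS over the cutoff grid is computed
    for each; the cell is summarized by the mean and sd of the maxima and
    the mean maximizing cutoff.  Deterministic for a given ``config.seed``;
    each cell's random substream depends only on the seed and the cell
    identity, so running a subset of cells reproduces the full run's rows.

    Returns a long-format DataFrame with one row per cell and columns
    ``scenario, n_total, prevalence, mean_max_tss, sd_max_tss,
    mean_argmax_cutoff, n_reps, seed``.
    """
    rows = []
    t_start = time.perf_counter()
    cell_no = 0
    for scen_name in config.scenarios:
        scenario = get_scenario(scen_name)
        for n_total in config.sample_sizes:
            for prevalence in config.prevalence_grid:
                cell_no += 1
                cell_ss = _cell_seed_sequence(config.seed, scenario.name, n_total, prevalence)
                rep_streams = cell_ss.spawn(config.n_reps)
                maxima = np.empty(config.n_reps)
                argmax = np.empty(config.n_reps)
                for i, ss in enumerate(rep_streams):
                    try:
                        data = sample_labeled_predictions(
                            scenario, n_total, prevalence,
                            np.random.Generator(np.random.PCG64(ss)),
                        )
                        maxima[i], argmax[i] = max_tss(data, config.cutoff_grid)
                    except (ValueError, UndefinedRateError) as exc:
                        raise RuntimeError(
                            f"cell (scenario={scenario.name}, N={n_total}, "
                            f"prevalence={prevalence}), replicate {i}: {exc}"
                        ) from exc
                rows.append({
                    "scenario": scenario.name,
                    "n_total": n_total,
                    "prevalence": prevalence,
                    "mean_max_tss": float(maxima.mean()),
                    "sd_max_tss": float(maxima.std(ddof=1)) if config.n_reps > 1 else 0.0,
                    "mean_argmax_cutoff": float(argmax.mean()),
                    "n_reps": config.n_reps,
                    "seed": config.seed,
                })
                logger.info(
                    "cell %d/%d %s N=%d pi=%.2f mean_max_tss=%.4f (%.1fs elapsed)",
                    cell_no, config.n_cells, scenario.name, n_total, prevalence,
                    rows[-1]["mean_max_tss"], time.perf_counter() - t_start,
                )
    return pd.DataFrame(rows)


def fixed_rate_confusion(
    tpr: float,
    tnr: float,
    prevalence: float,
    n_total: int,
    mode: str = "real",
) -> ConfusionMatrix:
    """Confusion matrix built by holding TPR and TNR constant.

    ``mode="real"`` fills cells exactly (tp = tpr*P, tn = tnr*(N-P)), so
    TSS is exactly tpr + tnr - 1 regardless of prevalence.
    ``mode="integer"`` rounds tp and tn to whole counts (half-to-even) and
    fills FN/FP as complements, reproducing the small jitter that integer
    cells impose on the realized rates.
    """
    if not 0 <= tpr <= 1 or not 0 <= tnr <= 1:
        raise ValueError("tpr and tnr must lie in [0, 1]")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    p = round(prevalence * n_total)
    if p < 1 or p > n_total - 1:
        raise ValueError(
            f"degenerate allocation: P={p} of N={n_total} leaves one class empty"
        )
    n_neg = n_total - p
    if mode == "real":
        return ConfusionMatrix(
            tp=tpr * p, fn=(1 - tpr) * p,
            tn=tnr * n_neg, fp=(1 - tnr) * n_neg,
        )
    if mode == "integer":
        tp = round(tpr * p)
        tn = round(tnr * n_neg)
        return ConfusionMatrix(
            tp=tp, fn=p - tp, tn=tn, fp=n_neg - tn, integer_mode=True,
        )
    raise ValueError(f"mode must be 'real' or 'integer', got {mode!r}")


def allouche_replication(
    tpr: float,
    tnr: float,
    prevalence_grid: Sequence[float] = DEFAULT_PREVALENCES,
    n_total: int = 100,
) -> pd.DataFrame:
    """Fixed-rate TSS across a prevalence grid, real and integer cells.

    With real cells the TSS column is constant at tpr + tnr - 1 — holding
    the rates fixed makes prevalence-independence true by construction,
    which is why this design cannot detect prevalence effects.  The integer
    column shows the rounding jitter, bounded by 0.5*(1/P + 1/(N-P)).
    """
    rows = []
    for pi in prevalence_grid:
        real = _tss(fixed_rate_confusion(tpr, tnr, pi, n_total, "real")).tss
        integer = _tss(fixed_rate_confusion(tpr, tnr, pi, n_total, "integer")).tss
        rows.append({
            "prevalence": float(pi),
            "tss_real": real,
            "tss_integer": integer,
        })
    return pd.DataFrame(rows)
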