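"""Confusion-matrix construction and threshold-based discrimination metrics.

The central quantity is the true skill statistic (TSS, also known as the
Youden index or Peirce/Kuipers skill score),

    TSS = TPR + TNR - 1,

with sensitivity TPR = TP/(TP+FN) and specificity TNR = TN/(TN+FP) taken
from a two-by-two confusion matrix of presence/absence observations against
binary predictions.  Cohen's kappa is provided as a chance-corrected
comparison baseline.

Confusion matrices come in two modes: *integer* matrices realized from
actual label vectors, and *real-valued* expected matrices whose cells are
algebraic expressions of error rates and prevalence.  Both are first-class;
a flag records which kind a given matrix is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricResult",
    "UndefinedRateError",
    "DegenerateTableError",
    "confusion_from_binary",
    "binarize",
    "tss",
    "kappa",
    "read_predictions",
]


class UndefinedRateError(ValueError):
    """A rate (TPR or TNR) is undefined because one class is absent."""


class DegenerateTableError(ValueError):
    """The table is degenerate for the requested statistic (e.g. kappa
    with chance agreement equal to 1)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Two-by-two confusion matrix of observations against predictions.

    Parameters
    ----------
    tp, fp, fn, tn
        True positives, false positives, false negatives, true negatives.
        Non-negative; real values are allowed for expected-value tables.
    integer_mode
        True when the cells are realized counts (must then be integral),
        False for algebraic expected-value tables.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    integer_mode: bool = False

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        for name, c in zip(("tp", "fp", "fn", "tn"), cells):
            if not np.isfinite(c) or c < 0:
                raise ValueError(f"cell {name}={c!r} must be finite and >= 0")
        if self.integer_mode and any(float(c) != int(c) for c in cells):
            raise ValueError("integer-mode matrix has non-integer cells")
        if self.n == 0:
            raise ValueError("empty confusion matrix (N = 0)")

    # -- margins -----------------------------------------------------------
    @property
    def n(self) -> float:
        """Total number of observations N."""
        return self.tp + self.fp + self.fn + self.tn

    @property
    def p(self) -> float:
        """Number of positive observations P = TP + FN."""
        return self.tp + self.fn

    @property
    def s(self) -> float:
        """Number of positive predictions S = TP + FP."""
        return self.tp + self.fp

    @property
    def prevalence(self) -> float:
        """Observed prevalence pi = P/N."""
        return self.p / self.n

    def swapped(self) -> "ConfusionMatrix":
        """Matrix with the class labels exchanged (tp<->tn, fp<->fn)."""
        return ConfusionMatrix(
            tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp,
            integer_mode=self.integer_mode,
        )


@dataclass(frozen=True)
class MetricResult:
    """Sensitivity, specificity and TSS for one confusion matrix."""

    tpr: float
    tnr: float
    tss: float
    kappa: Optional[float] = None


def confusion_from_binary(obs, pred) -> ConfusionMatrix:
    """Build an integer-mode confusion matrix from two binary label vectors.

    Parameters
    ----------
    obs, pred
        Equal-length sequences with entries in {0, 1}; ``obs`` are the
        observations (1 = presence), ``pred`` the binary predictions.
    """
    obs = np.asarray(obs)
    pred = np.asarray(pred)
    if obs.ndim != 1 or pred.ndim != 1:
        raise ValueError("obs and pred must be one-dimensional")
    if obs.size == 0:
        raise ValueError("empty label vectors")
    if obs.shape != pred.shape:
        raise ValueError(
            f"length mismatch: obs has {obs.size}, pred has {pred.size}"
        )
    for name, v in (("obs", obs), ("pred", pred)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} contains non-binary entries")
    obs = obs.astype(bool)
    pred = pred.astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(obs & pred)),
        fp=int(np.sum(~obs & pred)),
        fn=int(np.sum(obs & ~pred)),
        tn=int(np.sum(~obs & ~pred)),
        integer_mode=True,
    )


def binarize(probs, cutoff: float) -> np.ndarray:
    """Convert predicted probabilities to binary presence calls.

    Presence is called where the probability *strictly exceeds* the cutoff
    (P(x > xc)); ties at the cutoff are absences.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 <= cutoff <= 1:
        raise ValueError(f"cutoff {cutoff!r} outside [0, 1]")
    return (probs > cutoff).astype(np.int8)


def tss(cm: ConfusionMatrix) -> MetricResult:
    """Sensitivity, specificity and TSS = TPR + TNR - 1.

    Raises
    ------
    UndefinedRateError
        If either class is absent from the observations (P = 0 or
        N - P = 0), in which case one of the rates is 0/0.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    if pos == 0:
        raise UndefinedRateError("no positive observations: TPR undefined")
    if neg == 0:
        raise UndefinedRateError("no negative observations: TNR undefined")
    tpr = cm.tp / pos
    tnr = cm.tn / neg
    return MetricResult(tpr=tpr, tnr=tnr, tss=tpr + tnr - 1.0)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's chance-corrected agreement, (p_o - p_e) / (1 - p_e)."""
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    n = cm.n
    p_obs = (cm.tp + cm.tn) / n
    p_exp = (pos * cm.s + neg * (n - cm.s)) / (n * n)
    if p_exp == 1.0:
        raise DegenerateTableError("chance agreement equals 1")
    if pos == 0 or neg == 0:
        raise UndefinedRateError("kappa needs both classes observed")
    return (p_obs - p_exp) / (1.0 - p_exp)


def read_predictions(path: Union[str, Path], delimiter: str = ","):
    """Read user-supplied (label, probability) pairs from delimited text.

    Lines starting with ``#`` are comments; an optional header row with a
    non-numeric first field is skipped.  Returns ``(labels, probs)`` as
    numpy arrays.
    """
    labels: list[int] = []
    probs: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 2:
                raise ValueError(f"expected two columns, got: {line!r}")
            try:
                lab = float(parts[0])
            except ValueError:
                continue  # header row
            if lab not in (0.0, 1.0):
                raise ValueError(f"non-binary label {parts[0]!r}")
            labels.append(int(lab))
            probs.append(float(parts[1]))
    if not labels:
        raise ValueError(f"no data rows found in {path}")
    probs_arr = np.asarray(probs, dtype=float)
    if probs_arr.min() < 0 or probs_arr.max() > 1:
        raise ValueError("probabilities outside [0, 1]")
    return np.asarray(labels, dtype=np.int8), probs_arr
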