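"""Closed-form TSS under four binary observation-error scenarios.

Each scenario assumes a fixed total sample size N, prevalence pi = P/N and a
constant error rate, and describes a mechanism by which the observed
presence/absence pattern deviates from the (dichotomous) habitat-suitability
pattern:

``two_error``
    The model misclassifies: a false-negative rate e1 on suitable sites and
    a false-positive rate e2 on unsuitable sites.  TSS = 1 - e1 - e2,
    independent of prevalence.
``missed_presence``
    The model is perfect but a fraction e of true presences goes undetected,
    so S = P/(1-e) sites are predicted present while only P are observed.
    TSS = (1 - e - pi) / ((1 - pi)(1 - e)) — prevalence dependent.
``fallacious_absence``
    Suitable sites left unoccupied (metapopulation vacancies) are recorded
    as absences at rate e of the predicted-suitable sites; algebraically the
    same matrix as ``missed_presence``.
``fallacious_presence_prop_presences``
    A proportion e of presences is fallacious (sink populations); reduces to
    ``two_error`` with e2 = 0, hence TSS = 1 - e, prevalence independent.
``fallacious_presence_prop_unsuitable``
    Fallacious presences proportional (rate e) to the number of unsuitable
    sites.  The expected table's self-consistency condition
    TP = P - e(N - S) = S solves to S = (P - eN)/(1 - e); the widely
    circulated shortcut divides by (1 + e) instead and does not balance the
    table's margins.  Both variants are exposed (see
    :func:`tss_fallacious_presence`); the table-consistent one defines the
    expected matrix built by :func:`scenario_confusion`.

Every closed form is paired with :func:`scenario_confusion`, which fills the
expected (real-valued) confusion matrix cell by cell, so the formulas can be
cross-checked against matrix arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .metrics import ConfusionMatrix, tss as _tss

__all__ = [
    "SCENARIO_KINDS",
    "ErrorScenario",
    "scenario_confusion",
    "tss_two_error",
    "tss_missed_presence",
    "tss_fallacious_absence",
    "tss_fallacious_presence",
    "scenario_tss",
    "matrix_tss",
]

SCENARIO_KINDS = (
    "two_error",
    "missed_presence",
    "fallacious_absence",
    "fallacious_presence_prop_presences",
    "fallacious_presence_prop_unsuitable",
)


def _check_rate(name: str, value: float) -> None:
    if not 0 <= value < 1:
        raise ValueError(f"{name}={value!r} outside [0, 1)")


@dataclass(frozen=True)
class ErrorScenario:
    """An observation-error mechanism with its rate(s) and prevalence.

    ``two_error`` uses ``e1`` (false-negative) and ``e2`` (false-positive);
    the single-rate kinds use ``e``.  Prevalence must be strictly inside
    (0, 1); all rates in [0, 1).
    """

    kind: str
    prevalence: float
    e: Optional[float] = None
    e1: Optional[float] = None
    e2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(
                f"unknown kind {self.kind!r}; expected one of {SCENARIO_KINDS}"
            )
        if not 0 < self.prevalence < 1:
            raise ValueError(
                f"prevalence {self.prevalence!r} must be strictly in (0, 1)"
            )
        if self.kind == "two_error":
            if self.e1 is None or self.e2 is None:
                raise ValueError("two_error requires e1 and e2")
            _check_rate("e1", self.e1)
            _check_rate("e2", self.e2)
        else:
            if self.e is None:
                raise ValueError(f"{self.kind} requires a single rate e")
            _check_rate("e", self.e)
            if self.kind in ("missed_presence", "fallacious_absence"):
                if self.prevalence > 1 - self.e:
                    raise ValueError(
                        "prevalence > 1 - e: predicted presences S = "
                        "P/(1-e) would exceed N"
                    )
            if self.kind == "fallacious_presence_prop_unsuitable":
                if self.prevalence <= self.e:
                    raise ValueError(
                        "requires prevalence > e, else TP would be negative"
                    )


def scenario_confusion(scenario: ErrorScenario, n_total: float) -> ConfusionMatrix:
    """Expected (real-valued) confusion matrix for an error scenario.

    Cells are algebraic expectations at total sample size ``n_total``; no
    rounding is applied.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    n = float(n_total)
    pi = scenario.prevalence
    p = pi * n
    kind = scenario.kind

    if kind == "two_error":
        e1, e2 = scenario.e1, scenario.e2
        return ConfusionMatrix(
            tp=(1 - e1) * p, fn=e1 * p,
            fp=e2 * (n - p), tn=(1 - e2) * (n - p),
        )
    if kind == "fallacious_presence_prop_presences":
        # reduces to the two-error table with e2 = 0
        e = scenario.e
        return ConfusionMatrix(tp=(1 - e) * p, fn=e * p, fp=0.0, tn=n - p)
    if kind in ("missed_presence", "fallacious_absence"):
        e = scenario.e
        s = p / (1 - e)
        return ConfusionMatrix(tp=p, fn=0.0, fp=e * s, tn=n - s)
    # fallacious_presence_prop_unsuitable: solve TP = P - e(N-S) = S for S
    e = scenario.e
    s = (p - e * n) / (1 - e)
    return ConfusionMatrix(tp=s, fn=e * (n - s), fp=0.0, tn=n - p)


def tss_two_error(e1: float, e2: float) -> float:
    """TSS when the only errors are model misclassification at fixed rates.

    Equals ``1 - e1 - e2`` and is independent of prevalence: the rates
    enter TPR and TNR directly and the prevalence cancels.
    """
    _check_rate("e1", e1)
    _check_rate("e2", e2)
    return 1.0 - e1 - e2


def tss_missed_presence(e: float, pi: float) -> float:
    """TSS when a fraction ``e`` of presences is missed by observation.

    (1 - e - pi) / ((1 - pi)(1 - e)); depends on prevalence even though the
    error rate is constant.
    """
    _check_rate("e", e)
    if not 0 < pi < 1:
        raise ValueError(f"prevalence {pi!r} must be in (0, 1)")
    if pi > 1 - e:
        raise ValueError("prevalence > 1 - e: S would exceed N")
    return (1.0 - e - pi) / ((1.0 - pi) * (1.0 - e))


def tss_fallacious_absence(e: float, pi: float) -> float:
    """TSS under fallacious absences (suitable but unoccupied sites).

    Mathematically identical to :func:`tss_missed_presence`.
    """
    return tss_missed_presence(e, pi)


def tss_fallacious_presence(e: float, pi: float, variant: str = "table_consistent") -> float:
    """TSS when fallacious presences are proportional to unsuitable sites.

    ``variant="table_consistent"`` solves the expected table's own identity
    TP = P - e(N - S) = S, giving S = (P - eN)/(1 - e) and
    TSS = (pi - e)/(pi (1 - e)).  ``variant="printed"`` returns the widely
    quoted shortcut (pi - e)/(pi (1 + e)), whose implied S = (P - eN)/(1 + e)
    does not balance the table margins.  The two disagree whenever e > 0.
    """
    _check_rate("e", e)
    if not 0 < pi < 1:
        raise ValueError(f"prevalence {pi!r} must be in (0, 1)")
    if pi <= e:
        raise ValueError("requires pi > e, else TP would be negative")
    if variant == "table_consistent":
        return (pi - e) / (pi * (1.0 - e))
    if variant == "printed":
        return (pi - e) / (pi * (1.0 + e))
    raise ValueError(
        f"variant must be 'table_consistent' or 'printed', got {variant!r}"
    )


def scenario_tss(scenario: ErrorScenario) -> float:
    """Closed-form TSS for an :class:`ErrorScenario` (table-consistent)."""
    if scenario.kind == "two_error":
        return tss_two_error(scenario.e1, scenario.e2)
    if scenario.kind == "missed_presence":
        return tss_missed_presence(scenario.e, scenario.prevalence)
    if scenario.kind == "fallacious_absence":
        return tss_fallacious_absence(scenario.e, scenario.prevalence)
    if scenario.kind == "fallacious_presence_prop_presences":
        return tss_two_error(scenario.e, 0.0)
    return tss_fallacious_presence(scenario.e, scenario.prevalence)


def matrix_tss(scenario: ErrorScenario, n_total: float = 1000.0) -> float:
    """TSS computed through the expected confusion matrix (oracle route)."""
    return _tss(scenario_confusion(scenario, n_total)).tss
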