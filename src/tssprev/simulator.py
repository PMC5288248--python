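"""Synthetic labeled-prediction generator with beta-distributed scores.

The generative scheme: N observation sites receive binary presence/absence
labels at a target prevalence pi (P = round(pi*N) presences), and each site
gets a continuous predicted suitability in [0, 1].  Predictions for presence
sites are drawn from a beta density f1 and for absence sites from f0.  Four
discrimination-quality scenarios are defined by the shape of f1 (its
un-normalized form names the scenario); f0 is the mirror image f1(1-x):

=============  ==============  ==============  =======================
scenario       f1 ~ Beta(a,b)  f0 ~ Beta(a,b)  discrimination quality
=============  ==============  ==============  =======================
quadratic      (3, 1)          (1, 3)          good
linear         (2, 1)          (1, 2)          medium
square_root    (1.5, 1)        (1, 1.5)        weak
p16            (17/16, 1)      (1, 17/16)      extremely weak
=============  ==============  ==============  =======================

Because every scenario has one beta parameter equal to 1, the CDFs and
quantile functions have closed forms (F1(x) = x^a, F0(x) = 1-(1-x)^b), and
sampling uses inverse-CDF transforms of uniforms.  This makes draws exactly
reproducible from a seed and independent of any library's beta-sampler
internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import special

__all__ = [
    "SCENARIO_NAMES",
    "ModelScenario",
    "LabeledPredictions",
    "get_scenario",
    "allocate_presences",
    "density",
    "cdf",
    "quantile",
    "sample_labeled_predictions",
]

#: Beta parameters (alpha1, beta1, alpha0, beta0) per scenario.
_SCENARIO_PARAMS = {
    "quadratic": (3.0, 1.0, 1.0, 3.0),
    "linear": (2.0, 1.0, 1.0, 2.0),
    "square_root": (1.5, 1.0, 1.0, 1.5),
    "p16": (17.0 / 16.0, 1.0, 1.0, 17.0 / 16.0),
}

SCENARIO_NAMES = tuple(_SCENARIO_PARAMS)


@dataclass(frozen=True)
class ModelScenario:
    """A discrimination-quality scenario: beta parameters of f1 and f0."""

    name: str
    alpha1: float
    beta1: float
    alpha0: float
    beta0: float

    @classmethod
    def from_name(cls, name: str) -> "ModelScenario":
        try:
            a1, b1, a0, b0 = _SCENARIO_PARAMS[name]
        except KeyError:
            raise ValueError(
                f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}"
            ) from None
        return cls(name=name, alpha1=a1, beta1=b1, alpha0=a0, beta0=b0)

    def params(self, cond: str):
        """(alpha, beta) of the requested conditional density."""
        if cond == "presence":
            return self.alpha1, self.beta1
        if cond == "absence":
            return self.alpha0, self.beta0
        raise ValueError(f"cond must be 'presence' or 'absence', got {cond!r}")


def get_scenario(name_or_scenario: Union[str, ModelScenario]) -> ModelScenario:
    if isinstance(name_or_scenario, ModelScenario):
        return name_or_scenario
    return ModelScenario.from_name(name_or_scenario)


@dataclass(frozen=True)
class LabeledPredictions:
    """One simulated dataset: binary truth labels and predicted scores."""

    labels: np.ndarray
    probs: np.ndarray
    scenario: ModelScenario
    prevalence: float
    seed: Optional[object] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.labels.shape != self.probs.shape:
            raise ValueError("labels and probs must have equal length")

    @property
    def n_total(self) -> int:
        return int(self.labels.size)

    @property
    def n_presence(self) -> int:
        return int(np.sum(self.labels == 1))


def allocate_presences(n_total: int, prevalence: float) -> int:
    """Number of presence labels P = round(prevalence * n_total).

    Clamped to [1, n_total - 1] so both classes always exist; with the
    standard grid (N in {100, 1000, 10000}, prevalence a multiple of 0.05)
    the product is integral and no clamping occurs.
    """
    if n_total < 2:
        raise ValueError("n_total must be >= 2 to hold both classes")
    if not 0 < prevalence < 1:
        raise ValueError(f"prevalence {prevalence!r} must be in (0, 1)")
    p = round(prevalence * n_total)
    return int(min(max(p, 1), n_total - 1))


def _beta_pdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    inside = (x >= 0) & (x <= 1)
    out = np.zeros_like(x, dtype=float)
    xv = np.clip(x, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = xv ** (a - 1) * (1 - xv) ** (b - 1) / special.beta(a, b)
    out[inside] = val[inside]
    return out


def density(scenario, x, cond: str):
    """Conditional beta density f1 (presence) or f0 (absence) at x.

    Zero outside [0, 1].
    """
    sc = get_scenario(scenario)
    a, b = sc.params(cond)
    x = np.asarray(x, dtype=float)
    res = _beta_pdf(np.atleast_1d(x), a, b)
    return res[0] if x.ndim == 0 else res


def cdf(scenario, x, cond: str):
    """Conditional distribution function F1 or F0 at x.

    Closed forms x**a (beta=1) and 1-(1-x)**b (alpha=1) are used where they
    apply; the regularized incomplete beta function otherwise.
    """
    sc = get_scenario(scenario)
    a, b = sc.params(cond)
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x outside [0, 1]")
    if b == 1.0:
        return x ** a
    if a == 1.0:
        return 1.0 - (1.0 - x) ** b
    return special.betainc(a, b, x)


def quantile(scenario, u, cond: str):
    """Inverse of :func:`cdf` (the quantile transform used for sampling)."""
    sc = get_scenario(scenario)
    a, b = sc.params(cond)
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u outside [0, 1]")
    if b == 1.0:
        return u ** (1.0 / a)
    if a == 1.0:
        return 1.0 - (1.0 - u) ** (1.0 / b)
    return special.betaincinv(a, b, u)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_labeled_predictions(
    scenario,
    n_total: int,
    prevalence: float,
    rng,
) -> LabeledPredictions:
    """Draw one labeled prediction set.

    P = round(prevalence * n_total) sites are labeled present and receive
    scores drawn i.i.d. from f1; the remaining sites are absences with
    scores from f0.  ``rng`` may be a seed (int / SeedSequence) or an
    existing :class:`numpy.random.Generator`.
    """
    sc = get_scenario(scenario)
    gen = _as_rng(rng)
    n_pres = allocate_presences(n_total, prevalence)
    u = gen.random(n_total)
    probs = np.empty(n_total, dtype=float)
    probs[:n_pres] = quantile(sc, u[:n_pres], "presence")
    probs[n_pres:] = quantile(sc, u[n_pres:], "absence")
    labels = np.zeros(n_total, dtype=np.int8)
    labels[:n_pres] = 1
    seed_repr = rng if not isinstance(rng, np.random.Generator) else None
    return LabeledPredictions(
        labels=labels, probs=probs, scenario=sc,
        prevalence=prevalence, seed=seed_repr,
    )
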