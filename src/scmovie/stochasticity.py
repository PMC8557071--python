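"""Parametric characterization of single-cell attribute stochasticity.

Life attributes such as the interdivision time, division length and
elongation rate are skewed over a bacterial population; this module fits
Normal, Gamma and Lognormal models by maximum likelihood and selects
among them with the Bayesian Information Criterion (lower is better).
All three families have two free parameters, so BIC = -2 loglik + 2 ln n.
ΔBIC relative to the best family follows Jeffreys' scale: > 5 is strong,
> 10 decisive evidence against the weaker model.

Parameterizations: Normal(mu, sigma); Gamma with shape alpha and *rate*
beta so the mean is alpha/beta; Lognormal(mu_log, sigma_log) on the log
scale.  MLE variances use the n denominator (the descriptive life-
attribute statistics elsewhere use n-1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

logger = logging.getLogger(__name__)

FAMILIES = ("normal", "gamma", "lognormal")

#: Jeffreys' scale annotations for ΔBIC against the best model.
def jeffreys_label(delta_bic: float) -> str:
    if delta_bic > 10:
        return "decisive"
    if delta_bic > 5:
        return "strong"
    return "weak"


@dataclass
class DistributionFit:
    """An MLE fit of one parametric family to a sample."""

    family: str
    params: tuple[float, float]
    loglik: float
    n: int
    bic: float


@dataclass
class ModelSelection:
    """Per-family fits with BIC ranking."""

    fits: dict[str, DistributionFit]
    best: str
    delta_bic: dict[str, float] = field(default_factory=dict)

    def label(self, family: str) -> str:
        return jeffreys_label(self.delta_bic[family])


def _check_sample(x: np.ndarray, family: str) -> None:
    if x.size < 8:
        raise ValueError(f"need >= 8 samples for a 2-parameter MLE, got {x.size}")
    if family in ("gamma", "lognormal") and np.any(x <= 0):
        raise ValueError(f"{family} requires strictly positive samples")
    if np.var(x) == 0 or (family == "lognormal" and np.var(np.log(x)) == 0):
        raise ValueError("sample variance is zero; fit is degenerate")


def _gamma_mle_shape(logmean_minus_meanlog: float, tol: float = 1e-10) -> float:
    """Solve log(a) - digamma(a) = s for the gamma shape by Newton iteration.

    Started from the Minka moment-style approximation; converges in a
    handful of iterations for any s > 0.
    """
    s = logmean_minus_meanlog
    a = (3 - s + math.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    for _ in range(100):
        f = math.log(a) - special.digamma(a) - s
        fp = 1.0 / a - special.polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2
        if abs(a_new - a) <= tol * a:
            return a_new
        a = a_new
    return a


def fit_distribution(samples, family: str) -> DistributionFit:
    """Maximum-likelihood fit of one family, with log-likelihood and BIC.

    Normal and lognormal use the closed-form MLE (variance with the n
    denominator); gamma solves the shape score equation numerically.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = np.asarray(samples, dtype=float)
    _check_sample(x, family)
    n = x.size

    if family == "normal":
        mu = float(np.mean(x))
        sigma = float(np.sqrt(np.mean((x - mu) ** 2)))
        ll = float(np.sum(stats.norm.logpdf(x, mu, sigma)))
        params = (mu, sigma)
    elif family == "lognormal":
        lx = np.log(x)
        mu = float(np.mean(lx))
        sigma = float(np.sqrt(np.mean((lx - mu) ** 2)))
        ll = float(np.sum(stats.lognorm.logpdf(x, s=sigma, scale=math.exp(mu))))
        params = (mu, sigma)
    else:
        s = math.log(np.mean(x)) - float(np.mean(np.log(x)))
        alpha = _gamma_mle_shape(s)
        beta = alpha / float(np.mean(x))
        ll = float(np.sum(stats.gamma.logpdf(x, a=alpha, scale=1.0 / beta)))
        params = (alpha, beta)

    bic = -2.0 * ll + 2.0 * math.log(n)
    return DistributionFit(family, params, ll, n, bic)


def best_fit_auto(samples) -> ModelSelection:
    """Fit all three families and select the one with minimal BIC.

    A family whose domain excludes the sample (e.g. nonpositive values
    for gamma/lognormal) is dropped with a warning; at least two families
    must remain for a selection.
    """
    fits: dict[str, DistributionFit] = {}
    for family in FAMILIES:
        try:
            fits[family] = fit_distribution(samples, family)
        except ValueError as exc:
            logger.warning("family %s excluded: %s", family, exc)
    if len(fits) < 2:
        raise ValueError(f"fewer than 2 candidate families could be fitted ({sorted(fits)})")
    best = min(fits, key=lambda f: fits[f].bic)
    delta = {f: fits[f].bic - fits[best].bic for f in fits}
    return ModelSelection(fits=fits, best=best, delta_bic=delta)


def dominant_family(selections: dict) -> str:
    """The family most often competitive (ΔBIC <= 5) across groups.

    Given per-group model selections (e.g. one per generation or colony),
    counts for each family the groups where its ΔBIC against that group's
    best model is at most 5, and returns the family with the highest
    count.  Ties break toward the smallest mean ΔBIC across groups.
    """
    if not selections:
        raise ValueError("need at least one group")
    counts = dict.fromkeys(FAMILIES, 0)
    sums = dict.fromkeys(FAMILIES, 0.0)
    present = set()
    for sel in selections.values():
        for family, d in sel.delta_bic.items():
            present.add(family)
            if d <= 5:
                counts[family] += 1
            sums[family] += d
    candidates = sorted(present)
    return max(candidates, key=lambda f: (counts[f], -sums[f] / len(selections)))


def dist_mean_sd(family: str, params) -> dict:
    """Mean, standard deviation, and variance of a fitted family.

    Means: mu (normal), alpha/beta (gamma), exp(mu_log + sigma_log^2 / 2)
    (lognormal).  Both the variance and its square root are returned,
    labeled, since summary tables in the field sometimes print one where
    the other is meant.
    """
    a, b = params
    if family == "normal":
        mean, var = a, b**2
        if b <= 0:
            raise ValueError("sigma must be > 0")
    elif family == "gamma":
        if a <= 0 or b <= 0:
            raise ValueError("alpha and beta must be > 0")
        mean, var = a / b, a / b**2
    elif family == "lognormal":
        if b <= 0:
            raise ValueError("sigma_log must be > 0")
        mean = math.exp(a + b**2 / 2)
        var = (math.exp(b**2) - 1) * math.exp(2 * a + b**2)
    else:
        raise ValueError(f"unknown family {family!r}")
    return {"mean": mean, "sd": math.sqrt(var), "variance": var}


def fit_attribute_by_group(
    fdt, attr: str, group_by: str | None = None
) -> dict[object, ModelSelection]:
    """Run BIC model selection on a life attribute, optionally per group.

    ``group_by`` may be any life attribute such as ``generation`` or
    ``colony``; ``None`` treats the whole forest as one group keyed
    "population".  Groups too small or degenerate to fit are skipped with
    a warning.
    """
    values: dict[object, list[float]] = {}
    for cell_id in fdt.cell_nodes():
        data = fdt.graph.nodes[cell_id]
        if attr not in data or data[attr] is None or not np.isfinite(data[attr]):
            continue
        key = data[group_by] if group_by else "population"
        values.setdefault(key, []).append(float(data[attr]))
    out: dict[object, ModelSelection] = {}
    for key in sorted(values, key=str):
        try:
            out[key] = best_fit_auto(values[key])
        except ValueError as exc:
            logger.warning("group %r skipped: %s", key, exc)
    return out
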