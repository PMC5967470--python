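"""Downstream quantities: mean fixation rate, adaptive proportion, summaries.

The mean fixation rate of new mutations, relative to neutral and in units of
2*Ne generations, is

    mu_bar = (1/theta) * sum_c theta_c * gamma_c / (1 - exp(-gamma_c))

for a discrete DFE, and E[g / (e^g - 1)] with g = -gamma ~ Gamma(a, b) for
the reflected-Gamma DFE.  It enters the proportion of adaptive substitutions

    alpha = (d_sel - d_neu * mu_bar) / d_sel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kernel import GammaDFE, _gauss_genlaguerre
from .sfs_data import FitResult, PolarisedSFS, SFSValidationError, SiteClassParams

__all__ = [
    "DivergenceData",
    "fixation_rate_factor",
    "mean_fixation_rate_discrete",
    "mean_fixation_rate_continuous",
    "mean_fixation_rate",
    "alpha",
    "pooled_alpha",
    "scale_neutral_divergence",
    "SummaryStats",
    "sfs_summary_stats",
]


@dataclass(frozen=True)
class DivergenceData:
    """Per-site substitution counts in the selected and neutral compartments."""

    d_sel: float
    d_neu: float

    def __post_init__(self) -> None:
        if self.d_sel < 0 or self.d_neu < 0:
            raise SFSValidationError("divergence values must be non-negative")


def fixation_rate_factor(gamma):
    """gamma / (1 - exp(-gamma)), the fixation rate relative to neutral.

    Continuous through gamma = 0 (limit 1); overflow-safe for any float via
    expm1 (for gamma = -g < 0 this is g * e^-g / (1 - e^-g))."""
    g = np.asarray(gamma, dtype=float)
    out = np.empty_like(g)
    small = np.abs(g) < 1e-8
    out[small] = 1.0 + g[small] / 2.0
    neg = (~small) & (g < 0)
    mag = -g[neg]
    out[neg] = mag * np.exp(-mag) / (-np.expm1(-mag))
    pos = (~small) & (g > 0)
    out[pos] = g[pos] / (-np.expm1(-g[pos]))
    return float(out) if np.isscalar(gamma) or np.ndim(gamma) == 0 else out


def mean_fixation_rate_discrete(classes: list[SiteClassParams]) -> float:
    """theta-weighted mean of the per-class fixation rate factors."""
    theta_total = sum(c.theta for c in classes)
    if theta_total <= 0:
        raise SFSValidationError("total theta must be positive to define mu_bar")
    return float(
        sum(c.theta * fixation_rate_factor(c.gamma) for c in classes) / theta_total
    )


def mean_fixation_rate_continuous(dfe: GammaDFE, order: int = 128) -> float:
    """E[g / (e^g - 1)] for g ~ Gamma(a, b), by Gauss quadrature.

    Folding the e^-g decay of the integrand into the Gamma weight
    (substituting g = u*b/(1+b)) leaves only the smooth, polynomially
    growing factor g / (1 - e^-g) under a pure Gauss-Laguerre rule, so the
    default order is converged well past 1e-6 relative.
    """
    a, b = dfe.shape, dfe.scale
    u, w = _gauss_genlaguerre(order, a - 1.0)
    g = u * (b / (1.0 + b))
    phi = np.where(g > 1e-8, g / (-np.expm1(-np.maximum(g, 1e-300))), 1.0 + g / 2.0)
    return float((1.0 + b) ** (-a) * np.dot(w, phi) / w.sum())


def mean_fixation_rate(fit: FitResult | dict, variant_type: str = "snp") -> float:
    """mu_bar for one variant type of a fitted model (discrete or continuous)."""
    params = fit.params if isinstance(fit, FitResult) else fit
    if f"{variant_type}.shape" in params:
        return mean_fixation_rate_continuous(
            GammaDFE(shape=params[f"{variant_type}.shape"], scale=params[f"{variant_type}.scale"])
        )
    classes = []
    c = 1
    while f"{variant_type}.class{c}.theta" in params:
        classes.append(
            SiteClassParams(
                theta=params[f"{variant_type}.class{c}.theta"],
                gamma=params[f"{variant_type}.class{c}.gamma"],
                epsilon=min(max(params[f"{variant_type}.class{c}.epsilon"], 0.0), 0.5),
            )
        )
        c += 1
    if not classes:
        raise SFSValidationError(f"no parameters for variant type {variant_type!r}")
    return mean_fixation_rate_discrete(classes)


def alpha(div: DivergenceData, mu_bar: float) -> float:
    """Proportion of adaptive substitutions; may be negative."""
    if div.d_sel <= 0:
        raise SFSValidationError("d_sel must be positive to define alpha")
    return (div.d_sel - div.d_neu * mu_bar) / div.d_sel


def pooled_alpha(alphas: dict[str, float], d_sels: dict[str, float]) -> float:
    """Substitution-count-weighted combination of per-type alpha values."""
    total = sum(d_sels.values())
    if total <= 0:
        raise SFSValidationError("pooling requires positive selected divergence")
    return sum(alphas[t] * d_sels[t] for t in alphas) / total


def scale_neutral_divergence(
    d_point: float, snp_indel_ratio: float, del_ins_ratio: float
) -> tuple[float, float, float]:
    """Split neutral point-mutation divergence into INDEL/ins/del divergence.

    Uses mutation-accumulation rate ratios: d_indel = d_point / snp_indel_ratio,
    then d_ins : d_del = 1 : del_ins_ratio.
    """
    if d_point <= 0 or snp_indel_ratio <= 0 or del_ins_ratio <= 0:
        raise SFSValidationError("divergence and rate ratios must be positive")
    d_indel = d_point / snp_indel_ratio
    d_ins = d_indel / (1.0 + del_ins_ratio)
    d_del = d_indel * del_ins_ratio / (1.0 + del_ins_ratio)
    return d_indel, d_ins, d_del


@dataclass(frozen=True)
class SummaryStats:
    pi: float
    watterson_theta: float
    tajima_d: float | None


def sfs_summary_stats(sfs: PolarisedSFS) -> SummaryStats:
    """Per-site pi and Watterson's theta, and Tajima's D.

    D uses the standard variance normalisation; it is undefined (None) when
    there are no segregating sites.
    """
    n = sfs.frame.n
    m = sfs.frame.m
    x = sfs.counts
    i = np.arange(1, n, dtype=float)
    s = float(x.sum())
    pi_total = 2.0 * float(np.dot(i * (n - i), x)) / (n * (n - 1.0))
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    pi = pi_total / m
    theta_w = s / (a1 * m)
    if s == 0:
        return SummaryStats(pi=pi, watterson_theta=theta_w, tajima_d=None)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1.0)
    d = (pi_total - s / a1) / math.sqrt(var)
    return SummaryStats(pi=pi, watterson_theta=theta_w, tajima_d=d)
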