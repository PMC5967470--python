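"""Poisson random field likelihoods, ML fitting, and model comparison.

Dropping terms that do not depend on the parameters, the log likelihood of
an observed spectrum X under expected spectrum psi is

    L = sum_i ( -psi_i + x_i * ln(psi_i) ),

summed over variant types (SNP, or insertions + deletions jointly) and, when
a neutral reference is attached, over the selected and neutral regions with
a shared demography-nuisance vector R.

Fitting works in a transformed parameter space (log for theta, scale and r;
logit on [0, 0.5] for epsilon; identity for gamma) with bound-constrained
quasi-Newton optimisation from multiple starting points, followed by a
derivative-free polish of the best start.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from . import kernel
from .kernel import GammaDFE
from .model import ExpectedSFS
from .sfs_data import (
    FitResult,
    ModelSpec,
    PolarisedSFS,
    PolarisedSFSSet,
    SampleFrame,
    SFSValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerOptions",
    "ParamLayout",
    "poisson_log_likelihood",
    "indel_log_likelihood",
    "joint_log_likelihood",
    "apply_constraints",
    "fit_model",
    "likelihood_ratio_test",
    "aic_compare",
    "mle_classes",
]

#: default box bounds per parameter kind, chosen to cover every fitted value
#: reported for this model family (including gamma ~ -1600) with margin
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "theta": (1e-12, 0.1),
    "gamma": (-5000.0, 100.0),
    "epsilon": (1e-8, 0.5 - 1e-8),
    "shape": (0.01, 100.0),
    "scale": (1e-4, 1e6),
    "r": (0.01, 100.0),
}

_GAMMA_START_LADDER = (-0.5, -10.0, -50.0, -300.0, -1000.0)


def param_kind(pid: str) -> str:
    if pid.startswith("r."):
        return "r"
    suffix = pid.rsplit(".", 1)[-1]
    if suffix in ("theta", "gamma", "epsilon", "shape", "scale"):
        return suffix
    raise SFSValidationError(f"cannot infer kind of parameter {pid!r}")


def _to_z(kind: str, v: float) -> float:
    if kind in ("theta", "shape", "scale", "r"):
        return math.log(v)
    if kind == "epsilon":
        v = min(max(v, 1e-12), 0.5 - 1e-12)
        return math.log(v / (0.5 - v))
    return v


def _from_z(kind: str, z: float) -> float:
    if kind in ("theta", "shape", "scale", "r"):
        return math.exp(z)
    if kind == "epsilon":
        return 0.5 / (1.0 + math.exp(-z)) if z < 700 else 0.5
    return z


@dataclass
class OptimizerOptions:
    """Multi-start optimisation settings.

    ``n_starts`` counts one deterministic moment-style start plus random
    starts; ``seed`` makes the random starts reproducible.  ``bounds``
    overrides the per-kind box constraints.  ``use_interpolation`` routes
    likelihood evaluations through the per-n spline surrogate of tau
    (recommended; exact quadrature is used everywhere else).
    """

    n_starts: int = 10
    seed: int = 0
    tol: float = 1e-8
    maxiter: int = 500
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    use_interpolation: bool = True
    quad_points_gamma: int = 64
    gamma_start_range: tuple[float, float] = (-100.0, 10.0)
    nelder_polish: bool = True

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise SFSValidationError("n_starts must be >= 1")


# ---------------------------------------------------------------------------
# parameter layout and constraint expansion

class ParamLayout:
    """Maps between the free-parameter vector and the full parameter dict."""

    def __init__(self, spec: ModelSpec, n: int):
        self.spec = spec
        self.n = n
        self.all_ids = spec.param_ids(n)
        self.free_ids = spec.free_param_ids(n)
        self.ties = spec.epsilon_ties()
        self.fixed = spec.fixed_params()
        self.kinds = {pid: param_kind(pid) for pid in self.all_ids}

    @property
    def k(self) -> int:
        return len(self.free_ids)

    def full_params(self, free_values) -> dict[str, float]:
        free_values = np.asarray(free_values, dtype=float)
        if free_values.shape != (self.k,):
            raise SFSValidationError(
                f"free vector must have length k={self.k}, got {free_values.shape}"
            )
        full = dict(zip(self.free_ids, free_values.tolist()))
        full.update(self.fixed)
        for pid, leader in self.ties.items():
            full[pid] = full[leader]
        for rc in self.spec.ratio_constraints:
            full[rc.numerator] = rc.ratio * sum(full[d] for d in rc.denominators)
        return {pid: full[pid] for pid in self.all_ids}

    def free_vector(self, params: dict[str, float]) -> np.ndarray:
        return np.array([params[pid] for pid in self.free_ids])

    def to_z(self, free_values) -> np.ndarray:
        return np.array(
            [_to_z(self.kinds[pid], v) for pid, v in zip(self.free_ids, free_values)]
        )

    def from_z(self, z) -> np.ndarray:
        return np.array([_from_z(self.kinds[pid], v) for pid, v in zip(self.free_ids, z)])

    def z_bounds(self, bounds: dict[str, tuple[float, float]]) -> list[tuple[float, float]]:
        out = []
        for pid in self.free_ids:
            kind = self.kinds[pid]
            lo, hi = bounds.get(kind, DEFAULT_BOUNDS[kind])
            if kind == "epsilon":
                lo = max(lo, 1e-8)
                hi = min(hi, 0.5 - 1e-8)
            out.append((_to_z(kind, lo), _to_z(kind, hi)))
        return out


def apply_constraints(free_vector, spec: ModelSpec, n: int) -> dict[str, float]:
    """Expand a free-parameter vector into the full parameter dict.

    Tied epsilons are copied from their leader, 'zero' error models are fixed
    at 0, and each ratio constraint derives its numerator parameter as
    ratio * sum(denominators).
    """
    return ParamLayout(spec, n).full_params(free_vector)


# ---------------------------------------------------------------------------
# expected spectra for a full parameter dict (fast array path)

def _neutral_tau(n: int) -> np.ndarray:
    return 1.0 / np.arange(1, n, dtype=float)


def _type_class_spectra(
    spec: ModelSpec, params: dict[str, float], vtype: str, m: float, ev, order: int
) -> list[tuple[np.ndarray, float]]:
    """Uncorrected spectra and epsilons for every class of one selected type."""
    tm = spec.types[vtype]
    out = []
    if tm.dfe == "discrete":
        for c in range(1, tm.n_classes + 1):
            theta = params[f"{vtype}.class{c}.theta"]
            gamma = params[f"{vtype}.class{c}.gamma"]
            eps = params[f"{vtype}.class{c}.epsilon"]
            out.append((m * theta * ev.vector(gamma), eps))
    else:
        dfe = GammaDFE(shape=params[f"{vtype}.shape"], scale=params[f"{vtype}.scale"])
        out.append((m * params[f"{vtype}.theta"] * ev.dfe_vector(dfe, order=order), params[f"{vtype}.epsilon"]))
    return out


def _mix(classes: list[tuple[np.ndarray, float]]) -> np.ndarray:
    acc = np.zeros_like(classes[0][0])
    for psi, e in classes:
        acc += (1.0 - e) * psi + e * psi[::-1]
    return acc


def _mix_indel(ins, dels) -> tuple[np.ndarray, np.ndarray]:
    psi_ins = np.zeros_like(ins[0][0])
    psi_del = np.zeros_like(psi_ins)
    for psi, e in ins:
        psi_ins += (1.0 - e) * psi
        psi_del += e * psi[::-1]
    for psi, e in dels:
        psi_del += (1.0 - e) * psi
        psi_ins += e * psi[::-1]
    return psi_ins, psi_del


def expected_spectra(
    spec: ModelSpec,
    params: dict[str, float],
    frames: dict[str, SampleFrame],
    evaluator=None,
    order: int = 64,
) -> dict[tuple[str, str], np.ndarray]:
    """Corrected expected spectra for every (region, type) the model covers."""
    n = frames[spec.selected_region].n
    ev = evaluator or kernel.ExactTauEvaluator(n)
    r = None
    if spec.demography:
        r = np.array([params[f"r.{i}"] for i in range(2, n)])

    def augment(classes):
        if r is None:
            return classes
        out = []
        for psi, e in classes:
            scaled = psi.copy()
            scaled[1:] *= r
            out.append((scaled, e))
        return out

    out: dict[tuple[str, str], np.ndarray] = {}
    m_sel = frames[spec.selected_region].m
    per_type = {
        t: augment(_type_class_spectra(spec, params, t, m_sel, ev, order))
        for t in spec.types
    }
    if "snp" in per_type:
        out[(spec.selected_region, "snp")] = _mix(per_type["snp"])
    if "ins" in per_type:
        psi_ins, psi_del = _mix_indel(per_type["ins"], per_type["del"])
        out[(spec.selected_region, "ins")] = psi_ins
        out[(spec.selected_region, "del")] = psi_del

    if spec.has_neutral:
        m_neu = frames[spec.neutral_region].m
        tau0 = _neutral_tau(n)
        neutral = {
            t: augment(
                [(m_neu * params[f"{t}.neutral.theta"] * tau0, params[f"{t}.neutral.epsilon"])]
            )
            for t in spec.neutral_types
        }
        if "snp" in neutral:
            out[(spec.neutral_region, "snp")] = _mix(neutral["snp"])
        if "ins" in neutral:
            psi_ins, psi_del = _mix_indel(neutral["ins"], neutral["del"])
            out[(spec.neutral_region, "ins")] = psi_ins
            out[(spec.neutral_region, "del")] = psi_del
    return out


# ---------------------------------------------------------------------------
# log likelihoods

def _poisson_terms(psi: np.ndarray, x: np.ndarray) -> float:
    if np.any(psi < 0):
        raise SFSValidationError("expected SFS contains negative values")
    total = -float(psi.sum())
    pos = x > 0
    if np.any(pos):
        with np.errstate(divide="ignore"):
            lp = np.log(psi[pos])
        total += float(np.dot(x[pos], lp))
    return total


def poisson_log_likelihood(expected: ExpectedSFS, observed: PolarisedSFS) -> float:
    """sum_i(-psi_i + x_i ln psi_i); -inf if psi_i = 0 where x_i > 0."""
    if expected.frame != observed.frame:
        raise SFSValidationError("expected and observed spectra must share one SampleFrame")
    return _poisson_terms(expected.values, observed.counts)


def indel_log_likelihood(
    psi_ins: ExpectedSFS, psi_del: ExpectedSFS, x_ins: PolarisedSFS, x_del: PolarisedSFS
) -> float:
    """Joint insertion + deletion likelihood (sum of the two Poisson terms)."""
    return poisson_log_likelihood(psi_ins, x_ins) + poisson_log_likelihood(psi_del, x_del)


def _required_keys(spec: ModelSpec) -> list[tuple[str, str]]:
    keys = [(spec.selected_region, t) for t in ("snp", "ins", "del") if t in spec.types]
    keys += [(spec.neutral_region, t) for t in ("snp", "ins", "del") if t in spec.neutral_types]
    return keys


def _frames_from_data(spec: ModelSpec, data: PolarisedSFSSet) -> dict[str, SampleFrame]:
    frames = {spec.selected_region: data.frame(spec.selected_region)}
    if spec.has_neutral:
        frames[spec.neutral_region] = data.frame(spec.neutral_region)
    return frames


def joint_log_likelihood(
    spec: ModelSpec,
    params: dict[str, float],
    data: PolarisedSFSSet,
    evaluator=None,
    order: int = 64,
) -> float:
    """Selected-region (+ optional neutral-region) log likelihood, shared R."""
    for key in _required_keys(spec):
        if key not in data:
            raise SFSValidationError(f"data set lacks the required entry {key}")
    frames = _frames_from_data(spec, data)
    psi = expected_spectra(spec, params, frames, evaluator=evaluator, order=order)
    return sum(_poisson_terms(psi[key], data[key].counts) for key in _required_keys(spec))


# ---------------------------------------------------------------------------
# fitting

def _watterson_theta(sfs: PolarisedSFS) -> float:
    n = sfs.frame.n
    a_n = np.sum(1.0 / np.arange(1, n))
    return max(sfs.segregating_sites / (a_n * sfs.frame.m), 1e-9)


def _default_start(spec: ModelSpec, data: PolarisedSFSSet, n: int) -> dict[str, float]:
    start: dict[str, float] = {}
    for t, tm in spec.types.items():
        tw = _watterson_theta(data[(spec.selected_region, t)])
        if tm.dfe == "discrete":
            for c in range(1, tm.n_classes + 1):
                start[f"{t}.class{c}.theta"] = tw / tm.n_classes
                start[f"{t}.class{c}.gamma"] = _GAMMA_START_LADDER[(c - 1) % len(_GAMMA_START_LADDER)]
                start[f"{t}.class{c}.epsilon"] = 0.05
        else:
            start[f"{t}.theta"] = 1.5 * tw
            start[f"{t}.shape"] = 0.5
            start[f"{t}.scale"] = 30.0
            start[f"{t}.epsilon"] = 0.05
    for t in spec.neutral_types:
        start[f"{t}.neutral.theta"] = _watterson_theta(data[(spec.neutral_region, t)])
        start[f"{t}.neutral.epsilon"] = 0.05
    if spec.demography:
        for i in range(2, n):
            start[f"r.{i}"] = 1.0
    return start


def _random_start(
    layout: ParamLayout, base: dict[str, float], rng: np.random.Generator,
    options: OptimizerOptions,
) -> dict[str, float]:
    start = dict(base)
    glo, ghi = options.gamma_start_range
    for pid in layout.free_ids:
        kind = layout.kinds[pid]
        if kind == "theta":
            start[pid] = base[pid] * math.exp(rng.uniform(math.log(1 / 30), math.log(3)))
        elif kind == "gamma":
            start[pid] = rng.uniform(glo, ghi)
        elif kind == "epsilon":
            start[pid] = rng.uniform(0.005, 0.3)
        elif kind == "shape":
            start[pid] = math.exp(rng.uniform(math.log(0.05), math.log(5.0)))
        elif kind == "scale":
            start[pid] = math.exp(rng.uniform(math.log(0.5), math.log(5000.0)))
        elif kind == "r":
            start[pid] = math.exp(rng.uniform(math.log(0.5), math.log(2.0)))
    return start


def mle_classes(params: dict[str, float], vtype: str) -> list[tuple[float, float, float]]:
    """(theta, gamma, epsilon) triples of a discrete type, as stored."""
    out = []
    c = 1
    while f"{vtype}.class{c}.theta" in params:
        out.append(
            (
                params[f"{vtype}.class{c}.theta"],
                params[f"{vtype}.class{c}.gamma"],
                params[f"{vtype}.class{c}.epsilon"],
            )
        )
        c += 1
    return out


def _sort_classes(spec: ModelSpec, params: dict[str, float]) -> dict[str, float]:
    """Relabel discrete classes by gamma descending (label-switching fix)."""
    params = dict(params)
    for t, tm in spec.types.items():
        if tm.dfe != "discrete" or tm.n_classes < 2:
            continue
        triples = mle_classes(params, t)
        triples.sort(key=lambda tr: -tr[1])
        for c, (theta, gamma, eps) in enumerate(triples, 1):
            params[f"{t}.class{c}.theta"] = theta
            params[f"{t}.class{c}.gamma"] = gamma
            params[f"{t}.class{c}.epsilon"] = eps
    return params


def fit_model(
    spec: ModelSpec, data: PolarisedSFSSet, options: OptimizerOptions | None = None
) -> FitResult:
    """Maximum-likelihood fit with multiple starts; deterministic given seed.

    Returns the best local optimum over ``n_starts`` starts (one moment-style
    deterministic start, the rest random), polished with Nelder-Mead.
    Discrete classes are reported sorted by gamma descending.
    """
    options = options or OptimizerOptions()
    for key in _required_keys(spec):
        if key not in data:
            raise SFSValidationError(f"data set lacks the required entry {key}")
    n = data.n
    layout = ParamLayout(spec, n)
    frames = _frames_from_data(spec, data)
    ev = kernel.get_evaluator(n, interpolate=options.use_interpolation)
    counts = {key: data[key].counts for key in _required_keys(spec)}

    def neg_ll(z: np.ndarray) -> float:
        try:
            full = layout.full_params(layout.from_z(z))
            psi = expected_spectra(
                spec, full, frames, evaluator=ev, order=options.quad_points_gamma
            )
            ll = sum(_poisson_terms(psi[key], counts[key]) for key in counts)
        except (OverflowError, FloatingPointError, ValueError):
            return 1e18
        if not math.isfinite(ll):
            return 1e18
        return -ll

    rng = np.random.default_rng(options.seed)
    base = _default_start(spec, data, n)
    starts = [base]
    starts += [
        _random_start(layout, base, rng, options) for _ in range(options.n_starts - 1)
    ]
    z_bounds = layout.z_bounds(options.bounds)
    results = []
    for idx, start in enumerate(starts):
        z0 = np.clip(
            layout.to_z(layout.free_vector(start)),
            [lo for lo, _ in z_bounds],
            [hi for _, hi in z_bounds],
        )
        res = optimize.minimize(
            neg_ll, z0, method="L-BFGS-B", bounds=z_bounds,
            options={"maxiter": options.maxiter, "ftol": 1e-13, "gtol": 1e-9},
        )
        results.append(res)
        logger.info(
            "start %d: logL=%.6f converged=%s n_eval=%d", idx, -res.fun, res.success, res.nfev
        )
    best_idx = int(np.argmin([r.fun for r in results]))
    best = results[best_idx]
    if not any(r.success or math.isfinite(r.fun) for r in results):
        raise RuntimeError("no optimisation start produced a finite likelihood")
    z_best, f_best, converged = best.x, best.fun, bool(best.success)
    if options.nelder_polish:
        polish = optimize.minimize(
            neg_ll, z_best, method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-9, "xatol": 1e-9},
        )
        if polish.fun <= f_best:
            z_best, f_best = polish.x, polish.fun
            converged = converged or bool(polish.success)
    params = _sort_classes(spec, layout.full_params(layout.from_z(z_best)))
    return FitResult(
        spec=spec,
        params=params,
        loglik=-float(f_best),
        k=layout.k,
        n_starts=options.n_starts,
        converged=converged,
        start_logliks=tuple(-float(r.fun) for r in results),
        best_start=best_idx,
        seed=options.seed,
    )


# ---------------------------------------------------------------------------
# model comparison

def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """chi-square LRT of a nested pair: (statistic, df, p).

    The statistic is clipped at zero; a reduced model beating the full one by
    more than numerical tolerance triggers a warning (suspected optimiser
    failure).  The chi-square reference is used for every comparison,
    including class-count reductions where boundary effects make it
    approximate.
    """
    if reduced.k >= full.k:
        raise SFSValidationError(
            f"reduced model must have fewer free parameters ({reduced.k} >= {full.k})"
        )
    delta = 2.0 * (full.loglik - reduced.loglik)
    if delta < -1e-6:
        warnings.warn(
            f"reduced model log-likelihood exceeds the full model's by {-delta / 2:.3g}; "
            "the full-model optimisation may not have converged",
            RuntimeWarning,
            stacklevel=2,
        )
    stat = max(delta, 0.0)
    df = full.k - reduced.k
    return stat, df, float(chi2.sf(stat, df))


def aic_compare(fits: list[FitResult]):
    """AIC = 2k - 2L ranking (ascending; best first) with delta-AIC."""
    import pandas as pd

    if not fits:
        raise SFSValidationError("at least one fit is required")
    aic = np.array([2.0 * f.k - 2.0 * f.loglik for f in fits])
    order = np.argsort(aic, kind="stable")
    frame = pd.DataFrame(
        {
            "fit_index": order,
            "k": [fits[i].k for i in order],
            "loglik": [fits[i].loglik for i in order],
            "aic": aic[order],
            "delta_aic": aic[order] - aic[order[0]],
        }
    )
    return frame
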