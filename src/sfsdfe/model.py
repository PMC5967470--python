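"""Expected site-frequency spectra under mutation-selection-drift balance.

Builds the model-predicted spectrum for every model variant:

* uncorrected spectrum of one site class:      Psi_i = m * theta * tau_i(gamma)
* continuous (reflected-Gamma DFE) analogue:   Psi_i = m * theta * E[tau_i]
* demography augmentation:                     Psi*_i = r_i * Psi_i  (r_1 = 1)
* polarisation-error mixing (SNPs):            psi_i = (1-eps) Psi_i + eps Psi_{n-i}
* polarisation-error mixing (INDELs): a mispolarised insertion of size i is
  recorded as a deletion of size n-i, and vice versa, so insertion and
  deletion spectra contaminate each other.

When demography is on the order is fixed: scale by r first, then mix.  The
equations force this order; it is asserted by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import kernel
from .kernel import GammaDFE
from .sfs_data import (
    ContinuousTypeParams,
    DemographyNuisance,
    SampleFrame,
    SFSValidationError,
    SiteClassParams,
)

__all__ = [
    "ExpectedSFS",
    "uncorrected_sfs_discrete",
    "uncorrected_sfs_continuous",
    "apply_demography",
    "correct_sfs_snp",
    "correct_sfs_indel",
    "identifiability_collapse_check",
]

STAGES = ("uncorrected", "augmented", "corrected", "corrected_augmented")


@dataclass(frozen=True)
class ExpectedSFS:
    """Model-expected spectrum at one stage of the pipeline."""

    frame: SampleFrame
    variant_type: str
    values: np.ndarray = field(repr=False)
    stage: str = "uncorrected"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.frame.n - 1,):
            raise SFSValidationError(f"expected {self.frame.n - 1} values, got {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise SFSValidationError("expected SFS values must be finite and non-negative")
        if self.stage not in STAGES:
            raise SFSValidationError(f"unknown stage {self.stage!r}")

    @property
    def total(self) -> float:
        return float(self.values.sum())


def uncorrected_sfs_discrete(
    params: SiteClassParams,
    frame: SampleFrame,
    variant_type: str = "snp",
    evaluator=None,
) -> ExpectedSFS:
    """Psi_i = m * theta_c * tau_i(gamma_c) for one discrete site class."""
    ev = evaluator or kernel.ExactTauEvaluator(frame.n)
    values = frame.m * params.theta * ev.vector(params.gamma)
    return ExpectedSFS(frame=frame, variant_type=variant_type, values=values, stage="uncorrected")


def uncorrected_sfs_continuous(
    params: ContinuousTypeParams,
    frame: SampleFrame,
    variant_type: str = "snp",
    evaluator=None,
    order: int = 64,
) -> ExpectedSFS:
    """Psi_i = m * theta * E[tau_i(gamma)] under the reflected-Gamma DFE."""
    ev = evaluator or kernel.ExactTauEvaluator(frame.n)
    values = frame.m * params.theta * ev.dfe_vector(params.dfe, order=order)
    return ExpectedSFS(frame=frame, variant_type=variant_type, values=values, stage="uncorrected")


def apply_demography(uncorrected: ExpectedSFS, r: DemographyNuisance) -> ExpectedSFS:
    """Scale frequency classes i >= 2 by the shared nuisance multipliers r_i."""
    if uncorrected.stage != "uncorrected":
        raise SFSValidationError(
            f"demography must be applied to an uncorrected spectrum, got stage {uncorrected.stage!r}"
        )
    n = uncorrected.frame.n
    if r.r.shape != (n - 2,):
        raise SFSValidationError(f"r must have n-2 = {n - 2} entries, got {r.r.shape}")
    values = uncorrected.values.copy()
    values[1:] *= r.r
    return replace(uncorrected, values=values, stage="augmented")


def _check_mixable(spectra, epsilons) -> SampleFrame:
    frames = {s.frame for s in spectra}
    if len(frames) != 1:
        raise SFSValidationError("all spectra entering polarisation mixing must share one frame")
    stages = {s.stage for s in spectra}
    if not stages <= {"uncorrected", "augmented"}:
        raise SFSValidationError(f"cannot mix already-corrected spectra (stages {stages})")
    if len(stages) != 1:
        raise SFSValidationError("cannot mix augmented with unaugmented spectra")
    for e in epsilons:
        if not 0.0 <= e <= 0.5:
            raise SFSValidationError(f"epsilon must lie in [0, 0.5], got {e}")
    return next(iter(frames))


def _corrected_stage(input_stage: str) -> str:
    return "corrected_augmented" if input_stage == "augmented" else "corrected"


def correct_sfs_snp(per_class: list[tuple[ExpectedSFS, float]]) -> ExpectedSFS:
    """psi_i = sum_c [(1-eps_c) Psi_{c,i} + eps_c Psi_{c,n-i}].

    Inputs are augmented spectra when demography is on (scale first, then mix).
    """
    if not per_class:
        raise SFSValidationError("at least one site class is required")
    spectra = [s for s, _ in per_class]
    eps = [e for _, e in per_class]
    frame = _check_mixable(spectra, eps)
    values = np.zeros(frame.n - 1)
    for s, e in per_class:
        values += (1.0 - e) * s.values + e * s.values[::-1]
    return ExpectedSFS(
        frame=frame, variant_type=spectra[0].variant_type, values=values,
        stage=_corrected_stage(spectra[0].stage),
    )


def correct_sfs_indel(
    ins_classes: list[tuple[ExpectedSFS, float]],
    del_classes: list[tuple[ExpectedSFS, float]],
) -> tuple[ExpectedSFS, ExpectedSFS]:
    """Joint polarisation mixing of insertion and deletion spectra.

    psi^ins_i = sum_c (1-eps^ins_c) Psi^ins_{c,i} + sum_d eps^del_d Psi^del_{d,n-i}
    and symmetrically for deletions.
    """
    if not ins_classes or not del_classes:
        raise SFSValidationError("both insertion and deletion classes are required")
    spectra = [s for s, _ in ins_classes + del_classes]
    eps = [e for _, e in ins_classes + del_classes]
    frame = _check_mixable(spectra, eps)
    stage = _corrected_stage(spectra[0].stage)
    psi_ins = np.zeros(frame.n - 1)
    psi_del = np.zeros(frame.n - 1)
    for s, e in ins_classes:
        psi_ins += (1.0 - e) * s.values
        psi_del += e * s.values[::-1]
    for s, e in del_classes:
        psi_del += (1.0 - e) * s.values
        psi_ins += e * s.values[::-1]
    return (
        ExpectedSFS(frame=frame, variant_type="ins", values=psi_ins, stage=stage),
        ExpectedSFS(frame=frame, variant_type="del", values=psi_del, stage=stage),
    )


def identifiability_collapse_check(
    classes: list[SiteClassParams], frame: SampleFrame, rtol: float = 1e-10
) -> tuple[float, float]:
    """Collapse equal-gamma classes to (theta_total, eps*) and verify equality.

    When every class shares one gamma the multi-class corrected spectrum is
    indistinguishable from a single class with theta = sum theta_c and
    eps* = sum(eps_c theta_c) / theta.  Returns (theta_total, eps*); raises
    if the two spectra differ beyond ``rtol`` (which would indicate a
    numerical defect, not a modelling choice).
    """
    if not classes:
        raise SFSValidationError("at least one site class is required")
    gammas = {c.gamma for c in classes}
    if len(gammas) != 1:
        raise SFSValidationError(f"collapse requires equal gamma across classes, got {sorted(gammas)}")
    theta_total = sum(c.theta for c in classes)
    if theta_total <= 0:
        raise SFSValidationError("total theta must be positive")
    eps_star = sum(c.epsilon * c.theta for c in classes) / theta_total
    multi = correct_sfs_snp(
        [(uncorrected_sfs_discrete(c, frame), c.epsilon) for c in classes]
    )
    single = correct_sfs_snp(
        [(
            uncorrected_sfs_discrete(
                SiteClassParams(theta=theta_total, gamma=classes[0].gamma, epsilon=eps_star), frame
            ),
            eps_star,
        )]
    )
    if not np.allclose(multi.values, single.values, rtol=rtol, atol=0.0):
        raise AssertionError("identifiability collapse violated beyond numerical tolerance")
    return theta_total, eps_star
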