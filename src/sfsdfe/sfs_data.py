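"""Domain types and file I/O for polarised site-frequency spectrum data.

The on-disk SFS format is a small TSV dialect:

    #n=<int>
    #m <region_label>=<float>        (one line per region)
    region<TAB>type<TAB>i<TAB>count  (type in {snp, ins, del}; 1 <= i <= n-1)

``i`` is the derived-allele copy number; ``i = 0`` and ``i = n`` are invalid
because the likelihood only uses polymorphic sites.  Missing frequency
classes are zero-filled on read (low-rate simulated spectra legitimately
contain empty bins).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

logger = logging.getLogger(__name__)

VARIANT_TYPES = ("snp", "ins", "del")

__all__ = [
    "SampleFrame",
    "PolarisedSFS",
    "PolarisedSFSSet",
    "SiteClassParams",
    "ContinuousTypeParams",
    "DemographyNuisance",
    "TypeModel",
    "RatioConstraint",
    "ModelSpec",
    "FitResult",
    "SFSFormatError",
    "SFSValidationError",
    "read_sfs_file",
    "write_sfs_file",
    "build_sfs_from_variant_table",
    "read_model_config",
    "model_spec_from_dict",
]


class SFSFormatError(ValueError):
    """Malformed SFS or config file (missing headers, bad syntax)."""


class SFSValidationError(ValueError):
    """Structurally parseable input that violates a model invariant."""


@dataclass(frozen=True)
class SampleFrame:
    """Sampling frame of one region: n sequenced alleles over m callable sites.

    ``m`` may be non-integer (callable-site averages after filtering).
    """

    n: int
    m: float
    region_label: str = "selected"

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 3):
            raise SFSValidationError(f"sample size n must be an integer >= 3, got {self.n!r}")
        if not (self.m > 0 and math.isfinite(self.m)):
            raise SFSValidationError(f"callable-site count m must be positive, got {self.m!r}")


@dataclass(frozen=True)
class PolarisedSFS:
    """Observed derived-allele-count spectrum x_1..x_{n-1} for one variant type.

    Counts are stored as floats so that noise-free expected spectra can be
    passed through the likelihood machinery; file I/O enforces integers.
    """

    frame: SampleFrame
    variant_type: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.variant_type not in VARIANT_TYPES:
            raise SFSValidationError(
                f"variant_type must be one of {VARIANT_TYPES}, got {self.variant_type!r}"
            )
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.shape != (self.frame.n - 1,):
            raise SFSValidationError(
                f"counts must have n-1 = {self.frame.n - 1} entries, got {c.shape}"
            )
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise SFSValidationError("counts must be finite and non-negative")
        if c.sum() > self.frame.m:
            raise SFSValidationError(
                f"total polymorphic sites ({c.sum()}) exceeds callable sites m={self.frame.m}"
            )

    @property
    def segregating_sites(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class PolarisedSFSSet:
    """Collection of spectra keyed by (region_label, variant_type).

    All entries share one sample size n; entries within a region share the
    region's SampleFrame.
    """

    entries: dict[tuple[str, str], PolarisedSFS]

    def __post_init__(self) -> None:
        if not self.entries:
            raise SFSValidationError("empty SFS set")
        n_values = set()
        frames: dict[str, SampleFrame] = {}
        for (region, vtype), sfs in self.entries.items():
            if sfs.variant_type != vtype:
                raise SFSValidationError(f"key {vtype!r} does not match entry type {sfs.variant_type!r}")
            if sfs.frame.region_label != region:
                raise SFSValidationError(
                    f"key {region!r} does not match frame label {sfs.frame.region_label!r}"
                )
            n_values.add(sfs.frame.n)
            prev = frames.setdefault(region, sfs.frame)
            if prev != sfs.frame:
                raise SFSValidationError(f"entries of region {region!r} disagree on the SampleFrame")
        if len(n_values) != 1:
            raise SFSValidationError(f"all entries must share one sample size, got {sorted(n_values)}")

    @property
    def n(self) -> int:
        return next(iter(self.entries.values())).frame.n

    def frame(self, region: str) -> SampleFrame:
        for (r, _), sfs in self.entries.items():
            if r == region:
                return sfs.frame
        raise KeyError(f"no entries for region {region!r}")

    def regions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for region, _ in self.entries:
            if region not in seen:
                seen.append(region)
        return tuple(seen)

    def __getitem__(self, key: tuple[str, str]) -> PolarisedSFS:
        return self.entries[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries


# ---------------------------------------------------------------------------
# model parameter containers

@dataclass(frozen=True)
class SiteClassParams:
    """(theta, gamma, epsilon) of one discrete site class.

    theta = 4*Ne*u per site; gamma = 4*Ne*s (negative = deleterious);
    epsilon = probability the ancestral state is misidentified.  epsilon is
    bounded at 0.5 because beyond it the parameter is aliased with swapping
    the ancestral/derived labels.
    """

    theta: float
    gamma: float
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not (self.theta >= 0 and math.isfinite(self.theta)):
            raise SFSValidationError(f"theta must be >= 0, got {self.theta}")
        if not math.isfinite(self.gamma):
            raise SFSValidationError(f"gamma must be finite, got {self.gamma}")
        if not (0.0 <= self.epsilon <= 0.5):
            raise SFSValidationError(f"epsilon must lie in [0, 0.5], got {self.epsilon}")


@dataclass(frozen=True)
class ContinuousTypeParams:
    """Per-type parameters of the continuous (reflected-Gamma DFE) model."""

    theta: float
    epsilon: float
    dfe: "object"  # GammaDFE; imported lazily to keep module layers clean

    def __post_init__(self) -> None:
        if not (self.theta >= 0 and math.isfinite(self.theta)):
            raise SFSValidationError(f"theta must be >= 0, got {self.theta}")
        if not (0.0 <= self.epsilon <= 0.5):
            raise SFSValidationError(f"epsilon must lie in [0, 0.5], got {self.epsilon}")


@dataclass(frozen=True)
class DemographyNuisance:
    """Frequency-class distortion multipliers r_2..r_{n-1}; r_1 is fixed at 1.

    A single instance is shared by every variant type and region of a joint
    model, which is what lets it absorb demography and linked selection
    without confounding the selection parameters.
    """

    r: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        if r.ndim != 1:
            raise SFSValidationError("r must be a 1-D vector")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise SFSValidationError("all r_i must be positive and finite")

    @classmethod
    def ones(cls, n: int) -> "DemographyNuisance":
        return cls(r=np.ones(n - 2))


# ---------------------------------------------------------------------------
# model specification

_ERROR_MODELS = ("free", "shared", "zero")
_DFE_FORMS = ("discrete", "continuous")


@dataclass(frozen=True)
class TypeModel:
    """DFE form and error model for one variant type."""

    dfe: str = "discrete"
    n_classes: int = 1
    error_model: str = "free"

    def __post_init__(self) -> None:
        if self.dfe not in _DFE_FORMS:
            raise SFSValidationError(f"dfe must be one of {_DFE_FORMS}, got {self.dfe!r}")
        if self.dfe == "discrete" and self.n_classes < 1:
            raise SFSValidationError("a discrete DFE needs at least one site class")
        if self.error_model not in _ERROR_MODELS:
            raise SFSValidationError(
                f"error_model must be one of {_ERROR_MODELS}, got {self.error_model!r}"
            )


@dataclass(frozen=True)
class RatioConstraint:
    """Fix one theta as a multiple of the sum of others.

    value[numerator] = ratio * sum(value[d] for d in denominators); the
    numerator parameter is removed from the free-parameter vector.
    """

    numerator: str
    denominators: tuple[str, ...]
    ratio: float

    def __post_init__(self) -> None:
        if isinstance(self.denominators, str):
            object.__setattr__(self, "denominators", (self.denominators,))
        else:
            object.__setattr__(self, "denominators", tuple(self.denominators))
        if not (self.ratio > 0 and math.isfinite(self.ratio)):
            raise SFSValidationError(f"ratio must be positive, got {self.ratio}")
        if self.numerator in self.denominators:
            raise SFSValidationError("a constraint cannot reference its own target")


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit: DFE forms, error models, demography, constraints."""

    types: dict[str, TypeModel]
    demography: bool = False
    neutral_types: tuple[str, ...] = ()
    ratio_constraints: tuple[RatioConstraint, ...] = ()
    share_epsilon_across_types: bool = False
    selected_region: str = "selected"
    neutral_region: str = "neutral"

    def __post_init__(self) -> None:
        object.__setattr__(self, "neutral_types", tuple(self.neutral_types))
        object.__setattr__(self, "ratio_constraints", tuple(self.ratio_constraints))
        for t in self.types:
            if t not in VARIANT_TYPES:
                raise SFSValidationError(f"unknown variant type {t!r}")
        for t in self.neutral_types:
            if t not in VARIANT_TYPES:
                raise SFSValidationError(f"unknown neutral variant type {t!r}")
        if ("ins" in self.types) != ("del" in self.types):
            raise SFSValidationError(
                "insertions and deletions must be modelled jointly (their spectra "
                "cross-contaminate under polarisation error)"
            )
        if ("ins" in self.neutral_types) != ("del" in self.neutral_types):
            raise SFSValidationError("neutral insertions and deletions must appear together")
        if not self.types:
            raise SFSValidationError("at least one variant type must be modelled")
        if self.demography and not self.neutral_types:
            raise SFSValidationError("demography correction requires a neutral reference")

    @property
    def has_neutral(self) -> bool:
        return bool(self.neutral_types)

    def selected_param_ids(self) -> list[str]:
        ids: list[str] = []
        for t in VARIANT_TYPES:
            tm = self.types.get(t)
            if tm is None:
                continue
            if tm.dfe == "discrete":
                for c in range(1, tm.n_classes + 1):
                    ids += [f"{t}.class{c}.theta", f"{t}.class{c}.gamma", f"{t}.class{c}.epsilon"]
            else:
                ids += [f"{t}.theta", f"{t}.shape", f"{t}.scale", f"{t}.epsilon"]
        return ids

    def neutral_param_ids(self) -> list[str]:
        ids: list[str] = []
        for t in VARIANT_TYPES:
            if t in self.neutral_types:
                ids += [f"{t}.neutral.theta", f"{t}.neutral.epsilon"]
        return ids

    def param_ids(self, n: int | None = None) -> list[str]:
        """All structural parameter ids; r ids require the sample size."""
        ids = self.selected_param_ids() + self.neutral_param_ids()
        if self.demography:
            if n is None:
                raise SFSValidationError("sample size n is needed to enumerate r parameters")
            ids += [f"r.{i}" for i in range(2, n)]
        return ids

    def epsilon_ties(self) -> dict[str, str]:
        """Map of epsilon ids that are copies of another (shared error model)."""
        ties: dict[str, str] = {}
        leaders: list[str] = []
        for t in VARIANT_TYPES:
            tm = self.types.get(t)
            if tm is None or tm.error_model != "shared":
                continue
            if tm.dfe == "discrete":
                leader = f"{t}.class1.epsilon"
                for c in range(2, tm.n_classes + 1):
                    ties[f"{t}.class{c}.epsilon"] = leader
            else:
                leader = f"{t}.epsilon"
            leaders.append(leader)
        if self.share_epsilon_across_types and len(leaders) > 1:
            for extra in leaders[1:]:
                ties[extra] = leaders[0]
        return ties

    def fixed_params(self) -> dict[str, float]:
        fixed: dict[str, float] = {}
        for t in VARIANT_TYPES:
            tm = self.types.get(t)
            if tm is None or tm.error_model != "zero":
                continue
            if tm.dfe == "discrete":
                for c in range(1, tm.n_classes + 1):
                    fixed[f"{t}.class{c}.epsilon"] = 0.0
            else:
                fixed[f"{t}.epsilon"] = 0.0
        return fixed

    def free_param_ids(self, n: int | None = None) -> list[str]:
        ids = self.param_ids(n)
        ties = self.epsilon_ties()
        fixed = self.fixed_params()
        derived = {rc.numerator for rc in self.ratio_constraints}
        for rc in self.ratio_constraints:
            missing = [p for p in (rc.numerator, *rc.denominators) if p not in ids]
            if missing:
                raise SFSValidationError(f"ratio constraint references unknown parameters: {missing}")
            if set(rc.denominators) & derived:
                raise SFSValidationError("chained ratio constraints are not supported (cycle risk)")
        return [p for p in ids if p not in ties and p not in fixed and p not in derived]

    def free_param_count(self, n: int | None = None) -> int:
        return len(self.free_param_ids(n))


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one ModelSpec to one data set."""

    spec: ModelSpec
    params: dict[str, float]
    loglik: float
    k: int
    n_starts: int
    converged: bool
    start_logliks: tuple[float, ...] = ()
    best_start: int = 0
    seed: int | None = None


# ---------------------------------------------------------------------------
# SFS file I/O

def _type_order(vtype: str) -> int:
    return VARIANT_TYPES.index(vtype)


def read_sfs_file(path) -> PolarisedSFSSet:
    """Read the TSV SFS dialect; densifies missing frequency classes with 0."""
    n: int | None = None
    m_by_region: dict[str, float] = {}
    rows: dict[tuple[str, str], dict[int, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("n="):
                    try:
                        n = int(body[2:])
                    except ValueError as exc:
                        raise SFSFormatError(f"{path}:{lineno}: bad n header {line!r}") from exc
                elif body.startswith("m "):
                    try:
                        label, value = body[2:].split("=", 1)
                        m_by_region[label.strip()] = float(value)
                    except ValueError as exc:
                        raise SFSFormatError(f"{path}:{lineno}: bad m header {line!r}") from exc
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise SFSFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            region, vtype, i_str, count_str = parts
            try:
                i, count = int(i_str), int(count_str)
            except ValueError as exc:
                raise SFSFormatError(f"{path}:{lineno}: non-integer i or count") from exc
            if n is None:
                raise SFSFormatError(f"{path}: data row before the #n= header")
            if vtype not in VARIANT_TYPES:
                raise SFSValidationError(f"{path}:{lineno}: unknown variant type {vtype!r}")
            if not (1 <= i <= n - 1):
                raise SFSValidationError(
                    f"{path}:{lineno}: i={i} outside the polymorphic range [1, {n - 1}]"
                )
            if count < 0:
                raise SFSValidationError(f"{path}:{lineno}: negative count")
            bucket = rows.setdefault((region, vtype), {})
            if i in bucket:
                raise SFSValidationError(f"{path}:{lineno}: duplicate entry for ({region}, {vtype}, {i})")
            bucket[i] = count
    if n is None:
        raise SFSFormatError(f"{path}: missing #n= header")
    if not rows:
        raise SFSFormatError(f"{path}: no data rows")
    entries: dict[tuple[str, str], PolarisedSFS] = {}
    for (region, vtype), bucket in rows.items():
        if region not in m_by_region:
            raise SFSFormatError(f"{path}: missing '#m {region}=' header")
        counts = np.zeros(n - 1)
        for i, c in bucket.items():
            counts[i - 1] = c
        frame = SampleFrame(n=n, m=m_by_region[region], region_label=region)
        entries[(region, vtype)] = PolarisedSFS(frame=frame, variant_type=vtype, counts=counts)
    return PolarisedSFSSet(entries=entries)


def write_sfs_file(sfs_set: PolarisedSFSSet, path) -> None:
    """Write the TSV dialect with stable (region, type, i) ordering."""
    n = sfs_set.n
    keys = sorted(sfs_set.entries, key=lambda k: (k[0], _type_order(k[1])))
    regions = sorted({r for r, _ in keys})
    with open(path, "w") as fh:
        fh.write(f"#n={n}\n")
        for region in regions:
            fh.write(f"#m {region}={sfs_set.frame(region).m!r}\n")
        for key in keys:
            sfs = sfs_set.entries[key]
            counts = sfs.counts
            if not np.allclose(counts, np.round(counts)):
                raise SFSValidationError(
                    f"entry {key} has non-integer counts; only observed spectra can be written"
                )
            for i, c in enumerate(counts, 1):
                fh.write(f"{key[0]}\t{key[1]}\t{i}\t{int(round(c))}\n")


def build_sfs_from_variant_table(table, n: int, m_by_region: dict[str, float]) -> PolarisedSFSSet:
    """Tally a polarised variant table into spectra.

    ``table`` is an iterable of (region_label, variant_type, derived_count)
    rows (or a DataFrame with those columns, in order).  Rows with derived
    count 0 or n are monomorphic in the sample and dropped with a warning.
    """
    try:
        iterator = table.itertuples(index=False)
    except AttributeError:
        iterator = iter(table)
    tallies: dict[tuple[str, str], np.ndarray] = {}
    dropped = 0
    for row in iterator:
        region, vtype, i = row[0], row[1], int(row[2])
        if vtype not in VARIANT_TYPES:
            raise SFSValidationError(f"unknown variant type {vtype!r}")
        if i < 0 or i > n:
            raise SFSValidationError(f"derived count {i} outside [0, n={n}]")
        if i == 0 or i == n:
            dropped += 1
            continue
        counts = tallies.setdefault((region, vtype), np.zeros(n - 1))
        counts[i - 1] += 1
    if dropped:
        logger.warning("dropped %d monomorphic rows (derived count 0 or n)", dropped)
    if not tallies:
        raise SFSValidationError("variant table contains no polymorphic rows")
    entries = {}
    for (region, vtype), counts in tallies.items():
        if region not in m_by_region:
            raise SFSValidationError(f"no callable-site count m for region {region!r}")
        frame = SampleFrame(n=n, m=m_by_region[region], region_label=region)
        entries[(region, vtype)] = PolarisedSFS(frame=frame, variant_type=vtype, counts=counts)
    return PolarisedSFSSet(entries=entries)


# ---------------------------------------------------------------------------
# model configuration files

_MODEL_KEYS = {
    "types", "demography", "neutral_types", "ratio_constraints",
    "share_epsilon_across_types", "selected_region", "neutral_region",
}
_TYPE_KEYS = {"dfe", "classes", "error"}
_CONSTRAINT_KEYS = {"numerator", "denominator", "ratio"}


def model_spec_from_dict(cfg: dict) -> ModelSpec:
    """Build a validated ModelSpec from a plain (YAML-derived) dict."""
    unknown = set(cfg) - _MODEL_KEYS
    if unknown:
        raise SFSFormatError(f"unknown model config keys: {sorted(unknown)}")
    if "types" not in cfg:
        raise SFSFormatError("model config must declare 'types'")
    types: dict[str, TypeModel] = {}
    for t, tc in cfg["types"].items():
        tc = dict(tc or {})
        unknown = set(tc) - _TYPE_KEYS
        if unknown:
            raise SFSFormatError(f"unknown keys for type {t!r}: {sorted(unknown)}")
        types[t] = TypeModel(
            dfe=tc.get("dfe", "discrete"),
            n_classes=int(tc.get("classes", 1)),
            error_model=tc.get("error", "free"),
        )
    constraints = []
    for rc in cfg.get("ratio_constraints", []) or []:
        unknown = set(rc) - _CONSTRAINT_KEYS
        if unknown:
            raise SFSFormatError(f"unknown ratio-constraint keys: {sorted(unknown)}")
        denom = rc["denominator"]
        if isinstance(denom, str):
            denom = (denom,)
        constraints.append(
            RatioConstraint(numerator=rc["numerator"], denominators=tuple(denom), ratio=float(rc["ratio"]))
        )
    return ModelSpec(
        types=types,
        demography=bool(cfg.get("demography", False)),
        neutral_types=tuple(cfg.get("neutral_types", []) or []),
        ratio_constraints=tuple(constraints),
        share_epsilon_across_types=bool(cfg.get("share_epsilon_across_types", False)),
        selected_region=cfg.get("selected_region", "selected"),
        neutral_region=cfg.get("neutral_region", "neutral"),
    )


def read_model_config(path) -> ModelSpec:
    """Read the ``model:`` block of a YAML config file into a ModelSpec.

    If the file carries a top-level ``n``, the free-parameter count is
    validated (and logged) against it; other top-level blocks (``options``,
    ``truth``, ``study``) belong to the CLI layer and are ignored here.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "model" not in doc:
        raise SFSFormatError(f"{path}: config must contain a 'model' block")
    spec = model_spec_from_dict(doc["model"])
    n = doc.get("n")
    k = spec.free_param_count(int(n) if n is not None else None) if (n or not spec.demography) else None
    if k is not None:
        logger.info("model config %s: %d free parameters", path, k)
    return spec
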