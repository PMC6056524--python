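"""Shared domain types for the multiregion tumor-heterogeneity pipeline.

Conventions used throughout the package:

* variant positions are 1-based (VCF convention); copy-number segments and
  chromosome-arm definitions are 0-based half-open (BED convention);
* per-case read counts live in dense ``(variant, sample)`` matrices — a
  missing cell is a data error, never an implicit zero;
* the matched normal is a single sample per case, so its counts are stored
  per variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "COHORTS",
    "STAGES",
    "EFFECTS",
    "CATEGORIES",
    "TREE_CATEGORIES",
    "SampleMeta",
    "VariantSite",
    "ReadCountMatrix",
    "CaseTable",
    "MultiregionProfile",
    "CnaSegment",
    "ArmDefinition",
    "ArmCall",
    "FocalLocus",
    "CorrectedCounts",
    "Hyperparameters",
    "McmcConfig",
    "FAST_MCMC",
    "PAPER_MCMC_COUNTS",
    "PAPER_MCMC_CNA_COUNTS",
    "PAPER_MCMC_VAF",
    "PAPER_MCMC_CCF",
    "is_sex_chromosome",
]

COHORTS = ("PCRC", "ACRC")
STAGES = ("adenoma", "carcinoma", "ACRC")
EFFECTS = (
    "non-synonymous SNV",
    "stop-gain SNV",
    "splicing SNV",
    "indel",
    "silent",
    "other",
)
#: possible functional classes a driver mutation may carry
FUNCTIONAL_EFFECTS = ("non-synonymous SNV", "stop-gain SNV", "splicing SNV", "indel")
CATEGORIES = ("ubiquitous", "shared", "private")
TREE_CATEGORIES = ("trunk", "internal_branch", "external_branch", "unassigned")


def is_sex_chromosome(chrom: str) -> bool:
    """True for X/Y with or without a ``chr`` prefix (case-insensitive)."""
    name = chrom.lower()
    if name.startswith("chr"):
        name = name[3:]
    return name in ("x", "y")


@dataclass(frozen=True)
class SampleMeta:
    """One multiregion tumor sample.

    ``stage`` is ``"ACRC"`` exactly when the sample comes from the advanced
    cohort; precancerous samples are ``"adenoma"`` or ``"carcinoma"``
    (mirroring the trailing "A"/"C" of the sample-name convention).
    """

    sample_id: str
    case_id: str
    cohort: str
    stage: str
    tumor_content: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if (self.stage == "ACRC") != (self.cohort == "ACRC"):
            raise ValueError(
                f"sample {self.sample_id}: stage {self.stage!r} is inconsistent "
                f"with cohort {self.cohort!r}"
            )
        if self.tumor_content is not None and not (0.0 < self.tumor_content <= 1.0):
            raise ValueError(
                f"sample {self.sample_id}: tumor_content must lie in (0, 1]"
            )


@dataclass(frozen=True)
class VariantSite:
    """A somatic variant locus shared across the samples of one case."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    effect: str = "other"
    is_driver: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.is_driver and self.effect not in FUNCTIONAL_EFFECTS:
            raise ValueError(
                f"{self.key()}: drivers must carry a possible functional class, "
                f"not {self.effect!r}"
            )

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class ReadCountMatrix:
    """Dense per-case read counts: tumor matrices plus the matched normal.

    Shapes: ``depth``/``alt_reads``/``caller_flag`` are ``(n_variants,
    n_samples)``; ``normal_depth``/``normal_alt_reads`` are ``(n_variants,)``
    because one normal serves the whole case.
    """

    depth: np.ndarray
    alt_reads: np.ndarray
    normal_depth: np.ndarray
    normal_alt_reads: np.ndarray
    caller_flag: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.alt_reads = np.asarray(self.alt_reads, dtype=np.int64)
        self.normal_depth = np.asarray(self.normal_depth, dtype=np.int64)
        self.normal_alt_reads = np.asarray(self.normal_alt_reads, dtype=np.int64)
        self.caller_flag = np.asarray(self.caller_flag, dtype=bool)
        if self.depth.shape != self.alt_reads.shape != self.caller_flag.shape:
            raise ValueError("tumor count matrices must share one shape")
        if np.any(self.depth < 0) or np.any(self.alt_reads < 0):
            raise ValueError("read counts must be non-negative")
        if np.any(self.alt_reads > self.depth):
            bad = np.argwhere(self.alt_reads > self.depth)[0]
            raise ValueError(
                f"variant reads exceed depth at (variant {bad[0]}, sample {bad[1]})"
            )
        if np.any(self.normal_alt_reads > self.normal_depth):
            bad = int(np.argmax(self.normal_alt_reads > self.normal_depth))
            raise ValueError(f"normal variant reads exceed depth at variant {bad}")

    @property
    def n_variants(self) -> int:
        return self.depth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.depth.shape[1]

    def vaf(self) -> np.ndarray:
        """Tumor VAF matrix; NaN where depth is zero (VAF undefined)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.alt_reads / self.depth
        return np.where(self.depth > 0, out, np.nan)

    def normal_vaf(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.normal_alt_reads / self.normal_depth
        return np.where(self.normal_depth > 0, out, np.nan)


@dataclass
class CaseTable:
    """Everything the variant table carries for one case."""

    samples: list  # of SampleMeta, column order of the matrices
    variants: list  # of VariantSite, row order of the matrices
    counts: ReadCountMatrix

    def __post_init__(self) -> None:
        if self.counts.depth.shape != (len(self.variants), len(self.samples)):
            raise ValueError("count matrix shape does not match sample/variant lists")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id within a case")
        keys = [v.key() for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant within a case")

    @property
    def case_id(self) -> str:
        return self.samples[0].case_id


@dataclass
class MultiregionProfile:
    """Per-case presence/VAF matrix with per-variant category labels."""

    case_id: str
    samples: list
    variants: list
    presence: np.ndarray  # bool (n_variants, n_samples)
    vaf: np.ndarray  # float (n_variants, n_samples)
    category: np.ndarray  # str, one of CATEGORIES
    tree_category: Optional[np.ndarray] = None  # str, one of TREE_CATEGORIES

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.vaf = np.asarray(self.vaf, dtype=float)
        self.category = np.asarray(self.category, dtype=object)
        if self.presence.shape != (len(self.variants), len(self.samples)):
            raise ValueError("presence matrix shape mismatch")
        if self.category.shape != (len(self.variants),):
            raise ValueError("category vector length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def category_counts(self) -> dict:
        return {c: int(np.sum(self.category == c)) for c in CATEGORIES}

    def effective_tree_category(self) -> np.ndarray:
        """Tree labels, falling back on the category correspondence
        ubiquitous→trunk, shared→internal branch, private→external branch."""
        fallback = {
            "ubiquitous": "trunk",
            "shared": "internal_branch",
            "private": "external_branch",
        }
        mapped = np.array([fallback[c] for c in self.category], dtype=object)
        if self.tree_category is None:
            return mapped
        out = np.asarray(self.tree_category, dtype=object).copy()
        out[out == "unassigned"] = mapped[out == "unassigned"]
        return out


@dataclass(frozen=True, order=True)
class CnaSegment:
    """One copy-number segment of one sample (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2r: float = field(compare=False)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"segment {self.sample_id}:{self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArmDefinition:
    """A chromosome arm interval (0-based half-open)."""

    arm_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"arm {self.arm_id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ArmCall:
    """Arm-level CNA status across the samples of one case."""

    arm_id: str
    sample_ids: list
    mean_log2r: np.ndarray  # per sample
    status: np.ndarray  # "gain" | "loss" | "none" per sample
    category: str = "absent"  # "ubiquitous" | "heterogeneous" | "absent"
    discordant: bool = False


@dataclass
class FocalLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    sample_ids: list
    mean_log2r: np.ndarray
    present: np.ndarray  # bool per sample


@dataclass(frozen=True)
class CorrectedCounts:
    """Downsampling-corrected alteration numbers for one case."""

    case_id: str
    k: int
    n_ubiquitous: float
    n_heterogeneous: float


@dataclass(frozen=True)
class Hyperparameters:
    """Fixed prior constants of the hierarchical Bayesian models.

    Defaults are the published constants: the group-mean hierarchy uses
    Cauchy(beta0, tau0) with a Half-Cauchy(lambda0) scale, and the residual
    hierarchy is anchored at ``r0`` with Half-Cauchy scale hyper-priors
    ``l0`` (case level), ``l1`` (sample level) and ``l2`` (mutation level,
    VAF/CCF models only). ``r0`` defaults to 1 as printed; setting it to 0
    removes the anchor shift (see docs/methods.md on identifiability).
    """

    beta0: float = 0.0
    tau0: float = 1.0
    lambda0: float = 1.0
    r0: float = 1.0
    l0: float = 1.0
    l1: float = 1.0
    l2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau0", "lambda0", "l0", "l1", "l2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"scale hyperparameter {name} must be > 0")


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.

    ``n_total`` follows the published convention of counting iterations after
    burn-in when the two numbers are equal, and overall iterations otherwise:
    retained iterations per chain = ``n_total - n_burnin`` if positive, else
    ``n_total``.
    """

    n_chains: int = 4
    n_burnin: int = 2000
    n_total: int = 4000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_burnin, self.n_total, self.thin) < 1:
            raise ValueError("MCMC settings must be positive integers")
        if self.n_retained < 100:
            raise ValueError(
                "fewer than 100 retained draws per chain after thinning; "
                "increase n_total or reduce thin"
            )

    @property
    def n_sampling(self) -> int:
        extra = self.n_total - self.n_burnin
        return extra if extra > 0 else self.n_total

    @property
    def n_retained(self) -> int:
        return self.n_sampling // self.thin

    def with_seed(self, seed: int) -> "McmcConfig":
        return replace(self, seed=int(seed))


#: scaled-down default used by tests and quick runs
FAST_MCMC = McmcConfig(n_chains=4, n_burnin=2000, n_total=4000, thin=1)
#: published chain settings, kept as named configs
PAPER_MCMC_COUNTS = McmcConfig(n_chains=20, n_burnin=100_000, n_total=200_000, thin=5)
PAPER_MCMC_CNA_COUNTS = McmcConfig(n_chains=20, n_burnin=50_000, n_total=100_000, thin=5)
PAPER_MCMC_VAF = McmcConfig(n_chains=20, n_burnin=50_000, n_total=50_000, thin=5)
PAPER_MCMC_CCF = McmcConfig(n_chains=20, n_burnin=200_000, n_total=200_000, thin=5)
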