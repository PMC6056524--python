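"""Frequentist comparisons: driver trunk/branch enrichment, rank tests, and
six-class mutation spectra."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .types import MultiregionProfile, SampleMeta, VariantSite

__all__ = [
    "ContingencyTable2x2",
    "SpectrumProfile",
    "fisher_exact_two_sided",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "spectrum",
    "driver_trunk_branch_table",
    "SUBSTITUTION_CLASSES",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = cohorts, columns = (branch, trunk) driver-mutation counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p: the sum over all tables with the observed
    margins whose point hypergeometric probability does not exceed the
    observed table's (the sum-of-small-p convention)."""
    if isinstance(table, ContingencyTable2x2):
        table = table.as_array()
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0):
        raise ValueError("contingency cells must be non-negative")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def wilcoxon_rank_sum(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Convention: the exact null distribution when the samples are small and
    tie-free, otherwise the normal approximation with continuity correction
    (scipy's ``auto`` rule, fixed here as the package's convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not len(x) or not len(y):
        raise ValueError("both groups need at least one observation")
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_signed_rank(x, y=None, method: str = "auto") -> float:
    """Two-sided Wilcoxon signed-rank p for paired data (or differences)."""
    x = np.asarray(x, dtype=float)
    diffs = x - np.asarray(y, dtype=float) if y is not None else x
    if not len(diffs):
        raise ValueError("need at least one pair")
    if np.all(diffs == 0):
        raise ValueError("all paired differences are zero; test undefined")
    return float(sps.wilcoxon(diffs, alternative="two-sided", method=method).pvalue)


@dataclass
class SpectrumProfile:
    """Fractions of the six pyrimidine-context substitution classes plus the
    indel fraction, over the variants that could be classified."""

    fractions: Dict[str, float]
    n_classified: int
    n_excluded: int

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.fractions[c] for c in SUBSTITUTION_CLASSES + ("indel",)]
        )


def _classify(ref: str, alt: str) -> Optional[str]:
    if len(ref) != len(alt) or len(ref) != 1:
        return "indel"
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    if ref in ("G", "A"):  # collapse to the pyrimidine-reference strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def spectrum(variants: Iterable) -> SpectrumProfile:
    """Mutation spectrum of a variant set.

    Accepts :class:`VariantSite` records or plain ``(ref, alt)`` pairs.
    Substitutions collapse to the pyrimidine reference context (G>T counts
    as C>A, and so on); length-changing alleles count as indels; non-ACGT
    substitution alleles are excluded and tallied in ``n_excluded``.
    """
    counts = {c: 0 for c in SUBSTITUTION_CLASSES + ("indel",)}
    excluded = 0
    total = 0
    for v in variants:
        ref, alt = (v.ref, v.alt) if isinstance(v, VariantSite) else (v[0], v[1])
        cls = _classify(ref, alt)
        if cls is None:
            excluded += 1
            continue
        counts[cls] += 1
        total += 1
    fractions = {c: (counts[c] / total if total else 0.0) for c in counts}
    return SpectrumProfile(fractions=fractions, n_classified=total, n_excluded=excluded)


def driver_trunk_branch_table(
    profiles_by_cohort: Dict[str, Sequence[MultiregionProfile]]
) -> ContingencyTable2x2:
    """Branch/trunk driver-mutation counts per cohort (rows PCRC, ACRC;
    columns branch, trunk). Drivers are counted per mutation; tree labels
    fall back on the ubiquitous->trunk correspondence where unannotated."""
    cells = {}
    for cohort in ("PCRC", "ACRC"):
        branch = trunk = 0
        for prof in profiles_by_cohort.get(cohort, []):
            tree = prof.effective_tree_category()
            for i, v in enumerate(prof.variants):
                if not v.is_driver:
                    continue
                if tree[i] == "trunk":
                    trunk += 1
                else:
                    branch += 1
        cells[cohort] = (branch, trunk)
    return ContingencyTable2x2(
        a=cells["PCRC"][0], b=cells["PCRC"][1], c=cells["ACRC"][0], d=cells["ACRC"][1]
    )
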