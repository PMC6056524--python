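"""Downsampling correction of ubiquitous/heterogeneous alteration counts.

Cases contribute different numbers of samples, which biases raw counts: more
samples make "present in all" harder and "present in some" easier. The
correction enumerates every size-``k`` subset of a case's samples (``k`` = 4,
the smallest case size in the study design), recomputes both counts within
each subset, and reports medians:

* ubiquitous count of a subset = alterations present in all ``k`` samples
  (an alteration heterogeneous in the full case can be ubiquitous in a
  subset — the subset is treated as a self-contained case);
* heterogeneous count of a subset = the median over its ``k`` samples of the
  per-sample count of alterations present in that sample but not in all;
* the corrected values are the medians of these quantities over all
  C(J, k) subsets.

Enumeration is exhaustive (C(21, 4) = 5985 at the study maximum); medians use
the midpoint convention for even counts at both levels.
"""

from __future__ import annotations

from itertools import combinations
from typing import Union

import numpy as np

from .types import CorrectedCounts, MultiregionProfile

__all__ = ["corrected_alteration_counts", "corrected_shared_count", "subset_counts"]


def _presence_matrix(data) -> np.ndarray:
    if isinstance(data, MultiregionProfile):
        return data.presence
    arr = np.asarray(data)
    if arr.ndim != 2:
        raise ValueError("presence data must be a 2-D (alteration x sample) matrix")
    return arr.astype(bool)


def subset_counts(presence: np.ndarray, subset: tuple) -> tuple:
    """(ubiquitous count, per-sample-median heterogeneous count) within one
    sample subset, recomputed from scratch for the subset."""
    sub = presence[:, list(subset)]
    in_all = sub.all(axis=1)
    n_ubiq = int(in_all.sum())
    het_per_sample = (sub & ~in_all[:, None]).sum(axis=0)
    return n_ubiq, float(np.median(het_per_sample))


def corrected_alteration_counts(
    data: Union[np.ndarray, MultiregionProfile], k: int, case_id: str = ""
) -> CorrectedCounts:
    """Median-over-subsets corrected alteration counts for one case."""
    presence = _presence_matrix(data)
    n_samples = presence.shape[1]
    if isinstance(data, MultiregionProfile) and not case_id:
        case_id = data.case_id
    if k <= 0:
        raise ValueError("subset size k must be positive")
    if k > n_samples:
        raise ValueError(
            f"subset size k={k} exceeds the case's {n_samples} samples"
        )

    subs = np.array(list(combinations(range(n_samples), k)), dtype=np.intp)
    # (n_alterations, n_subsets, k) boolean tensor; small at study scale
    cube = presence[:, subs]
    in_all = cube.all(axis=2)
    ubiq = in_all.sum(axis=0)
    het = (cube & ~in_all[:, :, None]).sum(axis=0)
    het_median = np.median(het, axis=1)
    return CorrectedCounts(
        case_id=case_id,
        k=k,
        n_ubiquitous=float(np.median(ubiq)),
        n_heterogeneous=float(np.median(het_median)),
    )


def corrected_shared_count(
    data: Union[np.ndarray, MultiregionProfile], k: int
) -> float:
    """Median over size-``k`` subsets of the count of alterations present in
    at least two but not all of the subset's samples (the shared slice of the
    heterogeneous class, corrected the same way)."""
    presence = _presence_matrix(data)
    n_samples = presence.shape[1]
    if k <= 0 or k > n_samples:
        raise ValueError("invalid subset size k")
    subs = np.array(list(combinations(range(n_samples), k)), dtype=np.intp)
    cube = presence[:, subs]
    n_present = cube.sum(axis=2)
    shared = ((n_present >= 2) & (n_present < k)).sum(axis=0)
    return float(np.median(shared))
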