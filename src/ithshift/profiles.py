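"""Multiregion mutation profiles: admission, rescue, categorization, display
ordering, PCA sample colors, and tumor-content estimation.

A variant enters a case's profile when the upstream caller flagged it somatic
in at least one sample and every sample covers the position with strictly
more than ``min_depth_all_samples`` reads. In samples where the caller missed
it, presence can be rescued when the tumor VAF, the matched-normal VAF and a
Fisher's exact test on tumor-vs-normal read counts all pass their thresholds.
Variants present in every sample are ubiquitous; in several but not all,
shared; in exactly one, private.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import fisher_exact
from sklearn.decomposition import PCA

from .types import CaseTable, MultiregionProfile, ReadCountMatrix, VariantSite

__all__ = [
    "RescueThresholds",
    "admit_variants",
    "rescue_presence",
    "build_profile",
    "categorize",
    "order_for_heatmap",
    "pca_sample_colors",
    "estimate_tumor_content",
    "write_profile_table",
    "read_profile_table",
    "mark_drivers",
]


@dataclass(frozen=True)
class RescueThresholds:
    """Thresholds of the false-negative rescue step.

    ``min_depth_all_samples`` is exclusive: admission requires strictly more
    reads than this in every sample. The Fisher test is one-sided by default
    (enrichment of variant reads in the tumor); set
    ``fisher_alternative="two-sided"`` to change the convention.
    """

    min_tumor_vaf: float = 0.05
    max_normal_vaf: float = 0.01
    fisher_p_max: float = 0.05
    min_depth_all_samples: int = 10
    fisher_alternative: str = "greater"

    def __post_init__(self) -> None:
        if not 0 < self.min_tumor_vaf < 1:
            raise ValueError("min_tumor_vaf must lie in (0, 1)")
        if not 0 < self.fisher_p_max < 1:
            raise ValueError("fisher_p_max must lie in (0, 1)")


def admit_variants(
    counts: ReadCountMatrix, thresholds: RescueThresholds = RescueThresholds()
) -> np.ndarray:
    """Boolean mask of variants admitted to the profile.

    Admission: caller flag in >= 1 sample AND depth strictly greater than
    ``min_depth_all_samples`` in every sample of the case.
    """
    if counts.n_samples == 0:
        raise ValueError("case has zero samples")
    flagged = counts.caller_flag.any(axis=1)
    covered = (counts.depth > thresholds.min_depth_all_samples).all(axis=1)
    return flagged & covered


def rescue_presence(
    variant_idx: int,
    sample_idx: int,
    counts: ReadCountMatrix,
    thresholds: RescueThresholds = RescueThresholds(),
) -> bool:
    """Re-examine one (variant, sample) cell the caller left negative."""
    d = int(counts.depth[variant_idx, sample_idx])
    b = int(counts.alt_reads[variant_idx, sample_idx])
    if d == 0:  # VAF undefined: criterion (i) cannot hold
        return False
    if b / d < thresholds.min_tumor_vaf:
        return False
    nd = int(counts.normal_depth[variant_idx])
    nb = int(counts.normal_alt_reads[variant_idx])
    if nd > 0 and nb / nd > thresholds.max_normal_vaf:
        return False
    _, p = fisher_exact(
        [[b, d - b], [nb, nd - nb]], alternative=thresholds.fisher_alternative
    )
    return bool(p <= thresholds.fisher_p_max)


def build_profile(
    table: CaseTable, thresholds: RescueThresholds = RescueThresholds()
) -> MultiregionProfile:
    """Admission + rescue + categorization for one case."""
    counts = table.counts
    keep = admit_variants(counts, thresholds)
    idx = np.flatnonzero(keep)
    variants = [table.variants[i] for i in idx]
    presence = counts.caller_flag[idx].copy()
    vaf = counts.vaf()[idx]
    for row, i in enumerate(idx):
        for j in range(counts.n_samples):
            if not presence[row, j] and rescue_presence(i, j, counts, thresholds):
                presence[row, j] = True
    if len(idx) and not presence.any(axis=1).all():
        # cannot happen when admission requires a caller flag somewhere
        raise ValueError("admitted variant present in zero samples")
    profile = MultiregionProfile(
        case_id=table.case_id,
        samples=list(table.samples),
        variants=variants,
        presence=presence,
        vaf=np.where(presence, np.nan_to_num(vaf), 0.0),
        category=np.empty(len(variants), dtype=object),
    )
    return categorize(profile)


def categorize(profile: MultiregionProfile) -> MultiregionProfile:
    """Assign ubiquitous / shared / private from the presence matrix."""
    n_present = profile.presence.sum(axis=1)
    if np.any(n_present == 0):
        raise ValueError("variant present in zero samples cannot be categorized")
    cat = np.where(
        n_present == profile.n_samples,
        "ubiquitous",
        np.where(n_present == 1, "private", "shared"),
    )
    profile.category = cat.astype(object)
    return profile


def _chrom_rank(chrom: str) -> Tuple[int, str]:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (int(name), "")
    return ({"X": 23, "Y": 24, "M": 25, "MT": 25}.get(name.upper(), 26), name)


def order_for_heatmap(profile: MultiregionProfile) -> np.ndarray:
    """Display order: ubiquitous by genomic position; shared by average-linkage
    hierarchical clustering of presence rows; private by (sample, VAF desc)."""
    genome_key = [
        (_chrom_rank(v.chrom), v.pos, v.ref, v.alt) for v in profile.variants
    ]
    blocks: List[np.ndarray] = []

    ubiq = np.flatnonzero(profile.category == "ubiquitous")
    blocks.append(np.array(sorted(ubiq, key=lambda i: genome_key[i]), dtype=np.intp))

    shared = np.flatnonzero(profile.category == "shared")
    if len(shared) > 2:
        z = linkage(profile.presence[shared].astype(float), method="average",
                    metric="euclidean")
        blocks.append(shared[leaves_list(z)])
    else:
        blocks.append(shared)

    private = np.flatnonzero(profile.category == "private")
    if len(private):
        owner = profile.presence[private].argmax(axis=1)
        own_vaf = profile.vaf[private, owner]
        order = np.lexsort((-own_vaf, owner))
        blocks.append(private[order])
    else:
        blocks.append(private)

    return np.concatenate([b.astype(np.intp) for b in blocks])


def pca_sample_colors(profile: MultiregionProfile) -> Dict[str, Tuple[float, float, float]]:
    """RGB per sample from the first three principal components of the VAF
    profile, each component min-max rescaled to [0, 1] across the case's
    samples. Components the data cannot support (fewer than three samples, or
    zero variance) are fixed at 0.5 so identical profiles share one color."""
    x = np.where(profile.presence, profile.vaf, 0.0)  # samples are rows
    x = x.T
    m = x.shape[0]
    rgb = np.full((m, 3), 0.5)
    n_comp = min(3, m, x.shape[1]) if x.size else 0
    if n_comp >= 1 and m >= 2:
        scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
        for c in range(n_comp):
            col = scores[:, c]
            span = col.max() - col.min()
            if span > 1e-12:
                rgb[:, c] = (col - col.min()) / span
    return {
        s.sample_id: (float(r), float(g), float(b))
        for s, (r, g, b) in zip(profile.samples, rgb)
    }


def estimate_tumor_content(profile: MultiregionProfile, sample_id: str) -> float:
    """Cellularity estimate: twice the median ubiquitous VAF, capped at 1."""
    j = [s.sample_id for s in profile.samples].index(sample_id)
    ubiq = profile.category == "ubiquitous"
    vals = profile.vaf[ubiq, j]
    vals = vals[np.isfinite(vals)]
    if not len(vals):
        raise ValueError(
            f"sample {sample_id}: no ubiquitous variants with coverage; "
            "supply tumor content explicitly via sample metadata"
        )
    return min(1.0, 2.0 * float(np.median(vals)))


def mark_drivers(profile: MultiregionProfile, driver_genes) -> MultiregionProfile:
    """Flag variants on configured driver genes with a functional class."""
    from dataclasses import replace

    drivers = set(driver_genes)
    functional = {"non-synonymous SNV", "stop-gain SNV", "splicing SNV", "indel"}
    profile.variants = [
        replace(v, is_driver=(v.gene in drivers and v.effect in functional))
        for v in profile.variants
    ]
    return profile


# ---------------------------------------------------------------------------
# profile TSV (variant key, category, per-sample presence and VAF)


def write_profile_table(profile: MultiregionProfile, path) -> None:
    order = order_for_heatmap(profile)
    sample_ids = [s.sample_id for s in profile.samples]
    rows = []
    tree = profile.effective_tree_category()
    for i in order:
        v = profile.variants[i]
        row = {
            "case_id": profile.case_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "effect": v.effect,
            "is_driver": int(v.is_driver),
            "category": profile.category[i],
            "tree_category": tree[i],
        }
        for j, sid in enumerate(sample_ids):
            row[f"present:{sid}"] = int(profile.presence[i, j])
            row[f"vaf:{sid}"] = round(float(profile.vaf[i, j]), 6)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profile_table(path, samples) -> MultiregionProfile:
    """Rebuild a profile from its TSV; ``samples`` supplies the SampleMeta
    (the TSV stores only per-sample columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str},
                     keep_default_na=False, na_values=[])
    sample_ids = [s.sample_id for s in samples]
    variants = [
        VariantSite(
            chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
            gene=str(r.gene), effect=str(r.effect), is_driver=bool(int(r.is_driver)),
        )
        for r in df.itertuples(index=False)
    ]
    presence = df[[f"present:{s}" for s in sample_ids]].to_numpy(dtype=bool)
    vaf = df[[f"vaf:{s}" for s in sample_ids]].to_numpy(dtype=float)
    prof = MultiregionProfile(
        case_id=str(df["case_id"].iloc[0]) if len(df) else "",
        samples=list(samples),
        variants=variants,
        presence=presence,
        vaf=vaf,
        category=df["category"].to_numpy(dtype=object),
        tree_category=df["tree_category"].to_numpy(dtype=object),
    )
    return prof
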