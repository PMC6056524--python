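"""Synthetic multiregion whole-exome-like cohorts with known clonal truth.

Each simulated case is a small clone tree: a trunk clone present in every
region at cancer cell fraction (CCF) 1, a few subclones spanning contiguous
subsets of regions, and per-region private mutations. Observed variant reads
follow the measurement model the downstream Bayesian analysis assumes: the
expected VAF of a mutation with CCF ``C`` at local copy number ``CN`` in a
sample of tumor content ``TC`` is ``TC*C / ((1-TC)*2 + TC*CN)`` (mutant
multiplicity one); depths are over-dispersed (negative binomial) around the
study-like mean of 132x, and variant reads are Binomial draws at the
expected VAF plus a small error rate. Copy-number segments carry
``log2R = log2(((1-TC)*2 + TC*CN)/2)`` plus Gaussian noise.

Two regimes contrast the evolutionary modes the analysis is meant to
separate. ``darwinian`` places two or more subclones at high CCF carrying
driver-flagged shared mutations (selective sweeps in progress); ``neutral``
keeps shared clones rare and low-CCF and concentrates heterogeneity in
low-CCF private mutations. By default the precancerous (PCRC) cohort is
generated under the darwinian regime and the advanced (ACRC) cohort under
the neutral regime, so every downstream contrast has a known ground truth.

What the generator does not emulate: spatial geometry of regions, mutational
signatures beyond a crude C>T bias, germline contamination beyond a flat
error rate, and subclonal copy-number states (a subclone's CNA is clonal
within the regions that carry it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (
    read_arm_definitions,
    write_sample_metadata,
    write_segments,
    write_variant_table,
)
from .models import expected_vaf_from_ccf
from .types import (
    ArmDefinition,
    CaseTable,
    CnaSegment,
    ReadCountMatrix,
    SampleMeta,
    VariantSite,
    is_sex_chromosome,
)

__all__ = ["SimConfig", "SyntheticTruth", "simulate_case", "simulate_cohort"]

_DRIVERS = (
    "APC", "TP53", "KRAS", "PIK3CA", "FBXW7", "SMAD4", "TCF7L2", "SOX9",
    "ARID1A", "BRAF", "NRAS", "ACVR2A", "AMER1", "ATM", "CTNNB1", "ERBB3",
)

# regime-dependent defaults: (private fraction, shared-clone CCF range,
# private CCF range, subclone count range, branch-driver probability)
_REGIME = {
    "darwinian": (0.15, (0.60, 0.95), (0.10, 0.30), (2, 3), 0.5),
    "neutral": (0.30, (0.15, 0.40), (0.05, 0.20), (1, 2), 0.1),
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings; defaults mirror the study design
    (10 precancerous cases of 4-7 regions, 8 advanced cases, ~150 mutations
    and ~132x coverage per sample)."""

    n_pcrc_cases: int = 10
    n_acrc_cases: int = 8
    pcrc_samples_per_case: Tuple[int, int] = (4, 7)
    acrc_samples_per_case: Tuple[int, int] = (4, 12)
    stage_means: Dict[str, float] = field(
        default_factory=lambda: {"adenoma": 150.0, "carcinoma": 150.0, "ACRC": 150.0}
    )
    trunk_fraction: float = 0.6
    private_fraction: Optional[float] = None  # None: regime default
    shared_ccf: Optional[Tuple[float, float]] = None
    private_ccf: Optional[Tuple[float, float]] = None
    tumor_content: Tuple[float, float] = (0.4, 0.9)
    mean_depth: float = 132.0
    depth_dispersion: float = 8.0
    normal_error_rate: float = 0.002
    caller_fn_rate: float = 0.05
    n_driver_mutations: Tuple[int, int] = (3, 6)
    trunk_cna_arms: Tuple[int, int] = (1, 3)
    subclone_cna_arms: Tuple[int, int] = (0, 2)
    cna_states: Tuple[int, ...] = (1, 3)
    log2r_noise: float = 0.03
    indel_fraction: float = 0.05
    pcrc_regime: str = "darwinian"
    acrc_regime: str = "neutral"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pcrc_cases, self.n_acrc_cases) < 0:
            raise ValueError("case counts must be non-negative")
        lo, hi = self.tumor_content
        if not (0 < lo <= hi <= 1):
            raise ValueError("tumor_content bounds must satisfy 0 < lo <= hi <= 1")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if any(cn < 1 for cn in self.cna_states):
            raise ValueError(
                "copy states below 1 are rejected: the expected-VAF formula "
                "requires CN >= 1"
            )
        for regime in (self.pcrc_regime, self.acrc_regime):
            if regime not in _REGIME:
                raise ValueError(f"unknown regime {regime!r}")
        if not 0 < self.trunk_fraction < 1:
            raise ValueError("trunk_fraction must lie in (0, 1)")

    @property
    def n_cases(self) -> int:
        return self.n_pcrc_cases + self.n_acrc_cases


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated case."""

    case_id: str
    clone: np.ndarray  # per variant, e.g. "trunk", "sub1", "private:<sample>"
    category: np.ndarray  # true ubiquitous/shared/private
    ccf: np.ndarray  # (n_variants, n_samples)
    copy_number: np.ndarray  # (n_variants, n_samples) int
    tumor_content: np.ndarray  # per sample
    stages: List[str]

    def __post_init__(self) -> None:
        trunk = self.clone == "trunk"
        if trunk.any() and not np.allclose(self.ccf[trunk], 1.0):
            raise ValueError("trunk variants must have CCF 1 in every sample")
        priv = self.category == "private"
        if priv.any() and not np.all((self.ccf[priv] > 0).sum(axis=1) == 1):
            raise ValueError("private variants must have CCF > 0 in exactly one sample")


def _regime_params(cfg: SimConfig, regime: str):
    priv_frac, shared_ccf, private_ccf, n_sub, branch_p = _REGIME[regime]
    if cfg.private_fraction is not None:
        priv_frac = cfg.private_fraction
    if cfg.shared_ccf is not None:
        shared_ccf = cfg.shared_ccf
    if cfg.private_ccf is not None:
        private_ccf = cfg.private_ccf
    return priv_frac, shared_ccf, private_ccf, n_sub, branch_p


_BASES = np.array(list("ACGT"))
# crude colorectal-like substitution bias (C>T transitions dominate)
_SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_SUB_WEIGHTS = np.array([0.10, 0.06, 0.50, 0.08, 0.16, 0.10])


def _draw_variant_site(rng, arms: Sequence[ArmDefinition], used: set,
                       gene: str, effect: str, indel: bool) -> VariantSite:
    while True:
        arm = arms[rng.integers(len(arms))]
        pos = int(rng.integers(arm.start + 1, arm.end + 1))
        if (arm.chrom, pos) in used:
            continue
        used.add((arm.chrom, pos))
        break
    if indel:
        ref = "".join(rng.choice(_BASES, size=2))
        alt = ref[0]
        effect = "indel"
    else:
        cls = _SUB_CLASSES[rng.choice(6, p=_SUB_WEIGHTS)]
        ref, alt = cls.split(">")
        if rng.random() < 0.5:  # place on the purine strand half the time
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            ref, alt = comp[ref], comp[alt]
    return VariantSite(chrom=arm.chrom, pos=pos, ref=ref, alt=alt,
                       gene=gene, effect=effect,
                       is_driver=gene in _DRIVERS and effect != "silent")


def simulate_case(cfg: SimConfig, case_index: int):
    """Simulate one case.

    Returns ``(samples, variants, counts, segments, truth)``; cases with
    index below ``n_pcrc_cases`` belong to the precancerous cohort. The
    draw is deterministic in ``(cfg.seed, case_index)``.
    """
    if not 0 <= case_index < cfg.n_cases:
        raise ValueError(f"case_index out of range 0..{cfg.n_cases - 1}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(case_index,))
    )
    is_pcrc = case_index < cfg.n_pcrc_cases
    cohort = "PCRC" if is_pcrc else "ACRC"
    regime = cfg.pcrc_regime if is_pcrc else cfg.acrc_regime
    number = case_index + 1 if is_pcrc else case_index - cfg.n_pcrc_cases + 1
    case_id = f"{cohort}{number:02d}"
    priv_frac, shared_ccf_rng, private_ccf_rng, n_sub_rng, branch_p = _regime_params(
        cfg, regime
    )
    shared_frac = max(0.0, 1.0 - cfg.trunk_fraction - priv_frac)

    lo, hi = cfg.pcrc_samples_per_case if is_pcrc else cfg.acrc_samples_per_case
    n_smp = int(rng.integers(lo, hi + 1))
    if is_pcrc:
        stages = ["adenoma" if rng.random() < 0.5 else "carcinoma" for _ in range(n_smp)]
        sample_ids = [
            f"{case_id}_{j + 1}{'A' if st == 'adenoma' else 'C'}"
            for j, st in enumerate(stages)
        ]
    else:
        stages = ["ACRC"] * n_smp
        sample_ids = [f"{case_id}_{j + 1}" for j in range(n_smp)]
    tc = rng.uniform(*cfg.tumor_content, size=n_smp)
    samples = [
        SampleMeta(sid, case_id, cohort, st, tumor_content=float(t))
        for sid, st, t in zip(sample_ids, stages, tc)
    ]
    stage_mean = np.array([cfg.stage_means[s] for s in stages])
    case_mean = float(stage_mean.mean())

    # --- clone structure ---------------------------------------------------
    clones: List[Tuple[str, np.ndarray, float]] = [
        ("trunk", np.ones(n_smp, dtype=bool), 1.0)
    ]
    n_sub = int(rng.integers(n_sub_rng[0], n_sub_rng[1] + 1))
    for c in range(n_sub):
        span = int(rng.integers(2, max(3, n_smp))) if n_smp > 2 else 2
        span = min(span, n_smp - 1) if n_smp > 2 else min(span, n_smp)
        start = int(rng.integers(0, n_smp - span + 1))
        mask = np.zeros(n_smp, dtype=bool)
        mask[start : start + span] = True
        clones.append((f"sub{c + 1}", mask, float(rng.uniform(*shared_ccf_rng))))

    # --- copy-number states per arm ---------------------------------------
    arms = [a for a in read_arm_definitions() if not is_sex_chromosome(a.chrom)]
    arm_ids = [a.arm_id for a in arms]
    cn_by_arm: Dict[str, np.ndarray] = {}
    available = list(range(len(arms)))
    rng.shuffle(available)
    cursor = 0
    segments: List[CnaSegment] = []

    def take_arm():
        nonlocal cursor
        idx = available[cursor]
        cursor += 1
        return arms[idx]

    for name, mask, _ in clones:
        arm_range = cfg.trunk_cna_arms if name == "trunk" else cfg.subclone_cna_arms
        n_arms = int(rng.integers(arm_range[0], arm_range[1] + 1))
        for _ in range(n_arms):
            if cursor >= len(available):
                break
            arm = take_arm()
            state = int(rng.choice(cfg.cna_states))
            states = np.full(n_smp, 2, dtype=int)
            states[mask] = state
            cn_by_arm[arm.arm_id] = states

    arm_lookup = {a.arm_id: a for a in arms}
    for arm_id, states in cn_by_arm.items():
        arm = arm_lookup[arm_id]
        length = arm.length
        seg_start = arm.start + int(0.05 * length)
        seg_end = arm.start + int(0.85 * length)  # 80% of the arm: arm-level
        for j, sid in enumerate(sample_ids):
            cn_eff = states[j]
            mean_l2r = np.log2(((1 - tc[j]) * 2 + tc[j] * cn_eff) / 2.0)
            noise = rng.normal(0.0, cfg.log2r_noise)
            segments.append(
                CnaSegment(sample_id=sid, chrom=arm.chrom, start=seg_start,
                           end=seg_end, log2r=float(mean_l2r + noise))
            )

    def cn_at(chrom: str, pos: int, j: int) -> int:
        for arm_id, states in cn_by_arm.items():
            arm = arm_lookup[arm_id]
            if arm.chrom == chrom and arm.start < pos <= arm.end:
                return int(states[j])
        return 2

    # --- mutations ---------------------------------------------------------
    used_pos: set = set()
    variants: List[VariantSite] = []
    clone_of: List[str] = []

    n_trunk = int(rng.poisson(cfg.trunk_fraction * case_mean))
    sub_clones = clones[1:]
    counts_per_clone = []
    for name, mask, _ in sub_clones:
        span = int(mask.sum())
        lam = shared_frac * case_mean * n_smp / (max(len(sub_clones), 1) * span)
        counts_per_clone.append(int(rng.poisson(lam)))
    n_private = [int(rng.poisson(priv_frac * stage_mean[j])) for j in range(n_smp)]

    n_drivers = int(rng.integers(cfg.n_driver_mutations[0],
                                 cfg.n_driver_mutations[1] + 1))
    driver_genes = list(rng.choice(_DRIVERS, size=min(n_drivers, len(_DRIVERS)),
                                   replace=False))

    def add_variant(clone_name: str, gene: str = "", driver: bool = False):
        if not gene:
            gene = f"G{int(rng.integers(1, 20000)):05d}"
        indel = bool(rng.random() < cfg.indel_fraction) and not driver
        effect = "non-synonymous SNV" if (driver or rng.random() < 0.7) else "silent"
        variants.append(
            _draw_variant_site(rng, arms, used_pos, gene, effect, indel)
        )
        clone_of.append(clone_name)

    for gene in driver_genes:
        if sub_clones and rng.random() < branch_p:
            name = sub_clones[int(rng.integers(len(sub_clones)))][0]
        else:
            name = "trunk"
        add_variant(name, gene=gene, driver=True)
    for _ in range(n_trunk):
        add_variant("trunk")
    for (name, _, _), cnt in zip(sub_clones, counts_per_clone):
        for _ in range(cnt):
            add_variant(name)
    for j in range(n_smp):
        for _ in range(n_private[j]):
            add_variant(f"private:{sample_ids[j]}")

    n_var = len(variants)
    clone_mask = {name: mask for name, mask, _ in clones}
    clone_ccf = {name: ccf for name, mask, ccf in clones}
    ccf = np.zeros((n_var, n_smp))
    cn = np.full((n_var, n_smp), 2, dtype=int)
    category = np.empty(n_var, dtype=object)
    for i, (v, cname) in enumerate(zip(variants, clone_of)):
        if cname.startswith("private:"):
            j = sample_ids.index(cname.split(":", 1)[1])
            ccf[i, j] = rng.uniform(*private_ccf_rng)
            category[i] = "private"
        else:
            mask = clone_mask[cname]
            ccf[i, mask] = clone_ccf[cname]
            span = int(mask.sum())
            category[i] = "ubiquitous" if span == n_smp else (
                "private" if span == 1 else "shared"
            )
        for j in range(n_smp):
            cn[i, j] = cn_at(v.chrom, v.pos, j)

    # --- reads -------------------------------------------------------------
    p_depth = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.mean_depth)
    depth = rng.negative_binomial(cfg.depth_dispersion, p_depth, size=(n_var, n_smp))
    true_vaf = expected_vaf_from_ccf(ccf, tc[None, :], cn)
    p_obs = np.minimum(true_vaf + cfg.normal_error_rate, 1.0)
    alt = rng.binomial(depth, p_obs)
    normal_depth = rng.negative_binomial(cfg.depth_dispersion, p_depth, size=n_var)
    normal_alt = rng.binomial(normal_depth, cfg.normal_error_rate)

    with np.errstate(invalid="ignore", divide="ignore"):
        obs_vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        normal_vaf = np.where(normal_depth > 0, normal_alt / np.maximum(normal_depth, 1), 0.0)
    flag = (
        (alt >= 4)
        & (obs_vaf >= 0.05)
        & (normal_vaf[:, None] <= 0.1)
        & (rng.random((n_var, n_smp)) >= cfg.caller_fn_rate)
    )

    counts = ReadCountMatrix(depth, alt, normal_depth, normal_alt, flag)
    truth = SyntheticTruth(
        case_id=case_id,
        clone=np.array(clone_of, dtype=object),
        category=category,
        ccf=ccf,
        copy_number=cn,
        tumor_content=tc,
        stages=stages,
    )
    return samples, variants, counts, segments, truth


def simulate_cohort(cfg: SimConfig, outdir) -> Dict[str, Path]:
    """Simulate the full two-cohort study and write it in the pipeline's
    input formats plus a truth table. Byte-identical for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: Dict[str, CaseTable] = {}
    all_samples: List[SampleMeta] = []
    all_segments: List[CnaSegment] = []
    truth_rows: List[dict] = []
    for case_index in range(cfg.n_cases):
        samples, variants, counts, segments, truth = simulate_case(cfg, case_index)
        tables[samples[0].case_id] = CaseTable(samples, variants, counts)
        all_samples.extend(samples)
        all_segments.extend(segments)
        for i, v in enumerate(variants):
            for j, s in enumerate(samples):
                truth_rows.append(
                    {
                        "case_id": s.case_id,
                        "sample_id": s.sample_id,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "clone": truth.clone[i],
                        "category": truth.category[i],
                        "true_ccf": round(float(truth.ccf[i, j]), 6),
                        "copy_number": int(truth.copy_number[i, j]),
                        "tumor_content": round(float(truth.tumor_content[j]), 6),
                        "stage": truth.stages[j],
                    }
                )

    paths = {
        "variants": outdir / "variants.tsv",
        "segments": outdir / "segments.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_variant_table(tables, paths["variants"])
    write_segments(all_segments, paths["segments"])
    write_sample_metadata(all_samples, paths["samples"])
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
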