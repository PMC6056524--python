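"""End-to-end orchestration: simulate or ingest, profile, downsample, CNA,
Bayesian models, and the frequentist comparison report, under one config
with explicit seeds and a manifest of every output."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import cna as cna_mod
from . import downsample, profiles, stats
from .io import (
    load_config,
    read_arm_definitions,
    read_sample_metadata,
    read_segments,
    read_variant_table,
)
from .models import (
    AlterationCountModel,
    CcfCategoryModel,
    VafCategoryModel,
)
from .simulate import SimConfig, simulate_cohort
from .types import (
    CaseTable,
    Hyperparameters,
    McmcConfig,
    MultiregionProfile,
    PAPER_MCMC_COUNTS,
    PAPER_MCMC_VAF,
    PAPER_MCMC_CCF,
)

__all__ = [
    "RunManifest",
    "run_pipeline",
    "count_observations",
    "vaf_observations",
    "copy_number_from_segments",
]

log = logging.getLogger("ithshift")


def count_observations(profiles_by_case: Dict[str, MultiregionProfile]) -> pd.DataFrame:
    """Per-sample mutation counts with stage labels (count-model input)."""
    rows = []
    for case_id, prof in profiles_by_case.items():
        per_sample = prof.presence.sum(axis=0)
        for j, s in enumerate(prof.samples):
            rows.append(
                {
                    "case_id": case_id,
                    "sample_id": s.sample_id,
                    "stage": s.stage,
                    "n": int(per_sample[j]),
                }
            )
    return pd.DataFrame(rows)


def copy_number_from_segments(log2r: float, tumor_content: float) -> int:
    """Discretize a segment's log2 ratio into an absolute copy number given
    tumor content: CN = round(2*(2^log2R - (1 - TC)) / TC), floored at 1."""
    raw = 2.0 * (2.0 ** log2r - (1.0 - tumor_content)) / tumor_content
    return max(1, int(round(raw)))


def vaf_observations(
    table: CaseTable,
    profile: MultiregionProfile,
    tumor_content: Dict[str, float],
    scheme: str = "tree",
    segments: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-(mutation, sample) read counts for the VAF/CCF models.

    One row per presence cell with non-zero depth; the category label is
    ``<cohort>:<label>`` under either the tree scheme (trunk / internal
    branch / external branch) or the raw categorization. Copy number comes
    from the overlapping segment's log2R via the rounding rule, 2 where no
    segment covers the locus.
    """
    if scheme not in ("tree", "category"):
        raise ValueError("scheme must be 'tree' or 'category'")
    labels = (
        profile.effective_tree_category() if scheme == "tree" else profile.category
    )
    seg_by_sample: Dict[str, list] = {}
    for seg in segments or []:
        seg_by_sample.setdefault(seg.sample_id, []).append(seg)

    key_to_row = {v.key(): i for i, v in enumerate(table.variants)}
    counts = table.counts
    rows = []
    for i, v in enumerate(profile.variants):
        ridx = key_to_row[v.key()]
        for j, s in enumerate(profile.samples):
            if not profile.presence[i, j]:
                continue
            d = int(counts.depth[ridx, j])
            if d == 0:
                continue
            tc = tumor_content[s.sample_id]
            cn = 2
            for seg in seg_by_sample.get(s.sample_id, []):
                if seg.chrom == v.chrom and seg.start < v.pos <= seg.end:
                    cn = copy_number_from_segments(seg.log2r, tc)
                    break
            rows.append(
                {
                    "case_id": profile.case_id,
                    "sample_id": s.sample_id,
                    "category": f"{s.cohort}:{labels[i]}",
                    "b": int(counts.alt_reads[ridx, j]),
                    "d": d,
                    "tumor_content": tc,
                    "copy_number": cn,
                    "chrom": v.chrom,
                }
            )
    return pd.DataFrame(rows)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, dict] = field(default_factory=dict)
    summary: Dict[str, object] = field(default_factory=dict)

    def record(self, stage: str, status: str) -> None:
        self.stages[stage] = status

    def add_output(self, name: str, path: Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _digest(path)}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def _mcmc_from_config(cfg: dict, seed: int, preset_paper) -> McmcConfig:
    m = cfg["mcmc"]
    if m.get("preset") == "paper":
        return preset_paper.with_seed(seed)
    return McmcConfig(
        n_chains=int(m["n_chains"]),
        n_burnin=int(m["n_burnin"]),
        n_total=int(m["n_total"]),
        thin=int(m["thin"]),
        seed=seed,
    )


def run_pipeline(
    config: Optional[dict] = None,
    outdir="ithshift_run",
    seed: Optional[int] = None,
) -> RunManifest:
    """Run simulate/ingest -> profile -> downsample -> CNA -> Bayesian models
    -> comparison report. Fails at the first broken stage, keeping earlier
    outputs; every output file lands in the manifest with a digest."""
    config = config if config is not None else load_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config["mcmc"].get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)
    t0 = time.time()

    tc_source = config.get("tumor_content", {}).get("source")
    if tc_source not in ("profile", "metadata"):
        raise ValueError(
            "config option tumor_content.source must be 'profile' or 'metadata'"
        )

    # --- inputs -----------------------------------------------------------
    sim_cfg = config.get("simulate", {})
    if sim_cfg.get("enabled", False):
        keys = {f.name for f in SimConfig.__dataclass_fields__.values()}
        params = {k: v for k, v in sim_cfg.items() if k in keys}
        params.setdefault("seed", seed)
        if "stage_means" in params:
            params["stage_means"] = dict(params["stage_means"])
        for k in ("pcrc_samples_per_case", "acrc_samples_per_case", "tumor_content",
                  "n_driver_mutations", "trunk_cna_arms", "subclone_cna_arms",
                  "cna_states", "shared_ccf", "private_ccf"):
            if k in params and params[k] is not None:
                params[k] = tuple(params[k])
        paths = simulate_cohort(SimConfig(**params), outdir / "inputs")
        manifest.record("simulate", "ok")
        for name, p in paths.items():
            manifest.add_output(f"inputs/{name}", p)
        variant_path, segment_path, meta_path = (
            paths["variants"], paths["segments"], paths["samples"],
        )
    else:
        inputs = config.get("inputs", {})
        for key in ("variants", "segments", "samples"):
            if key not in inputs:
                raise ValueError(f"config option inputs.{key} is required")
        variant_path, segment_path, meta_path = (
            Path(inputs["variants"]), Path(inputs["segments"]), Path(inputs["samples"]),
        )

    metadata = read_sample_metadata(meta_path)
    tables = read_variant_table(variant_path, metadata=metadata)
    segments = read_segments(segment_path)
    log.info("loaded %d cases, %d segments", len(tables), len(segments))

    # --- mutation profiles ------------------------------------------------
    r = config["rescue"]
    thresholds = profiles.RescueThresholds(
        min_tumor_vaf=r["min_tumor_vaf"],
        max_normal_vaf=r["max_normal_vaf"],
        fisher_p_max=r["fisher_p_max"],
        min_depth_all_samples=r["min_depth_all_samples"],
        fisher_alternative=r["fisher_alternative"],
    )
    profile_dir = outdir / "profiles"
    profile_dir.mkdir(exist_ok=True)
    profs: Dict[str, MultiregionProfile] = {}
    tc_by_sample: Dict[str, float] = {}
    for case_id, table in tables.items():
        prof = profiles.build_profile(table, thresholds)
        prof = profiles.mark_drivers(prof, config["driver_genes"])
        profs[case_id] = prof
        for s in prof.samples:
            if tc_source == "metadata":
                if s.tumor_content is None:
                    raise ValueError(
                        f"tumor_content.source=metadata but sample {s.sample_id} "
                        "has no tumor_content"
                    )
                tc_by_sample[s.sample_id] = s.tumor_content
            else:
                try:
                    tc_by_sample[s.sample_id] = profiles.estimate_tumor_content(
                        prof, s.sample_id
                    )
                except ValueError:
                    if s.tumor_content is None:
                        raise
                    tc_by_sample[s.sample_id] = s.tumor_content
        out = profile_dir / f"{case_id}.tsv"
        profiles.write_profile_table(prof, out)
        manifest.add_output(f"profiles/{case_id}", out)
    manifest.record("profile", "ok")

    # --- downsampling-corrected counts ------------------------------------
    k = int(config["downsampling"]["k"])
    count_rows = []
    for case_id, prof in profs.items():
        if prof.n_samples < k:
            log.warning("case %s has fewer than %d samples; skipped", case_id, k)
            continue
        cc = downsample.corrected_alteration_counts(prof, k)
        shared = downsample.corrected_shared_count(prof, k)
        count_rows.append(
            {
                "case_id": case_id,
                "cohort": prof.samples[0].cohort,
                "n_ubiquitous": cc.n_ubiquitous,
                "n_heterogeneous": cc.n_heterogeneous,
                "n_shared": shared,
            }
        )
    counts_df = pd.DataFrame(count_rows)
    counts_path = outdir / "corrected_counts.tsv"
    counts_df.to_csv(counts_path, sep="\t", index=False)
    manifest.add_output("corrected_counts", counts_path)
    manifest.record("downsample", "ok")

    def _cohort_p(col: str) -> float:
        p = counts_df[counts_df["cohort"] == "PCRC"][col]
        a = counts_df[counts_df["cohort"] == "ACRC"][col]
        if not len(p) or not len(a):
            return float("nan")
        return stats.wilcoxon_rank_sum(p, a)

    manifest.summary["wilcoxon_shared_p"] = _cohort_p("n_shared")
    manifest.summary["wilcoxon_ubiquitous_p"] = _cohort_p("n_ubiquitous")
    manifest.summary["corrected_shared_median"] = {
        coh: float(counts_df[counts_df["cohort"] == coh]["n_shared"].median())
        for coh in ("PCRC", "ACRC")
        if (counts_df["cohort"] == coh).any()
    }

    # --- CNA profiles ------------------------------------------------------
    arms = read_arm_definitions()
    cna_rows = []
    for case_id, prof in profs.items():
        sample_ids = [s.sample_id for s in prof.samples]
        case_segs = [s for s in segments if s.sample_id in set(sample_ids)]
        calls = cna_mod.arm_calls(
            case_segs, arms, sample_ids,
            threshold=config["cna"]["log2r_threshold"],
            arm_fraction=config["cna"]["arm_fraction"],
        )
        mat, _ = cna_mod.cna_presence_matrix(calls)
        if mat.shape[1] >= k and mat.size:
            cc = downsample.corrected_alteration_counts(mat, k, case_id=case_id)
            ubiq, het = cc.n_ubiquitous, cc.n_heterogeneous
        else:
            ubiq = float(sum(c.category == "ubiquitous" for c in calls))
            het = float(sum(c.category == "heterogeneous" for c in calls))
        cna_rows.append(
            {
                "case_id": case_id,
                "cohort": prof.samples[0].cohort,
                "n_arms_called": len(calls),
                "n_ubiquitous": ubiq,
                "n_heterogeneous": het,
            }
        )
    cna_df = pd.DataFrame(cna_rows)
    cna_path = outdir / "cna_counts.tsv"
    cna_df.to_csv(cna_path, sep="\t", index=False)
    manifest.add_output("cna_counts", cna_path)
    manifest.record("cna", "ok")

    # --- Bayesian models ---------------------------------------------------
    hyper = Hyperparameters(**config["hyperparameters"])
    obs_counts = count_observations(profs)
    model_counts = AlterationCountModel(
        hyper=hyper, mcmc=_mcmc_from_config(config, seed, PAPER_MCMC_COUNTS)
    ).fit(obs_counts)
    counts_summary = model_counts.summary(kind="adjusted")
    counts_summary.to_csv(outdir / "bayes_counts.tsv", sep="\t")
    manifest.add_output("bayes_counts", outdir / "bayes_counts.tsv")
    manifest.record("bayes_counts", "ok")

    vaf_obs = pd.concat(
        [
            vaf_observations(tables[cid], profs[cid], tc_by_sample,
                             scheme="tree", segments=segments)
            for cid in profs
        ],
        ignore_index=True,
    )
    model_vaf = VafCategoryModel(
        hyper=hyper, mcmc=_mcmc_from_config(config, seed + 1, PAPER_MCMC_VAF)
    ).fit(vaf_obs)
    vaf_summary = model_vaf.summary(kind="adjusted")
    vaf_summary.to_csv(outdir / "bayes_vaf.tsv", sep="\t")
    manifest.add_output("bayes_vaf", outdir / "bayes_vaf.tsv")
    manifest.record("bayes_vaf", "ok")
    if {"PCRC:internal_branch", "ACRC:internal_branch"} <= set(model_vaf.groups_):
        manifest.summary["p_internal_branch_pcrc_gt_acrc"] = model_vaf.prob_greater(
            "PCRC:internal_branch", "ACRC:internal_branch"
        )

    model_ccf = CcfCategoryModel(
        hyper=hyper, mcmc=_mcmc_from_config(config, seed + 2, PAPER_MCMC_CCF)
    ).fit(vaf_obs)
    ccf_summary = model_ccf.summary(kind="adjusted")
    ccf_summary.to_csv(outdir / "bayes_ccf.tsv", sep="\t")
    manifest.add_output("bayes_ccf", outdir / "bayes_ccf.tsv")
    manifest.record("bayes_ccf", "ok")

    # --- frequentist comparisons -------------------------------------------
    by_cohort: Dict[str, List[MultiregionProfile]] = {"PCRC": [], "ACRC": []}
    for prof in profs.values():
        by_cohort[prof.samples[0].cohort].append(prof)
    table2 = stats.driver_trunk_branch_table(by_cohort)
    fisher_p = stats.fisher_exact_two_sided(table2)
    manifest.summary["driver_table"] = {
        "PCRC": [table2.a, table2.b], "ACRC": [table2.c, table2.d],
    }
    manifest.summary["fisher_driver_p"] = fisher_p

    all_ubiq, all_het = [], []
    for prof in profs.values():
        for i, v in enumerate(prof.variants):
            (all_ubiq if prof.category[i] == "ubiquitous" else all_het).append(v)
    manifest.summary["spectrum_ubiquitous"] = stats.spectrum(all_ubiq).fractions
    manifest.summary["spectrum_heterogeneous"] = stats.spectrum(all_het).fractions
    manifest.record("compare", "ok")

    manifest.summary["runtime_s"] = round(time.time() - t0, 2)
    manifest.write(outdir / "manifest.json")
    return manifest
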