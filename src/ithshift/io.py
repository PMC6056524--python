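"""Readers and writers for the pipeline's tabular formats.

All downstream modules consume the domain types produced here; nothing else
in the package re-parses files. Formats are plain TSV:

* variant table — one row per (variant, sample):
  ``case_id  sample_id  chrom  pos  ref  alt  gene  effect  depth  alt_reads
  normal_depth  normal_alt_reads  caller_flag``
* segments — SEG-style: ``sample_id  chrom  start  end  log2R``
* arm definitions — ``arm_id  chrom  start  end`` (an hg19 cytoband-derived
  table ships with the package)
* sample metadata — ``sample_id  case_id  cohort  stage  tumor_content``
* run configuration — YAML, deep-merged over built-in defaults.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    ArmDefinition,
    CaseTable,
    CnaSegment,
    ReadCountMatrix,
    SampleMeta,
    VariantSite,
)

__all__ = [
    "VARIANT_TABLE_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "read_segments",
    "write_segments",
    "read_arm_definitions",
    "read_sample_metadata",
    "write_sample_metadata",
    "DEFAULT_CONFIG",
    "load_config",
]

VARIANT_TABLE_COLUMNS = [
    "case_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "depth",
    "alt_reads",
    "normal_depth",
    "normal_alt_reads",
    "caller_flag",
]

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "log2R"]

METADATA_COLUMNS = ["sample_id", "case_id", "cohort", "stage", "tumor_content"]


def _infer_sample_meta(case_id: str, sample_id: str) -> SampleMeta:
    """Fall-back sample annotation from the naming convention: case prefix
    "ACRC" marks the advanced cohort; otherwise the trailing "A"/"C" of the
    sample name distinguishes adenoma from carcinoma."""
    if case_id.upper().startswith("ACRC"):
        return SampleMeta(sample_id, case_id, "ACRC", "ACRC")
    stage = "carcinoma" if sample_id.rstrip().upper().endswith("C") else "adenoma"
    return SampleMeta(sample_id, case_id, "PCRC", stage)


def read_sample_metadata(path) -> List[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "case_id": str})
    missing = set(METADATA_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        tc = row.get("tumor_content", np.nan)
        out.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                case_id=str(row["case_id"]),
                cohort=str(row["cohort"]),
                stage=str(row["stage"]),
                tumor_content=None if pd.isna(tc) else float(tc),
            )
        )
    return out


def write_sample_metadata(samples: Sequence[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "case_id": s.case_id,
            "cohort": s.cohort,
            "stage": s.stage,
            "tumor_content": "" if s.tumor_content is None else s.tumor_content,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table(
    path, metadata: Optional[Sequence[SampleMeta]] = None
) -> Dict[str, CaseTable]:
    """Parse a variant table into per-case dense matrices.

    Every (variant, sample) pair of a case must be present exactly once:
    duplicates and missing cells are rejected (a missing cell is not an
    implicit zero). Row numbers in error messages count the header as line 1.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"case_id": str, "sample_id": str, "chrom": str, "ref": str, "alt": str},
        keep_default_na=False,
        na_values=[],
    )
    missing_cols = set(VARIANT_TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"variant table missing columns: {sorted(missing_cols)}")
    df = df.copy()
    df["_row"] = np.arange(2, len(df) + 2)  # file line numbers

    for col in ("pos", "depth", "alt_reads", "normal_depth", "normal_alt_reads"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-integer value in column {col!r}: {exc}") from None
    bad = df[df["alt_reads"] > df["depth"]]
    if len(bad):
        raise ValueError(
            f"alt_reads exceeds depth at row {int(bad['_row'].iloc[0])}"
        )
    bad = df[df["normal_alt_reads"] > df["normal_depth"]]
    if len(bad):
        raise ValueError(
            f"normal_alt_reads exceeds normal_depth at row {int(bad['_row'].iloc[0])}"
        )
    if (df["pos"] < 1).any():
        row = int(df.loc[df["pos"] < 1, "_row"].iloc[0])
        raise ValueError(f"malformed coordinate (pos < 1) at row {row}")

    meta_by_id = {m.sample_id: m for m in metadata} if metadata else {}
    tables: Dict[str, CaseTable] = {}
    for case_id, grp in df.groupby("case_id", sort=True):
        key_cols = ["chrom", "pos", "ref", "alt"]
        dup = grp.duplicated(subset=key_cols + ["sample_id"])
        if dup.any():
            row = int(grp.loc[dup, "_row"].iloc[0])
            raise ValueError(f"duplicate (variant, sample) row at line {row}")

        sample_ids = sorted(grp["sample_id"].unique())
        vkeys = grp[key_cols].drop_duplicates().sort_values(["chrom", "pos", "ref", "alt"])
        vkeys = list(vkeys.itertuples(index=False, name=None))
        n_var, n_smp = len(vkeys), len(sample_ids)
        if len(grp) != n_var * n_smp:
            have = set(
                grp[key_cols + ["sample_id"]].itertuples(index=False, name=None)
            )
            missing = [
                (k, s) for k in vkeys for s in sample_ids if (*k, s) not in have
            ]
            raise ValueError(
                f"case {case_id}: missing (variant, sample) cells, e.g. "
                f"{missing[0][0]} in sample {missing[0][1]} "
                f"({len(missing)} missing in total)"
            )

        vidx = {k: i for i, k in enumerate(vkeys)}
        sidx = {s: j for j, s in enumerate(sample_ids)}
        depth = np.zeros((n_var, n_smp), dtype=np.int64)
        alt = np.zeros_like(depth)
        flag = np.zeros((n_var, n_smp), dtype=bool)
        ndepth = np.zeros(n_var, dtype=np.int64)
        nalt = np.zeros(n_var, dtype=np.int64)
        variants: List[Optional[VariantSite]] = [None] * n_var
        for rec in grp.itertuples(index=False):
            i = vidx[(rec.chrom, rec.pos, rec.ref, rec.alt)]
            j = sidx[rec.sample_id]
            depth[i, j] = rec.depth
            alt[i, j] = rec.alt_reads
            flag[i, j] = bool(int(rec.caller_flag))
            ndepth[i] = rec.normal_depth
            nalt[i] = rec.normal_alt_reads
            if variants[i] is None:
                variants[i] = VariantSite(
                    chrom=rec.chrom,
                    pos=int(rec.pos),
                    ref=rec.ref,
                    alt=rec.alt,
                    gene=str(rec.gene),
                    effect=str(rec.effect),
                )
        samples = [
            meta_by_id.get(s, _infer_sample_meta(str(case_id), s)) for s in sample_ids
        ]
        counts = ReadCountMatrix(depth, alt, ndepth, nalt, flag)
        tables[str(case_id)] = CaseTable(samples, variants, counts)
    return tables


def write_variant_table(tables: Union[Dict[str, CaseTable], CaseTable], path) -> None:
    if isinstance(tables, CaseTable):
        tables = {tables.case_id: tables}
    rows = []
    for case_id in sorted(tables):
        tab = tables[case_id]
        c = tab.counts
        for i, v in enumerate(tab.variants):
            for j, s in enumerate(tab.samples):
                rows.append(
                    (
                        case_id,
                        s.sample_id,
                        v.chrom,
                        v.pos,
                        v.ref,
                        v.alt,
                        v.gene,
                        v.effect,
                        int(c.depth[i, j]),
                        int(c.alt_reads[i, j]),
                        int(c.normal_depth[i]),
                        int(c.normal_alt_reads[i]),
                        int(c.caller_flag[i, j]),
                    )
                )
    pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_segments(path) -> List[CnaSegment]:
    """Read SEG-style segments, normalized to 0-based half-open and sorted by
    (sample, chrom, start). Overlapping segments within one sample and
    chromosome are rejected."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment file missing columns: {sorted(missing)}")
    segs = [
        CnaSegment(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            log2r=float(r.log2R),
        )
        for r in df.itertuples(index=False)
    ]
    segs.sort()
    for a, b in zip(segs, segs[1:]):
        if a.sample_id == b.sample_id and a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"overlapping segments for sample {a.sample_id} on {a.chrom}: "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )
    return segs


def write_segments(segments: Sequence[CnaSegment], path) -> None:
    rows = [(s.sample_id, s.chrom, s.start, s.end, s.log2r) for s in sorted(segments)]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_arm_definitions(path=None) -> List[ArmDefinition]:
    """Arm intervals; with no path, the packaged hg19 table is used."""
    if path is None:
        src = resources.files("ithshift.data").joinpath("arms_hg19.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype={"arm_id": str, "chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"arm_id": str, "chrom": str})
    arms = [
        ArmDefinition(str(r.arm_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    by_chrom: Dict[str, List[ArmDefinition]] = {}
    for a in arms:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda a: a.start)
        for x, y in zip(group, group[1:]):
            if y.start < x.end:
                raise ValueError(f"overlapping arm definitions on {chrom}")
    return arms


# ---------------------------------------------------------------------------
# run configuration

#: every published constant, overridable from a YAML file
DEFAULT_CONFIG: dict = {
    "rescue": {
        "min_tumor_vaf": 0.05,
        "max_normal_vaf": 0.01,
        "fisher_p_max": 0.05,
        "min_depth_all_samples": 10,  # admission requires strictly more reads
        "fisher_alternative": "greater",
    },
    "downsampling": {"k": 4},
    "cna": {
        "arm_fraction": 0.5,  # strict ">" of arm length
        "log2r_threshold": 0.15,  # strict "|mean| >"
        "focal_loci": [],
    },
    "hyperparameters": {
        "beta0": 0.0,
        "tau0": 1.0,
        "lambda0": 1.0,
        "r0": 1.0,
        "l0": 1.0,
        "l1": 1.0,
        "l2": 1.0,
    },
    "mcmc": {
        "preset": "fast",  # "fast" or "paper"
        "n_chains": 4,
        "n_burnin": 2000,
        "n_total": 4000,
        "thin": 1,
        "seed": 0,
    },
    "driver_genes": [
        "APC", "TP53", "KRAS", "PIK3CA", "FBXW7", "SMAD4", "TCF7L2",
        "SOX9", "ARID1A", "BRAF", "NRAS", "ACVR2A", "AMER1", "ATM",
        "CTNNB1", "ERBB3",
    ],
    "tumor_content": {"source": "profile"},  # "profile" | "metadata"
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path=None) -> dict:
    """Built-in defaults, deep-merged with an optional YAML override file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config file must contain a mapping")
    return _deep_merge(DEFAULT_CONFIG, user)
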