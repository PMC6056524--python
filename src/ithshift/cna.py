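"""Arm-level and focal copy-number profiles from segment log2 ratios.

A segment is arm-level when its overlap with an arm exceeds half the arm's
length (strictly). For each arm that carries an arm-level segment in at
least one sample of a case, every sample is (re-)examined: the arm's
length-weighted mean log2R is computed with uncovered bases contributing 0,
and a CNA is present when the absolute mean strictly exceeds the threshold
(0.15 by default). Presence with positive mean is a gain, negative a loss.
An arm is ubiquitous for the case when present with one sign in every
sample, heterogeneous when present in some samples or with discordant signs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import ArmCall, ArmDefinition, CnaSegment, FocalLocus, is_sex_chromosome

__all__ = [
    "SegmentArmAssignment",
    "arm_level_segments",
    "reexamine_arm",
    "focal_calls",
    "categorize_cna",
    "arm_calls",
    "cna_presence_matrix",
]

LOG2R_THRESHOLD = 0.15
ARM_FRACTION = 0.5


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


@dataclass(frozen=True)
class SegmentArmAssignment:
    segment: CnaSegment
    arm_id: str
    overlap: int
    is_arm_level: bool


def arm_level_segments(
    segments: Sequence[CnaSegment],
    arms: Sequence[ArmDefinition],
    arm_fraction: float = ARM_FRACTION,
) -> List[SegmentArmAssignment]:
    """Classify each segment against every arm it overlaps.

    Arm-level on an arm when the overlap strictly exceeds ``arm_fraction`` of
    the arm length; otherwise focal there. Segments overlapping no defined
    arm are excluded with a warning.
    """
    by_chrom: Dict[str, List[ArmDefinition]] = {}
    for arm in arms:
        by_chrom.setdefault(arm.chrom, []).append(arm)
    out: List[SegmentArmAssignment] = []
    for seg in segments:
        hits = 0
        for arm in by_chrom.get(seg.chrom, []):
            ov = _overlap(seg.start, seg.end, arm.start, arm.end)
            if ov == 0:
                continue
            hits += 1
            out.append(
                SegmentArmAssignment(
                    segment=seg,
                    arm_id=arm.arm_id,
                    overlap=ov,
                    is_arm_level=ov > arm_fraction * arm.length,
                )
            )
        if hits == 0:
            warnings.warn(
                f"segment {seg.sample_id}:{seg.chrom}:{seg.start}-{seg.end} "
                "overlaps no defined arm; excluded"
            )
    return out


def _weighted_mean_log2r(
    arm_like, segments: Sequence[CnaSegment]
) -> float:
    """Length-weighted mean log2R over an interval; uncovered bases count 0.
    Rounded to 12 decimals so exact-threshold inputs compare exactly."""
    total = 0.0
    for seg in segments:
        ov = _overlap(seg.start, seg.end, arm_like.start, arm_like.end)
        if ov:
            total += ov * seg.log2r
    return round(total / arm_like.length, 12)


def reexamine_arm(
    arm: ArmDefinition,
    sample_segments: Sequence[CnaSegment],
    threshold: float = LOG2R_THRESHOLD,
) -> Tuple[bool, float]:
    """(present, mean log2R) for one arm in one sample; presence requires the
    absolute weighted mean to strictly exceed the threshold."""
    mean = _weighted_mean_log2r(arm, [s for s in sample_segments if s.chrom == arm.chrom])
    return abs(mean) > threshold, mean


def categorize_cna(status: Sequence[str]) -> Tuple[str, bool]:
    """Case-level category from per-sample gain/loss/none statuses.

    Returns (category, discordant): ubiquitous when every sample is present
    with one common sign; heterogeneous when present in >= 1 but not all, or
    present everywhere with conflicting signs (flagged discordant).
    """
    present = [s for s in status if s != "none"]
    if not present:
        return "absent", False
    signs = set(present)
    if len(present) == len(status):
        if len(signs) == 1:
            return "ubiquitous", False
        return "heterogeneous", True
    return "heterogeneous", len(signs) > 1


def arm_calls(
    segments: Sequence[CnaSegment],
    arms: Sequence[ArmDefinition],
    sample_ids: Optional[Sequence[str]] = None,
    threshold: float = LOG2R_THRESHOLD,
    arm_fraction: float = ARM_FRACTION,
) -> List[ArmCall]:
    """Multiregion arm-level CNA profile for one case.

    Only arms that the segmentation supports with an arm-level segment in at
    least one sample are examined; in the other samples presence is decided
    by the |mean log2R| threshold. Sex-chromosome arms are processed like the
    rest (downstream CCF input excludes them separately).
    """
    if sample_ids is None:
        sample_ids = sorted({s.sample_id for s in segments})
    sample_ids = list(sample_ids)
    assigns = arm_level_segments(segments, arms, arm_fraction)
    candidate_arms = sorted({a.arm_id for a in assigns if a.is_arm_level})
    arm_by_id = {a.arm_id: a for a in arms}
    by_sample: Dict[str, List[CnaSegment]] = {sid: [] for sid in sample_ids}
    for seg in segments:
        if seg.sample_id in by_sample:
            by_sample[seg.sample_id].append(seg)

    calls: List[ArmCall] = []
    for arm_id in candidate_arms:
        arm = arm_by_id[arm_id]
        means = np.zeros(len(sample_ids))
        status = np.empty(len(sample_ids), dtype=object)
        for j, sid in enumerate(sample_ids):
            present, mean = reexamine_arm(arm, by_sample[sid], threshold)
            means[j] = mean
            status[j] = ("gain" if mean > 0 else "loss") if present else "none"
        category, discordant = categorize_cna(list(status))
        calls.append(
            ArmCall(
                arm_id=arm_id,
                sample_ids=sample_ids,
                mean_log2r=means,
                status=status,
                category=category,
                discordant=discordant,
            )
        )
    return calls


def focal_calls(
    segments: Sequence[CnaSegment],
    loci: Sequence[ArmDefinition],
    arms: Sequence[ArmDefinition],
    sample_ids: Optional[Sequence[str]] = None,
    threshold: float = LOG2R_THRESHOLD,
    arm_fraction: float = ARM_FRACTION,
) -> List[FocalLocus]:
    """Focal CNA profile over configured candidate loci.

    A locus is examined only when it overlaps a focally classified segment
    (not arm-level) in at least one sample; presence per sample then uses the
    |mean log2R| > threshold rule over the locus. An empty locus list yields
    an empty profile.
    """
    if not loci:
        return []
    if sample_ids is None:
        sample_ids = sorted({s.sample_id for s in segments})
    sample_ids = list(sample_ids)
    assigns = arm_level_segments(segments, arms, arm_fraction)
    focal_segments = [a.segment for a in assigns if not a.is_arm_level]
    by_sample: Dict[str, List[CnaSegment]] = {sid: [] for sid in sample_ids}
    for seg in segments:
        if seg.sample_id in by_sample:
            by_sample[seg.sample_id].append(seg)

    out: List[FocalLocus] = []
    for locus in loci:
        touches_focal = any(
            seg.chrom == locus.chrom
            and _overlap(seg.start, seg.end, locus.start, locus.end) > 0
            for seg in focal_segments
        )
        if not touches_focal:
            continue
        means = np.zeros(len(sample_ids))
        present = np.zeros(len(sample_ids), dtype=bool)
        for j, sid in enumerate(sample_ids):
            mean = _weighted_mean_log2r(
                locus, [s for s in by_sample[sid] if s.chrom == locus.chrom]
            )
            means[j] = mean
            present[j] = abs(mean) > threshold
        out.append(
            FocalLocus(
                locus_id=locus.arm_id,
                chrom=locus.chrom,
                start=locus.start,
                end=locus.end,
                sample_ids=sample_ids,
                mean_log2r=means,
                present=present,
            )
        )
    return out


def cna_presence_matrix(calls: Sequence[ArmCall]) -> Tuple[np.ndarray, List[str]]:
    """(arm x sample) presence matrix feeding the downsampling correction."""
    if not calls:
        return np.zeros((0, 0), dtype=bool), []
    sample_ids = list(calls[0].sample_ids)
    mat = np.array([[s != "none" for s in call.status] for call in calls], dtype=bool)
    return mat, sample_ids
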