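"""Structural junction typing and chromothripsis-like region scoring."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cnv import CopySegment

JUNCTION_TYPES = ("deletion", "tandem-duplication", "inversion", "interchromosomal")

Endpoint = Tuple[str, int, str]  # chrom, pos, orientation ('+'/'-')


@dataclass(frozen=True)
class Junction:
    left: Endpoint
    right: Endpoint
    type: str
    confidence: str = "high"


@dataclass
class ChromothripsisReport:
    chrom: str
    start: int
    end: int
    n_junctions: int
    density_per_mb: float
    n_major_states: int
    oscillations: int
    verdict: bool


def type_junction(left: Endpoint, right: Endpoint) -> str:
    """Classify a junction from its endpoint orientations.

    Intra-chromosomal endpoints are ordered by position first; +/- spanning
    a gap is a deletion, -/+ a tandem duplication, equal orientations an
    inversion; different chromosomes are interchromosomal.
    """
    for ep in (left, right):
        if ep[2] not in ("+", "-"):
            raise ValueError(f"unknown orientation code {ep[2]!r}")
    if left[0] != right[0]:
        return "interchromosomal"
    if left[1] > right[1]:
        left, right = right, left
    lo, ro = left[2], right[2]
    if lo == ro:
        return "inversion"
    if lo == "+" and ro == "-":
        return "deletion"
    return "tandem-duplication"


def junctions_in_region(
    junctions: pd.DataFrame, chrom: str, start: int, end: int
) -> pd.DataFrame:
    """Junctions with both endpoints inside the half-open region."""
    sel = (
        (junctions["chrom1"] == chrom)
        & (junctions["chrom2"] == chrom)
        & (junctions["pos1"] >= start)
        & (junctions["pos1"] < end)
        & (junctions["pos2"] >= start)
        & (junctions["pos2"] < end)
    )
    return junctions[sel]


def _major_states(
    segments: Sequence[CopySegment], start: int, end: int, bin_width: float = 0.5,
    min_cover: float = 0.1,
) -> Tuple[List[float], List[float]]:
    """Cluster segment mean ratios by rounding to ``bin_width`` log2 bins;
    a bin is major when its segments cover at least ``min_cover`` of the
    region. Returns (major bin centers sorted by covered length desc,
    per-segment bin assignment)."""
    lengths: dict = {}
    assignment = []
    for seg in segments:
        ov = min(seg.end, end) - max(seg.start, start)
        if ov <= 0:
            assignment.append(None)
            continue
        b = round(seg.mean_ratio / bin_width) * bin_width
        lengths[b] = lengths.get(b, 0) + ov
        assignment.append(b)
    region_len = end - start
    major = [b for b, l in lengths.items() if l >= min_cover * region_len]
    major.sort(key=lambda b: -lengths[b])
    return major, assignment


def score_region(
    junctions: pd.DataFrame,
    segments: Sequence[CopySegment],
    chrom: str,
    start: int,
    end: int,
    min_junctions_per_mb: float = 10.0,
    max_states: int = 2,
    min_oscillations: int = 5,
) -> ChromothripsisReport:
    """Chromothripsis-like evidence for one region: junction density, the
    number of major copy-number states, and state oscillations.
    """
    if end <= start:
        raise ValueError("empty region")
    region_segments = [
        s for s in segments
        if s.chrom == chrom and s.start < end and s.end > start
    ]
    inside = junctions_in_region(junctions, chrom, start, end)
    n_j = len(inside)
    mb = (end - start) / 1e6
    density = n_j / mb
    major, assignment = _major_states(region_segments, start, end)
    n_states = max(len(major), 1)
    oscillations = 0
    if len(major) >= 2:
        top2 = set(major[:2])
        path = [b for b in assignment if b in top2]
        oscillations = sum(1 for a, b in zip(path[:-1], path[1:]) if a != b)
    verdict = (
        density >= min_junctions_per_mb
        and n_states <= max_states
        and oscillations >= min_oscillations
    )
    return ChromothripsisReport(
        chrom=chrom,
        start=start,
        end=end,
        n_junctions=n_j,
        density_per_mb=density,
        n_major_states=n_states,
        oscillations=oscillations,
        verdict=verdict,
    )
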