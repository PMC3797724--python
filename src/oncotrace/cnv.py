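"""Coverage log-ratios, circular binary segmentation (CBS), lesser allele
fraction (LAF), LOH/gain/loss flags, and fine-scale focal-deletion calls.

CBS here is the classic recursive scheme: at each node, find the circular
arc maximizing the two-mean t statistic on partial sums; keep the split if
its permutation p-value is at or below alpha; recurse into the resulting
pieces. No undo step; ties broken at the leftmost arc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GeneModel


@dataclass
class CoverageWindow:
    chrom: str
    start: int
    end: int
    tumor: float
    normal: float
    ratio: float  # log2, NaN when masked


@dataclass
class CopySegment:
    chrom: str
    start: int
    end: int
    mean_ratio: float
    n_windows: int
    copy_number: Optional[float] = None
    laf: Optional[float] = None
    flags: set = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# windowed log ratio


def windowed_log_ratio(
    tumor_cov: pd.DataFrame,
    normal_cov: pd.DataFrame,
    window: int = 100_000,
    min_normal_cov: float = 10.0,
) -> pd.DataFrame:
    """Normalized per-window log2 tumor/normal coverage ratio.

    Inputs are per-window coverage tables (chrom, start, end, coverage) on
    the same grid. Each sample is first normalized by its own total so a
    global coverage difference cancels; windows with normal coverage below
    ``min_normal_cov`` are masked (ratio NaN).
    """
    key = ["chrom", "start", "end"]
    merged = tumor_cov[key + ["coverage"]].merge(
        normal_cov[key + ["coverage"]], on=key, suffixes=("_t", "_n")
    )
    if len(merged) != len(tumor_cov) or len(merged) != len(normal_cov):
        raise ValueError("tumor and normal coverage tables are on different grids")
    t_total = merged["coverage_t"].sum()
    n_total = merged["coverage_n"].sum()
    if t_total <= 0 or n_total <= 0:
        raise ValueError("zero total coverage")
    ratio = np.log2(
        (merged["coverage_t"] / t_total) / (merged["coverage_n"] / n_total)
    )
    ratio = ratio.where(merged["coverage_n"] >= min_normal_cov, np.nan)
    out = merged.rename(columns={"coverage_t": "tumor", "coverage_n": "normal"})
    out["ratio"] = ratio
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# circular binary segmentation


def _arc_stats(x: np.ndarray, inv_kk: np.ndarray) -> float:
    """Max |t| over circular arcs; helper shared by data and permutations."""
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    Z = S[None, :] - S[:, None]  # Z[i, j] = sum of x[i:j]
    total = S[-1]
    k = np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(Z / k - (total - Z) / (n - k)) * inv_kk
    return t


def _inv_kk(n: int, sd: float) -> np.ndarray:
    k = np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = sd * np.sqrt(1.0 / k + 1.0 / (n - k))
        inv = 1.0 / denom
    inv[~np.isfinite(inv)] = 0.0  # kills k<=0 and k>=n arcs
    return inv


def _best_arc(x: np.ndarray) -> Tuple[float, int, int]:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        return 0.0, 0, n
    inv = _inv_kk(n, sd)
    t = _arc_stats(x, inv)
    t[~np.isfinite(t)] = 0.0
    flat = int(np.argmax(t))  # row-major argmax = leftmost i, then leftmost j
    i, j = divmod(flat, n + 1)
    return float(t[i, j]), i, j


def _permutation_pvalue(
    x: np.ndarray,
    observed: float,
    rng: np.random.Generator,
    n_perm: int,
    alpha: float,
) -> float:
    """Permutation p-value for the max arc statistic, with early stop once
    significance at ``alpha`` is impossible."""
    n = len(x)
    # bound the (chunk, n+1, n+1) workspace to ~100 MB
    chunk = max(1, min(64, int(1.2e7 / ((n + 1) * (n + 1)))))
    sd = float(np.std(x, ddof=1))
    inv = _inv_kk(n, sd)
    exceed = 0
    done = 0
    stop_at = int(np.floor(alpha * (n_perm + 1)))  # > stop_at exceedances => p > alpha
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(x) for _ in range(b)])
        S = np.concatenate(
            [np.zeros((b, 1)), np.cumsum(perms, axis=1)], axis=1
        )
        Z = S[:, None, :] - S[:, :, None]
        total = S[:, -1][:, None, None]
        k = np.arange(n + 1)[None, :] - np.arange(n + 1)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(Z / k[None] - (total - Z) / (n - k)[None]) * inv[None]
        t[~np.isfinite(t)] = 0.0
        maxima = t.reshape(b, -1).max(axis=1)
        exceed += int(np.sum(maxima >= observed))
        done += b
        if exceed > stop_at:
            break
    return (1 + exceed) / (1 + done)


def cbs_segment(
    values: Sequence[float],
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    min_width: int = 2,
) -> List[int]:
    """Breakpoint indices (positions where a new segment starts) for a 1-D
    series. Non-finite values must be masked by the caller. Returns sorted
    interior breakpoints; an empty list means one segment.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        return []
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values must be masked before segmentation")
    rng = np.random.default_rng(seed)
    breaks: List[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = len(seg)
        if n < 2 * min_width:
            return
        stat, i, j = _best_arc(seg)
        if stat <= 0.0:
            return
        p = _permutation_pvalue(seg, stat, rng, n_perm, alpha)
        if p > alpha:
            return
        cuts = sorted({c for c in (i, j) if 0 < c < n})
        if not cuts:
            return
        for c in cuts:
            breaks.append(lo + c)
        edges = [lo] + [lo + c for c in cuts] + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(set(breaks))


def segment_ratios(
    ratio_df: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> List[CopySegment]:
    """Run CBS per chromosome on a windowed log-ratio table and return
    contiguous segments with mean ratios. Masked windows are skipped for
    segmentation but merged back into the covering segment's span."""
    segments: List[CopySegment] = []
    for chrom, group in ratio_df.groupby("chrom", sort=True):
        group = group.sort_values("start")
        finite = group[np.isfinite(group["ratio"])]
        if finite.empty:
            continue
        vals = finite["ratio"].to_numpy()
        breaks = cbs_segment(vals, alpha=alpha, n_perm=n_perm, seed=seed)
        edges = [0, *breaks, len(vals)]
        starts = finite["start"].to_numpy()
        ends = finite["end"].to_numpy()
        for a, b in zip(edges[:-1], edges[1:]):
            segments.append(
                CopySegment(
                    chrom=chrom,
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    mean_ratio=float(vals[a:b].mean()),
                    n_windows=b - a,
                )
            )
    return segments


def infer_copy_number(segments: Sequence[CopySegment], purity: float = 1.0) -> None:
    """Attach integer copy-number estimates (diploid-normal assumption),
    inverting the purity mixture when purity is known."""
    for seg in segments:
        mix = 2.0 * (2.0 ** seg.mean_ratio)
        if purity > 0:
            cn = (mix - 2.0 * (1.0 - purity)) / purity
        else:
            cn = mix
        seg.copy_number = float(np.round(max(cn, 0.0)))


# ---------------------------------------------------------------------------
# LAF and event flags


def lesser_allele_fraction(
    het_sites: pd.DataFrame, segments: Sequence[CopySegment]
) -> List[CopySegment]:
    """Mean lesser-allele fraction per segment.

    ``het_sites`` columns: chrom, pos (1-based), a_count, b_count. Sites
    with zero depth are skipped; segments with no usable site keep
    ``laf=None``.
    """
    df = het_sites.copy()
    depth = df["a_count"] + df["b_count"]
    df = df[depth > 0]
    laf = np.minimum(df["a_count"], df["b_count"]) / (df["a_count"] + df["b_count"])
    df = df.assign(laf=laf)
    for seg in segments:
        sel = df[
            (df["chrom"] == seg.chrom)
            & (df["pos"] - 1 >= seg.start)
            & (df["pos"] - 1 < seg.end)
        ]
        seg.laf = float(sel["laf"].mean()) if len(sel) else None
    return list(segments)


def call_loh_and_events(
    segments: Sequence[CopySegment],
    laf_threshold: float = 0.15,
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
) -> List[CopySegment]:
    """Flag LOH (low LAF), gain, and loss per segment; flags independent,
    so copy-neutral LOH is representable."""
    for seg in segments:
        seg.flags = set()
        if seg.laf is not None and seg.laf < laf_threshold:
            seg.flags.add("LOH")
        if seg.mean_ratio >= gain_threshold:
            seg.flags.add("gain")
        if seg.mean_ratio <= loss_threshold:
            seg.flags.add("loss")
    return list(segments)


def segments_to_frame(segments: Sequence[CopySegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_windows": s.n_windows,
                "mean_ratio": s.mean_ratio,
                "copy_number": s.copy_number,
                "laf": s.laf,
                "flags": ",".join(sorted(s.flags)) if s.flags else "",
            }
            for s in segments
        ]
    )


# ---------------------------------------------------------------------------
# focal deletion at fine scale


@dataclass
class FocalDeletionCall:
    chrom: str
    start: int
    end: int
    drop: float  # log2 depth vs flank mean
    exons: List[int]

    @property
    def length(self) -> int:
        return self.end - self.start


def _refine_breakpoint(
    ratio_base: np.ndarray, coarse: int, radius: int
) -> int:
    """Base-level two-mean least-squares changepoint within +-radius."""
    lo = max(1, coarse - radius)
    hi = min(len(ratio_base) - 1, coarse + radius)
    best, best_sse = coarse, np.inf
    x = ratio_base
    for c in range(lo, hi):
        left = x[max(0, coarse - 4 * radius) : c]
        right = x[c : min(len(x), coarse + 4 * radius)]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse = sse
            best = c
    return best


def detect_focal_deletion(
    tumor_base: np.ndarray,
    normal_base: np.ndarray,
    region_start: int,
    gene: GeneModel,
    fine_window: int = 200,
    min_drop: float = 0.4,
    alpha: float = 0.01,
    n_perm: int = 500,
    seed: int = 0,
) -> Optional[FocalDeletionCall]:
    """Detect an internal coverage drop within a gene region.

    Inputs are per-base depths over the region starting at ``region_start``
    (0-based). The series is binned to ``fine_window`` bp, segmented with
    CBS, and a deletion is an internal segment whose mean log2 ratio sits
    at least ``min_drop`` below both flanking segments. Breakpoints are
    then refined to base resolution by a least-squares changepoint fit.
    """
    if len(tumor_base) != len(normal_base):
        raise ValueError("tumor and normal base arrays differ in length")
    n_bases = len(tumor_base)
    if n_bases < 3 * fine_window:
        raise ValueError("region shorter than 3 fine windows")
    n_bins = n_bases // fine_window
    t_bin = tumor_base[: n_bins * fine_window].reshape(n_bins, fine_window).mean(axis=1)
    n_bin = normal_base[: n_bins * fine_window].reshape(n_bins, fine_window).mean(axis=1)
    ratio = np.log2((t_bin + 0.5) / (n_bin + 0.5))
    breaks = cbs_segment(ratio, alpha=alpha, n_perm=n_perm, seed=seed)
    if not breaks:
        return None
    edges = [0, *breaks, n_bins]
    means = [ratio[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    best = None
    for k in range(1, len(means) - 1):
        drop = min(means[k - 1] - means[k], means[k + 1] - means[k])
        if drop >= min_drop and (best is None or means[k] < means[best]):
            best = k
    if best is None:
        return None

    ratio_base = np.log2((tumor_base + 0.5) / (normal_base + 0.5))
    radius = 2 * fine_window
    start_b = _refine_breakpoint(ratio_base, edges[best] * fine_window, radius)
    end_b = _refine_breakpoint(ratio_base, edges[best + 1] * fine_window, radius)
    drop = min(means[best - 1] - means[best], means[best + 1] - means[best])
    abs_start = region_start + start_b
    abs_end = region_start + end_b
    return FocalDeletionCall(
        chrom=gene.chrom,
        start=abs_start,
        end=abs_end,
        drop=float(drop),
        exons=gene.overlapping_exons(abs_start, abs_end),
    )
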