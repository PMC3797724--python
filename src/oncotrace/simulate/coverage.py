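"""Window coverage, heterozygous-site allele counts, and base-level
coverage for a focused region."""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import (
    STREAM_BASECOV,
    STREAM_COVERAGE,
    STREAM_HETS,
    SimConfig,
    copy_state_arrays,
)

COVERAGE_COLUMNS = ["chrom", "start", "end", "sample", "coverage"]
HET_COLUMNS = ["chrom", "pos", "sample", "a_count", "b_count"]


def _window_grid(config: SimConfig) -> pd.DataFrame:
    rows = []
    w = config.window_size
    for chrom, length in config.genome:
        starts = np.arange(0, length, w)
        ends = np.minimum(starts + w, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _cn_mix(config: SimConfig, chrom: str, positions: np.ndarray, purity: float) -> np.ndarray:
    cn, _ = copy_state_arrays(config, chrom, positions)
    return purity * cn + (1.0 - purity) * 2.0


def simulate_coverage(config: SimConfig) -> pd.DataFrame:
    """Mean coverage per fixed-size window per sample.

    Tumor coverage scales with the purity-mixed local copy number
    (evaluated at the window midpoint); the normal is flat diploid. The
    noise model is Poisson read counts per window divided by window length
    in kb, so relative noise shrinks with window size.
    """
    grid = _window_grid(config)
    frames = []
    for s_i, sample in enumerate(config.samples):
        rng = config.rng(STREAM_COVERAGE, s_i)
        out = grid.copy()
        cov = np.empty(len(grid))
        for chrom in grid["chrom"].unique():
            mask = (grid["chrom"] == chrom).to_numpy()
            mids = ((grid.loc[mask, "start"] + grid.loc[mask, "end"]) // 2).to_numpy()
            purity = sample.purity if sample.role == "tumor" else 0.0
            mix = _cn_mix(config, chrom, mids, purity)
            kb = (grid.loc[mask, "end"] - grid.loc[mask, "start"]).to_numpy() / 1000.0
            lam = config.dna_depth * (mix / 2.0) * kb
            cov[mask] = rng.poisson(lam) / kb
        out["sample"] = sample.name
        out["coverage"] = cov
        frames.append(out)
    return pd.concat(frames, ignore_index=True)[COVERAGE_COLUMNS]


def simulate_het_sites(config: SimConfig) -> pd.DataFrame:
    """Tumor allele counts at germline-heterozygous sites.

    Sites are planted every ``het_spacing`` bp. For each tumor sample the
    total depth is Poisson at the local DNA content and the minor-allele
    count is binomial at the purity-mixed allele fraction.
    """
    frames = []
    for chrom, length in config.genome:
        pos = np.arange(config.het_spacing // 2, length, config.het_spacing)
        cn, minor = copy_state_arrays(config, chrom, pos)
        for s_i, sample in enumerate(config.tumor_samples):
            rng = config.rng(STREAM_HETS, s_i, hash(chrom) % (2**31))
            p = sample.purity
            mix_total = p * cn + (1.0 - p) * 2.0
            frac_b = (p * minor + (1.0 - p) * 1.0) / mix_total
            depth = rng.poisson(config.dna_depth * mix_total / 2.0)
            depth = np.maximum(depth, 1)
            b = rng.binomial(depth, frac_b)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos + 1,
                        "sample": sample.name,
                        "a_count": depth - b,
                        "b_count": b,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[HET_COLUMNS]


def simulate_base_coverage(
    config: SimConfig,
    chrom: str,
    start: int,
    end: int,
    samples: Optional[List[str]] = None,
) -> Dict[str, np.ndarray]:
    """Per-base read depth over ``[start, end)`` for the given samples.

    Used for fine-scale focal-deletion analysis; keep the region small
    (tens of kb) — arrays are dense.
    """
    if not 0 <= start < end <= config.chrom_length(chrom):
        raise ValueError(f"region {chrom}:{start}-{end} outside genome bounds")
    names = samples if samples is not None else [s.name for s in config.samples]
    pos = np.arange(start, end)
    out: Dict[str, np.ndarray] = {}
    for name in names:
        sample = config.sample(name)
        s_i = [s.name for s in config.samples].index(name)
        rng = config.rng(STREAM_BASECOV, s_i, start % (2**31))
        purity = sample.purity if sample.role == "tumor" else 0.0
        mix = _cn_mix(config, chrom, pos, purity)
        out[name] = rng.poisson(config.dna_depth * mix / 2.0).astype(float)
    return out
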