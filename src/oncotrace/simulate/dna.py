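"""Per-site DNA allele-count (pileup) simulation for all samples.

Emits records at three kinds of sites: planted somatic mutations (founder
or index-private), recurrent platform artifacts (present in the tumor
samples and in the panel of normals), and background error-only sites used
to measure specificity. Counts are binomial at the expected VAF; depth is
Poisson scaled by the local DNA content.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .config import (
    BASES,
    STREAM_DNA,
    STREAM_PANEL,
    SimConfig,
    TruthTable,
    build_truth,
    copy_state_arrays,
    expected_vaf,
)

PILEUP_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample", "ref_count", "alt_count", "depth",
]


def _site_frame(config: SimConfig, stream_extra: int, n_sites: int) -> pd.DataFrame:
    """Random intergenic-ish sites with ref/alt alleles."""
    rng = config.rng(STREAM_DNA, stream_extra)
    chroms, lengths = zip(*config.genome)
    lengths = np.asarray(lengths, dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_sites, p=lengths / lengths.sum())
    pos = np.array(
        [int(rng.integers(1, config.chrom_length(chroms[i]))) for i in chrom_idx]
    )
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    refs = np.array(BASES)[ref_idx]
    alts = np.array(BASES)[(ref_idx + alt_shift) % 4]
    df = pd.DataFrame(
        {"chrom": [chroms[i] for i in chrom_idx], "pos": pos, "ref": refs, "alt": alts}
    )
    return df.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)


def artifact_sites(config: SimConfig) -> pd.DataFrame:
    """Platform-artifact sites: moderate VAF in every tumor, panel hits > 0."""
    sites = _site_frame(config, 101, config.n_artifact_sites)
    rng = config.rng(STREAM_PANEL)
    sites["panel_hits"] = rng.integers(1, 61, size=len(sites))
    return sites


def make_panel(config: SimConfig) -> Dict[Tuple[str, int, str, str], int]:
    """Panel-of-normals hit counts keyed by (chrom, pos, ref, alt)."""
    arts = artifact_sites(config)
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): int(r.panel_hits)
        for r in arts.itertuples()
    }


def simulate_dna_pileups(config: SimConfig, truth: TruthTable | None = None) -> pd.DataFrame:
    """Pileup table over all samples at mutation, artifact, and background
    sites. Conservation holds by construction: ref + alt = depth."""
    if truth is None:
        truth = build_truth(config)
    arts = artifact_sites(config)
    bg = _site_frame(config, 102, config.n_background_sites)

    frames = []
    for s_i, sample in enumerate(config.samples):
        rng = config.rng(STREAM_DNA, 1000 + s_i)

        def _emit(sites: pd.DataFrame, vafs: np.ndarray) -> pd.DataFrame:
            cn_mix = np.empty(len(sites))
            for chrom in sites["chrom"].unique():
                mask = (sites["chrom"] == chrom).to_numpy()
                cn, _ = copy_state_arrays(
                    config, chrom, sites.loc[mask, "pos"].to_numpy() - 1
                )
                p = sample.purity if sample.role == "tumor" else 0.0
                cn_mix[mask] = p * cn + (1.0 - p) * 2.0
            depth = rng.poisson(config.dna_depth * cn_mix / 2.0)
            depth = np.maximum(depth, 1)
            alt = rng.binomial(depth, np.clip(vafs, config.error_rate, 1.0 - 1e-9))
            out = sites[["chrom", "pos", "ref", "alt"]].copy()
            out["sample"] = sample.name
            out["ref_count"] = depth - alt
            out["alt_count"] = alt
            out["depth"] = depth
            return out

        mut_vaf = truth.mutations[f"vaf_{sample.name}"].to_numpy()
        frames.append(_emit(truth.mutations, mut_vaf))

        art_vaf = np.full(len(arts), 0.30 if sample.role == "tumor" else config.error_rate)
        frames.append(_emit(arts, art_vaf))

        frames.append(_emit(bg, np.full(len(bg), config.error_rate)))

    df = pd.concat(frames, ignore_index=True)[PILEUP_COLUMNS]
    return df.sort_values(["chrom", "pos", "sample"], kind="mergesort").reset_index(
        drop=True
    )
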