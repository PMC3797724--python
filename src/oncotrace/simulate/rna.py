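"""RNA simulation: per-gene read counts and per-variant-site allele counts.

Gene counts are Poisson around expression x exon length x depth; the
mutant-allele read count at a variant site is binomial at the configured
true mutant transcript fraction (error-level in samples that do not carry
the mutation, or when the gene is unexpressed).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import STREAM_RNA, SimConfig, TruthTable, build_truth

GENE_COUNT_COLUMNS = ["gene", "sample", "reads", "exon_length"]
SITE_COUNT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "sample", "alt_count", "depth",
]


def simulate_rna(config: SimConfig, truth: TruthTable | None = None):
    """Returns ``(gene_counts, site_counts)`` DataFrames for the RNA samples."""
    if truth is None:
        truth = build_truth(config)
    rna_samples = config.rna_samples or [s.name for s in config.tumor_samples]
    expr = dict(zip(truth.genes["gene"], truth.genes["expression"]))
    lengths = {g.name: g.exon_length for g in config.gene_models}

    for gene, frac in config.true_mutant_rna_fractions.items():
        if frac > 0 and expr.get(gene, 0.0) == 0.0:
            warnings.warn(
                f"mutant RNA fraction set for unexpressed gene {gene}; counts will be 0"
            )

    gene_frames = []
    site_frames = []
    muts = truth.mutations
    for s_i, name in enumerate(rna_samples):
        rng = config.rng(STREAM_RNA, s_i)
        genes = truth.genes["gene"].to_numpy()
        lam = np.array(
            [expr[g] * (lengths[g] / 1000.0) * config.rna_depth for g in genes]
        )
        reads = rng.poisson(lam)
        gene_frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "sample": name,
                    "reads": reads,
                    "exon_length": [lengths[g] for g in genes],
                }
            )
        )

        carried = muts[f"vaf_{name}"].to_numpy() > 0
        site_lam = np.array([expr.get(g, 0.0) * config.rna_site_depth for g in muts["gene"]])
        depth = rng.poisson(site_lam)
        frac = np.where(
            carried,
            [config.true_mutant_rna_fractions.get(g, 0.0) for g in muts["gene"]],
            0.0,
        )
        frac = np.clip(frac, config.error_rate, 1.0 - 1e-9)
        alt = rng.binomial(depth, frac)
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": muts["chrom"],
                    "pos": muts["pos"],
                    "ref": muts["ref"],
                    "alt": muts["alt"],
                    "gene": muts["gene"],
                    "sample": name,
                    "alt_count": alt,
                    "depth": depth,
                }
            )
        )
    gene_counts = pd.concat(gene_frames, ignore_index=True)[GENE_COUNT_COLUMNS]
    site_counts = pd.concat(site_frames, ignore_index=True)[SITE_COUNT_COLUMNS]
    return gene_counts, site_counts
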