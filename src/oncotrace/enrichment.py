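"""Perturbation-response ranking and gene-permutation set enrichment.

The per-gene response statistic is the differential change in expression:
CE_T = log2 X_T - log2 X_0 within a condition, and DCE_T = CE(mt) - CE(wt).
Genes ranked by decreasing DCE feed a weighted Kolmogorov-Smirnov
enrichment score whose null is built from random gene-label permutations
(random same-size gene sets), with NES normalization by the signed null
means and a standard NES-ratio FDR estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def change_in_expression(matrix: pd.DataFrame, condition: str, timepoint: int) -> pd.Series:
    """CE_T = log2 X_T - log2 X_0 per gene for one condition."""
    if timepoint not in (1, 2):
        raise ValueError("timepoint must be 1 or 2")
    col_t = f"{condition}_{timepoint}h"
    col_0 = f"{condition}_0h"
    for col in (col_t, col_0):
        if col not in matrix.columns:
            raise KeyError(f"column {col!r} missing from expression matrix")
        if (matrix[col] <= 0).any():
            raise ValueError("expression values must be strictly positive")
    return np.log2(matrix[col_t]) - np.log2(matrix[col_0])


def differential_change(ce_mt: pd.Series, ce_wt: pd.Series) -> pd.Series:
    """DCE_T = CE_mt,T - CE_wt,T (elementwise over a shared gene universe)."""
    if set(ce_mt.index) != set(ce_wt.index):
        raise ValueError("gene universes differ between conditions")
    return ce_mt - ce_wt.reindex(ce_mt.index)


def rank_genes(dce: pd.Series) -> pd.Series:
    """Decreasing DCE; ties broken by gene identifier."""
    df = dce.rename("dce").rename_axis("gene").reset_index()
    df = df.sort_values(["dce", "gene"], ascending=[False, True], kind="mergesort")
    return df.set_index("gene")["dce"]


@dataclass
class EnrichmentResult:
    set_id: str
    size: int
    es: float
    nes: float
    pvalue: float
    fdr: float


# ---------------------------------------------------------------------------
# enrichment score


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Signed max-deviation enrichment score for each row of hit positions.

    ``pos``: (m, k) integer positions of set members in the ranked list
    (need not be sorted); ``weights``: per-rank hit weights (already
    |score|^p). The running sum rises by the normalized hit weight at each
    member and falls by 1/(n-k) elsewhere; extremes are attained at the
    member positions, so only those need evaluation.
    """
    pos = np.sort(pos, axis=1)
    m, k = pos.shape
    w = weights[pos]
    totals = w.sum(axis=1, keepdims=True)
    uniform = totals == 0
    w = np.where(uniform, 1.0 / k, w / np.where(totals == 0, 1.0, totals))
    hit_cum = np.cumsum(w, axis=1)
    miss = 1.0 / (n - k)
    j = np.arange(1, k + 1)
    dev_after = hit_cum - (pos + 1 - j) * miss
    dev_before = (hit_cum - w) - (pos - (j - 1)) * miss
    es_pos = dev_after.max(axis=1)
    es_neg = dev_before.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def enrichment_score(
    ranked: pd.Series, members: Set[str], p: float = 1.0
) -> float:
    """ES of one gene set in a ranked list (descending scores)."""
    genes = ranked.index.to_numpy()
    weights = np.abs(ranked.to_numpy()) ** p
    idx = {g: i for i, g in enumerate(genes)}
    pos = np.array([[idx[g] for g in members if g in idx]])
    if pos.size == 0:
        raise ValueError("gene set has no members in the universe")
    return float(_es_from_positions(pos, weights, len(genes))[0])


def _null_positions(
    n: int, k: int, n_perm: int, rng: np.random.Generator, chunk: int = 2000
) -> np.ndarray:
    """(n_perm, k) random distinct position rows (gene-label permutation)."""
    out = np.empty((n_perm, k), dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n))
        out[done : done + b] = np.argpartition(keys, k, axis=1)[:, :k]
        done += b
    return out


def gsea_permutation(
    ranked: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 10_000,
    p: float = 1.0,
    min_size: int = 15,
    seed: int = 0,
) -> List[EnrichmentResult]:
    """Gene-permutation enrichment over a collection of gene sets.

    For each set the null ES distribution comes from ``n_perm`` random
    same-size gene sets; NES divides ES by the mean |null ES| of matching
    sign; p-values carry the +1 permutation correction; FDR is the
    standard NES-based ratio estimate pooled across sets of the same sign.
    """
    genes = ranked.index.to_numpy()
    n = len(genes)
    weights = np.abs(ranked.to_numpy()) ** p
    idx = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    observed: List[Tuple[str, int, float]] = []
    null_cache: Dict[int, np.ndarray] = {}
    for set_id, members in gene_sets.items():
        pos = np.array(sorted({idx[g] for g in members if g in idx}))
        if pos.size == 0:
            logger.info("gene set %s has no members in the universe; skipped", set_id)
            continue
        if pos.size < min_size:
            logger.info(
                "gene set %s below min size (%d < %d); skipped",
                set_id, pos.size, min_size,
            )
            continue
        es = float(_es_from_positions(pos[None, :], weights, n)[0])
        observed.append((set_id, int(pos.size), es))

    results: List[EnrichmentResult] = []
    all_null_nes: List[np.ndarray] = []
    nes_obs: List[float] = []
    pvals: List[float] = []
    for set_id, k, es in observed:
        if k not in null_cache:
            null_pos = _null_positions(n, k, n_perm, rng)
            null_cache[k] = _es_from_positions(null_pos, weights, n)
        null = null_cache[k]
        pos_mean = null[null > 0].mean() if np.any(null > 0) else 1.0
        neg_mean = -null[null < 0].mean() if np.any(null < 0) else 1.0
        nes = es / pos_mean if es >= 0 else es / neg_mean
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        # one-sided tail among same-signed nulls (keeps null p uniform),
        # with the +1 permutation correction
        if es >= 0:
            n_side = int(np.sum(null >= 0))
            pval = (1 + int(np.sum(null >= es))) / (1 + max(n_side, 1))
        else:
            n_side = int(np.sum(null < 0))
            pval = (1 + int(np.sum(null <= es))) / (1 + max(n_side, 1))
        pval = min(pval, 1.0)
        nes_obs.append(float(nes))
        pvals.append(float(pval))
        all_null_nes.append(null_nes)

    # NES-ratio FDR, sign-pooled
    fdrs = []
    null_pool = np.concatenate(all_null_nes) if all_null_nes else np.array([])
    nes_arr = np.array(nes_obs)
    for nes in nes_obs:
        if nes >= 0:
            null_frac_den = np.mean(null_pool >= 0) or 1.0
            null_frac = np.mean(null_pool >= nes) / null_frac_den
            obs_den = np.mean(nes_arr >= 0) or 1.0
            obs_frac = np.mean(nes_arr >= nes) / obs_den
        else:
            null_frac_den = np.mean(null_pool < 0) or 1.0
            null_frac = np.mean(null_pool <= nes) / null_frac_den
            obs_den = np.mean(nes_arr < 0) or 1.0
            obs_frac = np.mean(nes_arr <= nes) / obs_den
        fdrs.append(min(1.0, float(null_frac / obs_frac)) if obs_frac > 0 else 1.0)

    for (set_id, k, es), nes, pval, fdr in zip(observed, nes_obs, pvals, fdrs):
        results.append(
            EnrichmentResult(
                set_id=set_id, size=k, es=es, nes=nes, pvalue=pval, fdr=fdr
            )
        )
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ID": r.set_id,
                "Size": r.size,
                "ES": r.es,
                "NES": r.nes,
                "p-value": r.pvalue,
                "FDR": r.fdr,
            }
            for r in results
        ]
    )
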