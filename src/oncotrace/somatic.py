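"""Somatic small-variant calling from paired tumor/normal pileups.

The somatic score is a base-10 log likelihood ratio of binomial models:
the alternative (tumor at its observed variant fraction, normal at the
error rate) against the better of two nulls — germline heterozygous
(normal at VAF 0.5; the tumor fraction is left free, since copy-number
change moves germline VAF in tumors) or sequencing error in both samples.
Leaving the tumor fraction free under the germline null also makes the
score non-decreasing in tumor variant count when the normal is clean.
Positive scores favor a somatic event; the calling threshold is
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import log
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genome import GeneModel, translate_codon

logger = logging.getLogger(__name__)

LN10 = log(10.0)

Site = Tuple[str, int, str, str]  # chrom, 1-based pos, ref, alt

ANNOTATIONS = (
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "frameshift",
    "non-coding",
)


@dataclass
class SomaticVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    score: float
    tumor_vaf: float
    normal_vaf: float
    panel_hits: int = 0
    annotation: str = "non-coding"
    gene: str = ""

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PanelOfNormals:
    """Recurrent-variant counts across a panel of unrelated germline genomes."""

    hits: Dict[Site, int] = field(default_factory=dict)
    size: int = 119

    def __post_init__(self) -> None:
        for site, count in self.hits.items():
            if not 0 <= count <= self.size:
                raise ValueError(f"panel count {count} at {site} exceeds panel size")

    def count(self, site: Site) -> int:
        return self.hits.get(site, 0)

    @classmethod
    def from_table(cls, df: pd.DataFrame, size: int = 119) -> "PanelOfNormals":
        hits = {
            (r.chrom, int(r.pos), r.ref, r.alt): int(r.hits) for r in df.itertuples()
        }
        return cls(hits=hits, size=size)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "pos": p, "ref": r, "alt": a, "hits": n}
            for (c, p, r, a), n in sorted(self.hits.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "hits"])


# ---------------------------------------------------------------------------
# scoring


def somatic_score(
    tumor_alt: int,
    tumor_depth: int,
    normal_alt: int,
    normal_depth: int,
    error_rate: float = 0.01,
) -> float:
    """log10 likelihood ratio of the somatic model vs the best null."""
    arr = somatic_score_array(
        np.array([tumor_alt]),
        np.array([tumor_depth]),
        np.array([normal_alt]),
        np.array([normal_depth]),
        error_rate,
    )
    return float(arr[0])


def somatic_score_array(
    tumor_alt: np.ndarray,
    tumor_depth: np.ndarray,
    normal_alt: np.ndarray,
    normal_depth: np.ndarray,
    error_rate: float = 0.01,
) -> np.ndarray:
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    tumor_depth = np.asarray(tumor_depth)
    normal_depth = np.asarray(normal_depth)
    if np.any(tumor_depth <= 0) or np.any(normal_depth <= 0):
        raise ValueError("zero-depth site: somatic score undefined")
    e = error_rate
    mhat = np.maximum(tumor_alt / tumor_depth, e)
    l_somatic = binom.logpmf(tumor_alt, tumor_depth, mhat) + binom.logpmf(
        normal_alt, normal_depth, e
    )
    l_germline = binom.logpmf(tumor_alt, tumor_depth, mhat) + binom.logpmf(
        normal_alt, normal_depth, 0.5
    )
    l_error = binom.logpmf(tumor_alt, tumor_depth, e) + binom.logpmf(
        normal_alt, normal_depth, e
    )
    return (l_somatic - np.maximum(l_germline, l_error)) / LN10


# ---------------------------------------------------------------------------
# calling


def call_somatic(
    pileups: pd.DataFrame,
    tumor: str,
    normal: str,
    threshold: float = 5.0,
    min_depth: int = 10,
    error_rate: float = 0.01,
) -> List[SomaticVariant]:
    """Score every site with paired counts and return those at or above
    ``threshold`` with at least ``min_depth`` in both samples, sorted by
    (chrom, pos, ref, alt) and duplicate-free.
    """
    if pileups.empty:
        return []
    samples = set(pileups["sample"].unique())
    if normal not in samples:
        raise ValueError(f"normal sample {normal!r} missing from pileup table")
    if tumor not in samples:
        raise ValueError(f"tumor sample {tumor!r} missing from pileup table")
    t = pileups[pileups["sample"] == tumor]
    n = pileups[pileups["sample"] == normal]
    key = ["chrom", "pos", "ref", "alt"]
    merged = t.merge(n, on=key, suffixes=("_t", "_n"))
    if merged.empty:
        return []
    deep = merged[
        (merged["depth_t"] >= min_depth) & (merged["depth_n"] >= min_depth)
    ].copy()
    if deep.empty:
        return []
    scores = somatic_score_array(
        deep["alt_count_t"].to_numpy(),
        deep["depth_t"].to_numpy(),
        deep["alt_count_n"].to_numpy(),
        deep["depth_n"].to_numpy(),
        error_rate,
    )
    deep["score"] = scores
    hits = deep[deep["score"] >= threshold]
    variants = [
        SomaticVariant(
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            score=float(r.score),
            tumor_vaf=float(r.alt_count_t / r.depth_t),
            normal_vaf=float(r.alt_count_n / r.depth_n),
        )
        for r in hits.itertuples()
    ]
    variants.sort(key=lambda v: v.site)
    seen = set()
    unique = []
    for v in variants:
        if v.site not in seen:
            seen.add(v.site)
            unique.append(v)
    return unique


def filter_against_panel(
    variants: Sequence[SomaticVariant],
    panel: PanelOfNormals,
    max_hits: int = 0,
) -> List[SomaticVariant]:
    """Drop variants recurrent in the panel of normals; annotate hit counts."""
    kept = []
    for v in variants:
        v.panel_hits = panel.count(v.site)
        if v.panel_hits > max_hits:
            logger.info(
                "panel_fail %s:%d %s>%s seen in %d/%d panel genomes",
                v.chrom, v.pos, v.ref, v.alt, v.panel_hits, panel.size,
            )
            continue
        kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# coding annotation


def annotate_coding(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene_models: Iterable[GeneModel],
    coding_seqs: Mapping[str, str],
    codon_table: int = 1,
) -> Tuple[str, str]:
    """Classify a variant's coding effect. Returns (annotation, gene name).

    SNVs are translated through the gene's codon frame; indels are
    classified by length modulo 3 (in-frame coding indels are reported as
    nonsynonymous). Positions outside every exon are non-coding.
    """
    if ref == alt:
        raise ValueError("variant allele equals reference")
    pos0 = pos - 1
    for gene in gene_models:
        if gene.chrom != chrom:
            continue
        cidx = gene.coding_index(pos0)
        if cidx is None:
            continue
        if len(ref) != len(alt):
            shift = abs(len(ref) - len(alt))
            return ("frameshift" if shift % 3 else "nonsynonymous", gene.name)
        if len(ref) > 1:  # multi-base substitution: treat as nonsynonymous
            return ("nonsynonymous", gene.name)
        seq = coding_seqs[gene.name]
        alt_coding = alt if gene.strand == "+" else _COMP[alt]
        codon_start = ((cidx - gene.frame) // 3) * 3 + gene.frame
        if codon_start < 0 or codon_start + 3 > len(seq):
            return ("non-coding", gene.name)
        codon = seq[codon_start : codon_start + 3]
        mut = list(codon)
        mut[cidx - codon_start] = alt_coding
        aa_ref = translate_codon(codon, codon_table)
        aa_alt = translate_codon("".join(mut), codon_table)
        if aa_alt == aa_ref:
            return ("synonymous", gene.name)
        if aa_alt == "*":
            return ("stopgain", gene.name)
        return ("nonsynonymous", gene.name)
    return ("non-coding", "")


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def annotate_variants(
    variants: Sequence[SomaticVariant],
    gene_models: Sequence[GeneModel],
    coding_seqs: Mapping[str, str],
) -> List[SomaticVariant]:
    for v in variants:
        v.annotation, v.gene = annotate_coding(
            v.chrom, v.pos, v.ref, v.alt, gene_models, coding_seqs
        )
    return list(variants)


def mutation_rate_per_mb(n_nonsyn: int, footprint_mb: float) -> float:
    """Non-synonymous mutations per megabase of interrogated footprint."""
    if footprint_mb <= 0:
        raise ValueError("footprint must be > 0")
    return n_nonsyn / footprint_mb


# ---------------------------------------------------------------------------
# VCF output


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=oncotrace
{contigs}##INFO=<ID=SS,Number=1,Type=Float,Description="Somatic score (log10 likelihood ratio)">
##INFO=<ID=TVAF,Number=1,Type=Float,Description="Tumor variant allele fraction">
##INFO=<ID=NVAF,Number=1,Type=Float,Description="Normal variant allele fraction">
##INFO=<ID=PANEL_N,Number=1,Type=Integer,Description="Panel-of-normals genomes carrying the variant">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=ANN,Number=1,Type=String,Description="Coding annotation">
##FILTER=<ID=panel_fail,Description="Recurrent in the panel of normals">
##FILTER=<ID=low_depth,Description="Insufficient depth in tumor or normal">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(
    variants: Sequence[SomaticVariant],
    path: str,
    contigs: Optional[Sequence[Tuple[str, int]]] = None,
    filters: Optional[Mapping[Site, str]] = None,
) -> None:
    contig_lines = ""
    if contigs:
        contig_lines = "".join(
            f"##contig=<ID={name},length={length}>\n" for name, length in contigs
        )
    filters = filters or {}
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contig_lines))
        for v in sorted(variants, key=lambda v: v.site):
            info = (
                f"SS={v.score:.4f};TVAF={v.tumor_vaf:.4f};NVAF={v.normal_vaf:.4f};"
                f"PANEL_N={v.panel_hits}"
            )
            if v.gene:
                info += f";GENE={v.gene}"
            info += f";ANN={v.annotation}"
            flt = filters.get(v.site, "PASS")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{flt}\t{info}\n"
            )


def read_vcf(path: str) -> List[SomaticVariant]:
    """Read back a VCF written by :func:`write_vcf` (PASS records only)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, flt, info = line.rstrip("\n").split("\t")[:8]
            if flt not in ("PASS", "."):
                continue
            fields = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            out.append(
                SomaticVariant(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    score=float(fields.get("SS", "nan")),
                    tumor_vaf=float(fields.get("TVAF", "nan")),
                    normal_vaf=float(fields.get("NVAF", "nan")),
                    panel_hits=int(fields.get("PANEL_N", 0)),
                    annotation=fields.get("ANN", "non-coding"),
                    gene=fields.get("GENE", ""),
                )
            )
    return out
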