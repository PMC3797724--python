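"""DNA+RNA integration: RPKM, mutant-allele transcript fraction, and the
expressed-driver classification of mutated genes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

CLASSES = (
    "expressed-driver-candidate",
    "expressed-low-fraction",
    "mutant-not-detected",
    "gene-not-expressed",
)


def rpkm(reads: int, exon_length: int, total_mapped: int) -> float:
    """Reads per kilobase of exon per million mapped reads."""
    if exon_length <= 0:
        raise ValueError("exon length must be > 0")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be > 0")
    return 1e9 * reads / (exon_length * total_mapped)


def mutant_fraction(
    variant_reads: int, total_reads: int, min_site_depth: int = 5
) -> Optional[float]:
    """RNA mutant-allele fraction, or None below the depth floor."""
    if total_reads < min_site_depth:
        return None
    return variant_reads / total_reads


def rpkm_table(gene_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample RPKM from a long table (gene, sample, reads, exon_length).

    Total mapped reads are taken per sample across all genes in the table.
    """
    out = gene_counts.copy()
    totals = out.groupby("sample")["reads"].transform("sum")
    out["rpkm"] = [
        rpkm(int(r), int(l), int(t))
        for r, l, t in zip(out["reads"], out["exon_length"], totals)
    ]
    return out


def fraction_table(site_counts: pd.DataFrame, min_site_depth: int = 5) -> pd.DataFrame:
    """Per (site, sample) RNA mutant fraction from alt_count/depth columns."""
    out = site_counts.copy()
    out["fraction"] = [
        mutant_fraction(int(a), int(d), min_site_depth)
        for a, d in zip(out["alt_count"], out["depth"])
    ]
    return out


@dataclass
class ExpressedVariantReport:
    gene: str
    label: str  # temporal label: shared / private-to-index / ...
    rpkm: Dict[str, float] = field(default_factory=dict)
    fraction: Dict[str, Optional[float]] = field(default_factory=dict)
    klass: str = "gene-not-expressed"


def classify_driver_candidates(
    rpkms: pd.DataFrame,
    fractions: pd.DataFrame,
    labels: Dict[str, str],
    required_samples: Sequence[str],
    rpkm_min: float = 1.0,
    fraction_min: float = 0.30,
    mode: str = "all",
) -> List[ExpressedVariantReport]:
    """Assign each mutated gene exactly one expression class.

    gene-not-expressed: RPKM below ``rpkm_min`` in a required sample;
    mutant-not-detected: no required sample has a defined, non-zero
    fraction; expressed-low-fraction: mutant reads seen but the fraction
    condition (> ``fraction_min``) fails; expressed-driver-candidate: the
    gene is expressed and the fraction condition holds in all (or, with
    ``mode='any'``, at least one) required samples.
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    rp = rpkms.set_index(["gene", "sample"])["rpkm"]
    fr = fractions.set_index(["gene", "sample"])["fraction"]
    reports = []
    for gene, label in labels.items():
        r: Dict[str, float] = {}
        f: Dict[str, Optional[float]] = {}
        for s in required_samples:
            if (gene, s) not in rp.index:
                raise ValueError(f"required sample {s!r} absent for gene {gene!r}")
            r[s] = float(rp.loc[(gene, s)])
            val = fr.loc[(gene, s)] if (gene, s) in fr.index else None
            f[s] = None if pd.isna(val) else float(val)
        expressed = all(r[s] >= rpkm_min for s in required_samples)
        defined = [f[s] for s in required_samples if f[s] is not None]
        cond = [f[s] is not None and f[s] > fraction_min for s in required_samples]
        hit = all(cond) if mode == "all" else any(cond)
        if not expressed:
            klass = "gene-not-expressed"
        elif hit:
            klass = "expressed-driver-candidate"
        elif any(v > 0 for v in defined):
            klass = "expressed-low-fraction"
        else:
            klass = "mutant-not-detected"
        reports.append(
            ExpressedVariantReport(
                gene=gene, label=label, rpkm=r, fraction=f, klass=klass
            )
        )
    return reports


def report_frame(reports: Sequence[ExpressedVariantReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        row = {"gene": rep.gene, "label": rep.label, "class": rep.klass}
        for s, v in rep.rpkm.items():
            row[f"rpkm_{s}"] = v
        for s, v in rep.fraction.items():
            row[f"fraction_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
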