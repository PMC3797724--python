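"""Configuration and ground truth for the multi-sample tumor simulator.

One :class:`SimConfig` (with one integer seed) determines every output
byte-for-byte: DNA pileups, window coverage, heterozygous-site counts,
structural junctions, RNA counts, and the perturbation expression matrix.
Sub-generators derive independent RNG streams from the global seed so each
output is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..genome import GeneModel

# Fixed stream ids for sub-seeding; changing these changes all outputs.
STREAM_SEQ = 1
STREAM_DNA = 2
STREAM_COVERAGE = 3
STREAM_HETS = 4
STREAM_JUNCTIONS = 5
STREAM_RNA = 6
STREAM_PERTURB = 7
STREAM_PANEL = 8
STREAM_TRUTH = 9
STREAM_BASECOV = 10

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Sample:
    name: str
    role: str  # "normal" | "tumor"
    timepoint: str
    purity: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("normal", "tumor"):
            raise ValueError(f"unknown role {self.role!r}")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0,1], got {self.purity}")


@dataclass(frozen=True)
class PloidyRegion:
    """Tumor copy state over a genomic interval (pure-tumor values)."""

    chrom: str
    start: int
    end: int
    cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty ploidy region")
        if not 0 <= self.minor_cn * 2 <= self.cn * 2 or self.minor_cn > self.cn:
            raise ValueError("minor_cn must be in [0, cn]")


@dataclass(frozen=True)
class FocalDeletion:
    chrom: str
    start: int
    end: int
    gene: str
    cn_inside: int = 2
    minor_inside: int = 1


@dataclass(frozen=True)
class ChromothripsisRegion:
    chrom: str
    start: int
    end: int
    n_junctions: int
    cn_states: Tuple[int, int] = (4, 2)
    n_oscillations: int = 10  # number of alternating blocks


@dataclass
class SimConfig:
    seed: int
    genome: List[Tuple[str, int]]
    gene_models: List[GeneModel]
    samples: List[Sample]
    n_founder_mutations: int = 15
    n_private_mutations: int = 30
    n_artifact_sites: int = 20
    n_background_sites: int = 5000
    dna_depth: float = 100.0
    rna_depth: float = 30.0
    rna_site_depth: float = 20.0
    error_rate: float = 0.01
    window_size: int = 100_000
    het_spacing: int = 20_000
    baseline_cn: Tuple[int, int] = (4, 2)  # (total, minor) outside profile
    ploidy_profile: List[PloidyRegion] = field(default_factory=list)
    focal_deletion: Optional[FocalDeletion] = None
    chromothripsis_region: Optional[ChromothripsisRegion] = None
    true_mutant_rna_fractions: Dict[str, float] = field(default_factory=dict)
    rna_samples: List[str] = field(default_factory=list)
    # perturbation experiment
    n_perturb_genes: int = 2000
    responsive_genes: List[str] = field(default_factory=list)
    effect_size: float = 4.0
    perturb_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        lengths = dict(self.genome)
        for name, length in self.genome:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.dna_depth <= 0 or self.rna_depth <= 0:
            raise ValueError("depths must be > 0")
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must be in (0, 0.5)")
        for frac in self.true_mutant_rna_fractions.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError("mutant RNA fractions must be in [0,1]")
        for region in self.ploidy_profile:
            if region.chrom not in lengths or region.end > lengths[region.chrom]:
                raise ValueError(f"ploidy region outside genome: {region}")
        if self.focal_deletion is not None:
            fd = self.focal_deletion
            if fd.chrom not in lengths or fd.end > lengths[fd.chrom]:
                raise ValueError("focal deletion outside genome bounds")
        if self.chromothripsis_region is not None:
            ct = self.chromothripsis_region
            if ct.chrom not in lengths or ct.end > lengths[ct.chrom]:
                raise ValueError("chromothripsis region outside genome bounds")

    # -- RNG plumbing ------------------------------------------------------
    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, *extra])

    @property
    def tumor_samples(self) -> List[Sample]:
        return [s for s in self.samples if s.role == "tumor"]

    @property
    def normal_sample(self) -> Sample:
        normals = [s for s in self.samples if s.role == "normal"]
        if not normals:
            raise ValueError("config declares no normal sample")
        return normals[0]

    def sample(self, name: str) -> Sample:
        for s in self.samples:
            if s.name == name:
                return s
        raise KeyError(name)

    def chrom_length(self, chrom: str) -> int:
        return dict(self.genome)[chrom]


# ---------------------------------------------------------------------------
# copy-state resolution


def copy_state_arrays(
    config: SimConfig, chrom: str, positions: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Pure-tumor (total, minor) copy number at each position.

    Overlay order: baseline < ploidy_profile < chromothripsis oscillation
    < focal deletion. Later layers win.
    """
    positions = np.asarray(positions)
    cn = np.full(positions.shape, config.baseline_cn[0], dtype=float)
    minor = np.full(positions.shape, config.baseline_cn[1], dtype=float)
    for region in config.ploidy_profile:
        if region.chrom != chrom:
            continue
        mask = (positions >= region.start) & (positions < region.end)
        cn[mask] = region.cn
        minor[mask] = region.minor_cn
    ct = config.chromothripsis_region
    if ct is not None and ct.chrom == chrom:
        block = (ct.end - ct.start) / ct.n_oscillations
        inside = (positions >= ct.start) & (positions < ct.end)
        idx = np.floor((positions[inside] - ct.start) / block).astype(int)
        idx = np.clip(idx, 0, ct.n_oscillations - 1)
        state = np.where(idx % 2 == 0, ct.cn_states[0], ct.cn_states[1])
        cn[inside] = state
        minor[inside] = state // 2
    fd = config.focal_deletion
    if fd is not None and fd.chrom == chrom:
        mask = (positions >= fd.start) & (positions < fd.end)
        cn[mask] = fd.cn_inside
        minor[mask] = fd.minor_inside
    return cn, minor


def resolved_copy_map(config: SimConfig) -> pd.DataFrame:
    """Elementary constant-copy-state segments for the whole genome."""
    rows = []
    for chrom, length in config.genome:
        cuts = {0, length}
        for region in config.ploidy_profile:
            if region.chrom == chrom:
                cuts.update((region.start, region.end))
        ct = config.chromothripsis_region
        if ct is not None and ct.chrom == chrom:
            block = (ct.end - ct.start) / ct.n_oscillations
            cuts.update(
                int(round(ct.start + i * block)) for i in range(ct.n_oscillations + 1)
            )
        fd = config.focal_deletion
        if fd is not None and fd.chrom == chrom:
            cuts.update((fd.start, fd.end))
        edges = sorted(c for c in cuts if 0 <= c <= length)
        mids = np.array([(a + b) // 2 for a, b in zip(edges[:-1], edges[1:])])
        cn, minor = copy_state_arrays(config, chrom, mids)
        prev = None
        for (a, b), c, m in zip(zip(edges[:-1], edges[1:]), cn, minor):
            if prev is not None and prev["cn"] == c and prev["minor_cn"] == m:
                prev["end"] = b
                continue
            prev = {"chrom": chrom, "start": a, "end": b, "cn": c, "minor_cn": m}
            rows.append(prev)
    return pd.DataFrame(rows)


def expected_ratio(cn: float, purity: float) -> float:
    """Expected coverage log2 ratio vs a diploid normal."""
    mix = purity * cn + (1.0 - purity) * 2.0
    return float(np.log2(mix / 2.0))


def expected_laf(cn: float, minor: float, purity: float) -> float:
    """Expected lesser allele fraction at a germline-het site."""
    mix_minor = purity * minor + (1.0 - purity) * 1.0
    mix_total = purity * cn + (1.0 - purity) * 2.0
    frac = mix_minor / mix_total
    return float(min(frac, 1.0 - frac))


def expected_vaf(cn: float, mutant_copies: float, purity: float) -> float:
    """Expected somatic VAF given local copy number and purity."""
    return float(purity * mutant_copies / (purity * cn + (1.0 - purity) * 2.0))


# ---------------------------------------------------------------------------
# per-gene coding sequences (deterministic in the seed)


def coding_sequences(config: SimConfig) -> Dict[str, str]:
    """Spliced coding sequence per gene, drawn from the seeded stream."""
    seqs: Dict[str, str] = {}
    for i, gene in enumerate(config.gene_models):
        rng = config.rng(STREAM_SEQ, i)
        seqs[gene.name] = "".join(rng.choice(BASES, size=gene.exon_length))
    return seqs


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class TruthTable:
    """Planted events with their per-sample expectations."""

    mutations: pd.DataFrame  # chrom,pos,ref,alt,gene,label + vaf_<sample>
    segments: pd.DataFrame  # chrom,start,end,cn,minor_cn
    genes: pd.DataFrame  # gene,expression,mutant_rna_fraction

    def expected_segment_values(self, purity: float) -> pd.DataFrame:
        out = self.segments.copy()
        out["ratio"] = [expected_ratio(c, purity) for c in out["cn"]]
        out["laf"] = [
            expected_laf(c, m, purity) for c, m in zip(out["cn"], out["minor_cn"])
        ]
        return out


def _mutation_sites(config: SimConfig) -> pd.DataFrame:
    """Choose exonic sites for founder and private mutations.

    Founders occupy the first ``n_founder`` genes, private mutations the
    next ``n_private`` genes, one SNV each, placed mid-gene.
    """
    n_total = config.n_founder_mutations + config.n_private_mutations
    coding_genes = [g for g in config.gene_models if g.strand == "+"]
    if len(coding_genes) < n_total:
        raise ValueError(
            f"need {n_total} '+'-strand genes for mutations, have {len(coding_genes)}"
        )
    seqs = coding_sequences(config)
    rng = config.rng(STREAM_TRUTH)
    rows = []
    for i in range(n_total):
        gene = coding_genes[i]
        label = "founder" if i < config.n_founder_mutations else "private"
        # middle exon, offset clear of the exon edges
        exon_i = len(gene.exons) // 2
        start, end = gene.exons[exon_i]
        offset = int(rng.integers(3, end - start - 3))
        pos0 = start + offset
        cidx = gene.coding_index(pos0)
        ref = seqs[gene.name][cidx]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        rows.append(
            {
                "chrom": gene.chrom,
                "pos": pos0 + 1,  # 1-based
                "ref": ref,
                "alt": alt,
                "gene": gene.name,
                "label": label,
            }
        )
    return pd.DataFrame(rows)


def build_truth(config: SimConfig) -> TruthTable:
    muts = _mutation_sites(config)
    cn, minor = zip(
        *(
            tuple(
                np.concatenate(
                    copy_state_arrays(config, row.chrom, np.array([row.pos - 1]))
                )
            )
            for row in muts.itertuples()
        )
    )
    muts["cn"] = cn
    muts["minor_cn"] = minor
    muts["mutant_copies"] = np.maximum(1, np.round(muts["cn"] / 2.0))
    for sample in config.samples:
        if sample.role == "normal":
            muts[f"vaf_{sample.name}"] = 0.0
            continue
        carries = (
            np.ones(len(muts), dtype=bool)
            if sample.name == _index_tumor(config).name
            else (muts["label"] == "founder").to_numpy()
        )
        vafs = np.where(
            carries,
            [
                expected_vaf(c, m, sample.purity)
                for c, m in zip(muts["cn"], muts["mutant_copies"])
            ],
            0.0,
        )
        muts[f"vaf_{sample.name}"] = vafs

    segments = resolved_copy_map(config)

    rng = config.rng(STREAM_TRUTH, 1)
    gene_rows = []
    for gene in config.gene_models:
        expr = float(np.round(rng.lognormal(mean=2.5, sigma=0.7), 3))
        # genes planted with a high mutant transcript fraction are kept well
        # expressed so the fraction estimate is not depth-starved
        if config.true_mutant_rna_fractions.get(gene.name, 0.0) >= 0.3:
            expr = max(expr, 20.0)
        gene_rows.append(
            {
                "gene": gene.name,
                "expression": expr,
                "mutant_rna_fraction": config.true_mutant_rna_fractions.get(
                    gene.name, 0.0
                ),
            }
        )
    genes = pd.DataFrame(gene_rows)
    return TruthTable(mutations=muts, segments=segments, genes=genes)


def _index_tumor(config: SimConfig) -> Sample:
    """The latest tumor sample: carrier of private mutations."""
    return config.tumor_samples[-1]


# ---------------------------------------------------------------------------
# default configuration


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-serializable view of a configuration (for provenance)."""
    d = asdict(config)
    d["gene_models"] = [
        {"name": g.name, "chrom": g.chrom, "strand": g.strand,
         "exons": [list(e) for e in g.exons], "frame": g.frame}
        for g in config.gene_models
    ]
    d["genome"] = [list(x) for x in d["genome"]]
    return d


def _grid_gene(name: str, chrom: str, start: int, n_exons: int = 5,
               exon_len: int = 300, intron_len: int = 2000) -> GeneModel:
    exons = tuple(
        (start + i * (exon_len + intron_len), start + i * (exon_len + intron_len) + exon_len)
        for i in range(n_exons)
    )
    return GeneModel(name=name, chrom=chrom, strand="+", exons=exons)


def deletion_target_gene() -> GeneModel:
    """A 15-exon gene on the large contig whose exons 10-12 sit inside the
    planted focal deletion (76,916,706-76,932,433)."""
    exon_len = 200
    starts = [
        76_880_000, 76_884_000, 76_888_000, 76_892_000, 76_896_000,
        76_900_000, 76_904_000, 76_908_000, 76_912_000,          # exons 1-9
        76_918_000, 76_924_000, 76_930_000,                      # exons 10-12
        76_936_000, 76_940_000, 76_944_000,                      # exons 13-15
    ]
    exons = tuple((s, s + exon_len) for s in starts)
    return GeneModel(name="GX01", chrom="chrX", strand="+", exons=exons)


DELETION_START = 76_916_706
DELETION_END = 76_932_433


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The packaged miniature dataset: 3 small autosomes plus one large
    contig holding the focal-deletion fixture coordinates."""
    genome = [
        ("chr1", 5_000_000),
        ("chr2", 5_000_000),
        ("chr3", 5_000_000),
        ("chrX", 78_000_000),
    ]
    genes: List[GeneModel] = []
    idx = 1
    for chrom in ("chr1", "chr2", "chr3"):
        for j in range(17):
            genes.append(_grid_gene(f"G{idx:03d}", chrom, 150_000 + j * 280_000))
            idx += 1
    genes.append(deletion_target_gene())

    samples = [
        Sample("NORM", "normal", "germline", 0.0),
        Sample("Met1", "tumor", "diagnosis", 0.9),
        Sample("PT1", "tumor", "resection", 0.65),
        Sample("PT2", "tumor", "resection", 0.65),
        Sample("PT3", "tumor", "resection", 0.65),
        Sample("PT4", "tumor", "resection", 0.65),
        Sample("Met2", "tumor", "autopsy", 0.9),
    ]

    ploidy_profile = [
        PloidyRegion("chr1", 0, 2_000_000, 4, 2),          # balanced tetraploid
        PloidyRegion("chr1", 2_000_000, 4_000_000, 3, 0),  # LOH (CN step so CBS can see it)
        PloidyRegion("chr2", 0, 2_500_000, 4, 1),          # 3:1 -> LAF 0.25
        PloidyRegion("chr2", 2_500_000, 5_000_000, 6, 3),  # gain
        PloidyRegion("chr3", 3_500_000, 5_000_000, 2, 1),  # diploid pocket
    ]
    focal = FocalDeletion("chrX", DELETION_START, DELETION_END, "GX01", 2, 1)
    chromo = ChromothripsisRegion("chr3", 500_000, 3_000_000, 60, (4, 2), 10)

    fractions = {"G001": 0.45, "G002": 0.45, "G003": 0.45}
    rng = np.random.default_rng([seed, 999])
    for i in range(4, 13):
        fractions[f"G{i:03d}"] = float(np.round(rng.uniform(0.05, 0.15), 3))
    # G013-G015 stay at 0 -> mutant allele never expressed

    cfg = dict(
        seed=seed,
        genome=genome,
        gene_models=genes,
        samples=samples,
        ploidy_profile=ploidy_profile,
        focal_deletion=focal,
        chromothripsis_region=chromo,
        true_mutant_rna_fractions=fractions,
        rna_samples=["Met1", "PT1", "Met2"],
        responsive_genes=[f"PG{i:05d}" for i in range(1, 41)],
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
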