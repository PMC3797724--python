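"""Readers and writers for the plain-text interchange formats.

TSV tables go through pandas; BED12 gene models, BEDPE junctions, GMT
gene-set collections, and the SEG segment table are simple line formats
written/parsed directly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd

from .cnv import CopySegment, segments_to_frame
from .genome import GeneModel


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BED12 gene models


def write_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = [s for s, _ in g.exons]
            sizes = [e - s for s, e in g.exons]
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.name,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        ",".join(map(str, sizes)) + ",",
                        ",".join(str(s - g.start) for s in starts) + ",",
                    ]
                )
                + "\n"
            )


def read_bed12(path) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            genes.append(GeneModel(name=name, chrom=chrom, strand=strand, exons=exons))
    return genes


# ---------------------------------------------------------------------------
# BEDPE junctions


def write_bedpe(junctions: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in junctions.itertuples():
            fh.write(
                "\t".join(
                    [
                        r.chrom1, str(r.pos1), str(r.pos1 + 1),
                        r.chrom2, str(r.pos2), str(r.pos2 + 1),
                        f"{r.type}|{r.sample}", r.confidence,
                        r.strand1, r.strand2,
                    ]
                )
                + "\n"
            )


def read_bedpe(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            jtype, sample = f[6].split("|", 1) if "|" in f[6] else (f[6], "")
            rows.append(
                {
                    "chrom1": f[0], "pos1": int(f[1]), "strand1": f[8],
                    "chrom2": f[3], "pos2": int(f[4]), "strand2": f[9],
                    "type": jtype, "sample": sample, "confidence": f[7],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA (per-gene spliced coding sequences)


def write_fasta(seqs: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Dict[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# SEG


def write_seg(segments: Sequence[CopySegment], path, sample: str = "tumor") -> None:
    df = segments_to_frame(segments)
    df.insert(0, "sample", sample)
    df.to_csv(path, sep="\t", index=False)
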