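"""Structural junction simulation (BEDPE-shaped tables)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import STREAM_JUNCTIONS, SimConfig

JUNCTION_COLUMNS = [
    "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
    "type", "sample", "confidence",
]

# orientation pairs by junction type (intra-chromosomal, left < right)
_TYPE_STRANDS = {
    "deletion": ("+", "-"),
    "tandem-duplication": ("-", "+"),
    "inversion": ("+", "+"),
}

_MIN_SPAN_PER_JUNCTION = 100  # bp of region per requested junction


def simulate_junctions(config: SimConfig) -> pd.DataFrame:
    """Junctions per tumor sample.

    Junction endpoints cluster uniformly inside the configured
    chromothripsis region; one deletion-type junction spans the focal
    deletion breakpoints exactly. The normal sample has none.
    """
    rows = []
    ct = config.chromothripsis_region
    fd = config.focal_deletion
    if ct is not None and ct.n_junctions > 0:
        if (ct.end - ct.start) < _MIN_SPAN_PER_JUNCTION * ct.n_junctions:
            raise ValueError(
                f"chromothripsis region too small for {ct.n_junctions} junctions"
            )
    for s_i, sample in enumerate(config.tumor_samples):
        rng = config.rng(STREAM_JUNCTIONS, s_i)
        if ct is not None:
            types = rng.choice(list(_TYPE_STRANDS), size=ct.n_junctions)
            for jtype in types:
                a, b = sorted(rng.integers(ct.start, ct.end, size=2))
                if a == b:
                    b = min(b + 1, ct.end - 1)
                s1, s2 = _TYPE_STRANDS[jtype]
                rows.append(
                    {
                        "chrom1": ct.chrom, "pos1": int(a), "strand1": s1,
                        "chrom2": ct.chrom, "pos2": int(b), "strand2": s2,
                        "type": jtype, "sample": sample.name, "confidence": "high",
                    }
                )
        if fd is not None:
            rows.append(
                {
                    "chrom1": fd.chrom, "pos1": fd.start, "strand1": "+",
                    "chrom2": fd.chrom, "pos2": fd.end, "strand2": "-",
                    "type": "deletion", "sample": sample.name, "confidence": "high",
                }
            )
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)
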