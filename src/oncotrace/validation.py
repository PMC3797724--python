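"""Ultra-deep amplicon validation and temporal (shared vs private)
classification of somatic variants across the sample timeline.

A variant is present in a sample when it has strictly more than
``min_reads`` variant reads AND a variant-read fraction strictly above
``min_fraction`` (defaults >5 reads and >1%). Sanger-method records carry
a presence flag instead of counts and bypass the count rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import pandas as pd

SiteKey = Tuple[str, int, str, str]

LABELS = ("shared", "private-to-index", "partial", "unvalidated")


@dataclass(frozen=True)
class TemporalClassification:
    site: SiteKey
    presence: Dict[str, bool]
    label: str


def validate_site(
    variant_count: int,
    total_count: int,
    min_reads: int = 5,
    min_fraction: float = 0.01,
) -> bool:
    """Apply the deep-sequencing presence rule (strict inequalities)."""
    if total_count == 0:
        warnings.warn("zero-depth amplicon observation treated as absent")
        return False
    if variant_count < 0 or variant_count > total_count:
        raise ValueError("variant count must be within [0, total]")
    return variant_count > min_reads and (variant_count / total_count) > min_fraction


def presence_table(
    amplicons: pd.DataFrame,
    min_reads: int = 5,
    min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Per (site, sample) presence flags from an amplicon count table.

    Expected columns: chrom, pos, ref, alt, sample, variant_count,
    total_count, and optionally ``method`` ('deep' or 'sanger'); a sanger
    row is present iff variant_count > 0.
    """
    rows = []
    for r in amplicons.itertuples():
        method = getattr(r, "method", "deep")
        if method == "sanger":
            present = r.variant_count > 0
        else:
            present = validate_site(
                int(r.variant_count), int(r.total_count), min_reads, min_fraction
            )
        rows.append(
            {
                "chrom": r.chrom,
                "pos": int(r.pos),
                "ref": r.ref,
                "alt": r.alt,
                "sample": r.sample,
                "present": present,
            }
        )
    return pd.DataFrame(rows)


def classify_timeline(
    presence: pd.DataFrame,
    index_sample: str,
    early_samples: Sequence[str],
) -> List[TemporalClassification]:
    """Label each site by its occupancy across the timeline.

    shared: present in the index sample and in every early sample;
    private-to-index: present in the index sample only;
    partial: present in the index and a strict non-empty subset of the
    early samples; unvalidated: absent from the index sample.
    """
    needed = [index_sample, *early_samples]
    out = []
    for site, group in presence.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        flags = dict(zip(group["sample"], group["present"]))
        missing = [s for s in needed if s not in flags]
        if missing:
            raise ValueError(
                f"site {site} lacks observations for samples: {', '.join(missing)}"
            )
        if not flags[index_sample]:
            label = "unvalidated"
        else:
            n_early = sum(bool(flags[s]) for s in early_samples)
            if n_early == len(early_samples):
                label = "shared"
            elif n_early == 0:
                label = "private-to-index"
            else:
                label = "partial"
        out.append(TemporalClassification(site=site, presence=flags, label=label))
    return out


def summarize_timeline(classifications: Sequence[TemporalClassification]) -> pd.Series:
    counts = pd.Series(
        {label: sum(c.label == label for c in classifications) for label in LABELS}
    )
    validated = counts["shared"] + counts["private-to-index"] + counts["partial"]
    counts["validated"] = validated
    counts["shared_fraction"] = counts["shared"] / validated if validated else float("nan")
    return counts


def validation_accuracy(candidates: int, confirmed: int) -> float:
    """Fraction of candidate variants confirmed by orthogonal sequencing."""
    if candidates <= 0:
        raise ValueError("candidates must be > 0")
    if confirmed > candidates:
        raise ValueError("confirmed cannot exceed candidates")
    return confirmed / candidates
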