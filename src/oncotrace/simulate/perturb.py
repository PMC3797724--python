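"""Two-condition, three-timepoint perturbation expression matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import STREAM_PERTURB, SimConfig

CONDITIONS = ("wt", "mt")
TIMEPOINTS = (0, 1, 2)


def perturb_columns() -> list[str]:
    return [f"{c}_{t}h" for c in CONDITIONS for t in TIMEPOINTS]


def simulate_perturbation_matrix(config: SimConfig) -> pd.DataFrame:
    """Strictly positive expression matrix, genes x (condition, hour).

    Genes in ``config.responsive_genes`` get a multiplicative up-shift of
    ``effect_size`` in the mt condition at 1h and 2h; everything else is
    symmetric multiplicative noise around a per-gene baseline.
    """
    if config.effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    rng = config.rng(STREAM_PERTURB)
    n = config.n_perturb_genes
    genes = [f"PG{i:05d}" for i in range(1, n + 1)]
    responsive = set(config.responsive_genes)
    base = rng.lognormal(mean=5.0, sigma=1.0, size=n)
    data = {}
    for cond in CONDITIONS:
        for t in TIMEPOINTS:
            noise = rng.lognormal(mean=0.0, sigma=config.perturb_noise_sd, size=n)
            vals = base * noise
            if cond == "mt" and t > 0:
                shift = np.array(
                    [config.effect_size if g in responsive else 1.0 for g in genes]
                )
                vals = vals * shift
            data[f"{cond}_{t}h"] = vals
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return df[perturb_columns()]
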