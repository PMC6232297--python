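"""Per-sample richness and diversity indices.

Observed richness S, total reads N, Margalef richness (S-1)/ln N and the
inverse Simpson index 1/sum(p_i^2).  Indices are computed on counts
(optionally rarefied first) because N enters the Margalef formula.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import OTUTable

__all__ = ["species_richness", "margalef", "inverse_simpson", "diversity_table"]


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a single sample's counts")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if arr.sum() == 0:
        raise ValueError("sample has zero total count")
    return arr


def species_richness(counts) -> int:
    """Number of OTUs observed (count > 0)."""
    return int((_as_counts(counts) > 0).sum())


def margalef(counts) -> float:
    """Margalef richness (S - 1) / ln N; requires N >= 2 individuals."""
    arr = _as_counts(counts)
    n = arr.sum()
    if n < 2:
        raise ValueError("Margalef index requires at least 2 individuals")
    s = (arr > 0).sum()
    return float((s - 1) / np.log(n))


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum(p_i^2), the effective number of taxa."""
    arr = _as_counts(counts)
    p = arr / arr.sum()
    return float(1.0 / np.sum(p**2))


def diversity_table(table: OTUTable) -> pd.DataFrame:
    """One row per sample: S, N, margalef_d, inv_simpson."""
    rows = {}
    for sample, row in table.counts.iterrows():
        counts = row.to_numpy()
        rows[sample] = {
            "S": species_richness(counts),
            "N": int(counts.sum()),
            "margalef_d": margalef(counts),
            "inv_simpson": inverse_simpson(counts),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")
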