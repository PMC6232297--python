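"""Transforms and filters feeding every downstream analysis.

The resemblance-based analyses consume square-root-transformed relative
abundances of the full community; the correlation network consumes *unaltered*
relative abundances of the abundant subset of OTUs (present in at least five
samples / >20% of samples and reaching >=1% of at least one sample).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .containers import (
    RAW_RELATIVE,
    SQRT_RELATIVE,
    EnvTable,
    OTUTable,
    RelAbundanceTable,
    TaxonomyMap,
)

__all__ = [
    "relative_abundance",
    "sqrt_transform",
    "zscore_env",
    "filter_network_otus",
    "rarefy",
    "aggregate_taxa",
]


def relative_abundance(table: OTUTable) -> RelAbundanceTable:
    """Per-sample relative abundance: count / sample total."""
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)}")
    values = table.counts.div(totals, axis=0)
    return RelAbundanceTable(values, RAW_RELATIVE)


def sqrt_transform(rel: RelAbundanceTable) -> RelAbundanceTable:
    """Elementwise square root of a raw relative-abundance table.

    Applying it twice is rejected: the tag tracks the transform state so a
    table cannot silently be quarter-root transformed.
    """
    if rel.transform_tag != RAW_RELATIVE:
        raise ValueError(
            f"sqrt_transform expects a {RAW_RELATIVE!r} table, got "
            f"{rel.transform_tag!r}"
        )
    return RelAbundanceTable(np.sqrt(rel.values), SQRT_RELATIVE)


def zscore_env(env: EnvTable) -> EnvTable:
    """Normalize each environmental variable to mean 0, sample SD 1.

    Missing values are ignored in the mean/SD and stay missing.  A variable
    with fewer than two observed values or zero variance is an error.
    """
    values = env.values.copy()
    for col in values.columns:
        x = values[col]
        n_obs = x.notna().sum()
        if n_obs < 2:
            raise ValueError(f"variable {col!r} has fewer than 2 observed values")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"variable {col!r} is constant; cannot normalize")
        values[col] = (x - x.mean()) / sd
    return EnvTable(values, zscored=True)


def filter_network_otus(
    rel: RelAbundanceTable,
    min_samples: int = 5,
    min_sample_frac: float = 0.2,
    min_abundance: float = 0.01,
) -> RelAbundanceTable:
    """Select the abundant OTUs used for network correlations.

    An OTU is retained iff it is observed (value > 0) in at least
    ``max(min_samples, ceil(min_sample_frac * n_samples))`` samples *and*
    reaches ``min_abundance`` relative abundance in at least one sample.
    Retained values are not altered.  Idempotent.
    """
    if rel.transform_tag != RAW_RELATIVE:
        raise ValueError("filter operates on raw relative abundances")
    n_samples = rel.values.shape[0]
    prevalence_cut = max(min_samples, math.ceil(min_sample_frac * n_samples))
    observed = (rel.values > 0).sum(axis=0)
    peak = rel.values.max(axis=0)
    keep = (observed >= prevalence_cut) & (peak >= min_abundance)
    if not keep.any():
        warnings.warn("no OTUs pass the abundance/prevalence filter")
    return RelAbundanceTable(rel.values.loc[:, keep], RAW_RELATIVE)


def rarefy(table: OTUTable, depth: int, seed=None) -> OTUTable:
    """Subsample every sample without replacement to exactly ``depth`` reads."""
    totals = table.totals
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"depth {depth} exceeds totals of samples: {list(short.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, (_, row) in enumerate(table.counts.iterrows()):
        counts = row.to_numpy()
        # multivariate hypergeometric == subsampling reads without replacement
        out[i] = rng.multivariate_hypergeometric(counts, depth)
    df = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OTUTable(df, metadata=table.metadata)


def aggregate_taxa(rel: RelAbundanceTable, taxonomy: TaxonomyMap,
                   rank: str = "phylum") -> RelAbundanceTable:
    """Sum relative abundances of OTUs sharing a taxonomic label.

    OTUs without an assignment at ``rank`` pool into ``"unclassified"``.
    Per-sample totals are conserved.
    """
    if rel.transform_tag != RAW_RELATIVE:
        raise ValueError("aggregate_taxa operates on raw relative abundances")
    labels = [taxonomy.label(otu, rank) for otu in rel.otu_ids]
    agg = rel.values.T.groupby(pd.Index(labels, name=rank)).sum().T
    return RelAbundanceTable(agg, RAW_RELATIVE)
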