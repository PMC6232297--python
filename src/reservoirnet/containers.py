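"""Core tabular containers shared by every stage of the pipeline.

The pipeline revolves around three tables: an OTU count table
(samples x OTUs, nonnegative integers), an environmental-variable table
(samples x variables, real-valued, missing values allowed) and an optional
taxonomy map.  Relative-abundance matrices derived from the count table carry
a ``transform_tag`` so that downstream stages can enforce their preconditions
(e.g. Bray-Curtis expects square-root-transformed relative abundances, the
network correlations expect untransformed ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "EnvTable",
    "TaxonomyMap",
    "RelAbundanceTable",
    "RAW_RELATIVE",
    "SQRT_RELATIVE",
]

RAW_RELATIVE = "raw-relative"
SQRT_RELATIVE = "sqrt-relative"

#: metadata columns describing the sampling design
DESIGN_COLUMNS = ("reservoir", "site", "month")


@dataclass
class OTUTable:
    """OTU count table with optional per-sample design metadata.

    Parameters
    ----------
    counts:
        DataFrame of shape (n_samples, n_otus); nonnegative integers; the
        index holds sample ids and the columns OTU ids.
    metadata:
        Optional DataFrame indexed by sample id with design columns such as
        ``reservoir``, ``site`` and ``month``.
    """

    counts: pd.DataFrame
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr != np.floor(arr)) or not np.all(np.isfinite(arr)):
            r, o = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))[0]
            raise ValueError(
                f"non-integer count at sample {c.index[r]!r}, OTU {c.columns[o]!r}"
            )
        if (arr < 0).any():
            r, o = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[r]!r}, OTU {c.columns[o]!r}"
            )
        totals = arr.sum(axis=1)
        if (totals == 0).any():
            bad = c.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total count: {bad}")
        self.counts = c.astype(np.int64)
        if self.metadata is not None and not self.metadata.index.equals(c.index):
            self.metadata = self.metadata.reindex(c.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids) -> "OTUTable":
        meta = None if self.metadata is None else self.metadata.loc[sample_ids]
        return OTUTable(self.counts.loc[sample_ids], meta)


@dataclass
class EnvTable:
    """Environmental variables per sample; NaN marks a missing measurement."""

    values: pd.DataFrame
    zscored: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate sample ids in environmental table")
        if v.columns.has_duplicates:
            raise ValueError("duplicate variable names in environmental table")
        self.values = v.astype(float)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def variables(self) -> list:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "EnvTable":
        return EnvTable(self.values.loc[sample_ids], zscored=self.zscored)


@dataclass
class TaxonomyMap:
    """OTU id -> (phylum, class, genus); any level may be ``None``."""

    assignments: dict = field(default_factory=dict)

    RANKS = ("phylum", "class", "genus")

    def label(self, otu_id: str, rank: str) -> str:
        if rank not in self.RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {self.RANKS}")
        entry = self.assignments.get(otu_id)
        if entry is None:
            return "unclassified"
        value = dict(zip(self.RANKS, entry)).get(rank)
        return value if value else "unclassified"


@dataclass
class RelAbundanceTable:
    """Relative-abundance matrix in [0, 1] with a transform tag."""

    values: pd.DataFrame
    transform_tag: str = RAW_RELATIVE

    def __post_init__(self) -> None:
        if self.transform_tag not in (RAW_RELATIVE, SQRT_RELATIVE):
            raise ValueError(f"unknown transform tag {self.transform_tag!r}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (np.nanmin(arr) < -1e-12 or np.nanmax(arr) > 1 + 1e-12):
            raise ValueError("relative abundances must lie in [0, 1]")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "RelAbundanceTable":
        return RelAbundanceTable(self.values.loc[sample_ids], self.transform_tag)


def align_samples(otus, env):
    """Intersect sample ids of an OTU-side table and an EnvTable.

    Returns the two tables restricted to the shared samples (original OTU-table
    order) together with a report dict listing what was dropped, so callers can
    log exactly which samples fell out of the analysis.
    """
    shared = [s for s in otus.sample_ids if s in set(env.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between OTU and environmental tables")
    report = {
        "n_shared": len(shared),
        "dropped_otu_samples": [s for s in otus.sample_ids if s not in set(shared)],
        "dropped_env_samples": [s for s in env.sample_ids if s not in set(shared)],
    }
    return otus.subset_samples(shared), env.subset_samples(shared), report
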