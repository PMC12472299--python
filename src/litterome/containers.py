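"""Core in-memory containers shared by every analysis stage.

The hub object is :class:`CommunityTable`, a samples-by-taxa count matrix
carrying optional QIIME-style taxonomy lineages per taxon and a treatment
group label per sample.  All downstream stages (diversity, assembly,
networks, biomarker discovery) consume it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CommunityTable"]


@dataclass
class CommunityTable:
    """Samples x taxa count matrix with taxonomy and treatment metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per sample, one column per taxon.
    taxonomy
        Semicolon-delimited lineage string per taxon
        (``k__...;p__...;c__...;o__...;f__...;g__...``); optional.
    metadata
        Treatment-group label per sample; optional.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    metadata: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in community table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon ids in community table")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("negative counts in community table")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.columns).fillna("")
        if self.metadata is not None:
            missing = self.counts.index.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"samples missing from metadata: {list(missing)}")
            self.metadata = self.metadata.reindex(self.counts.index)

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def groups(self) -> pd.Series:
        if self.metadata is None:
            raise ValueError("community table carries no sample metadata")
        return self.metadata

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def copy_with(self, counts: pd.DataFrame) -> "CommunityTable":
        """New table with replaced counts, taxonomy/metadata subset to match."""
        taxonomy = None
        if self.taxonomy is not None:
            taxonomy = self.taxonomy.reindex(counts.columns)
        metadata = None
        if self.metadata is not None:
            metadata = self.metadata.reindex(counts.index)
        return CommunityTable(counts=counts, taxonomy=taxonomy, metadata=metadata)
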