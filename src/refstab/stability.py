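"""Common container for per-gene stability values and ranks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = ["StabilityResult", "rank_values"]


def rank_values(values: pd.Series, *, higher_is_better: bool = False) -> pd.Series:
    """Assign integer ranks 1..n, most stable first.

    Ties are broken deterministically by position in the input index (a
    stable sort), matching the documented tie-break policy.  NaN values are
    always ranked last.
    """
    v = values.astype(float)
    key = -v if higher_is_better else v
    # NaN sorts last under stable mergesort with nan-aware key
    key = key.fillna(np.inf)
    order = np.argsort(key.values, kind="stable")
    ranks = np.empty(len(v), dtype=int)
    ranks[order] = np.arange(1, len(v) + 1)
    return pd.Series(ranks, index=values.index, name="rank")


@dataclass
class StabilityResult:
    """Per-gene stability values and ranks for one method on one dataset."""

    method: str
    values: pd.Series
    ranks: pd.Series
    direction: str  # "lower is better" | "higher is better"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.values.index) != set(self.ranks.index):
            raise ContractError("values and ranks must cover the same genes")
        n = len(self.ranks)
        if sorted(self.ranks) != list(range(1, n + 1)):
            raise ContractError("ranks must be a permutation of 1..n_genes")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    def ordered_genes(self) -> list:
        """Genes from most to least stable."""
        return list(self.ranks.sort_values().index)

    def tied_genes(self) -> list[tuple]:
        """Groups of genes sharing identical stability values."""
        groups = self.values.groupby(self.values).groups
        return [tuple(idx) for val, idx in groups.items() if len(idx) > 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "rank": self.ranks})
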