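"""BestKeeper descriptive statistics, index and correlation ranking.

All statistics operate on the Cq scale (not quantities).  The index is the
per-sample geometric mean of the candidate genes' Cq; genes are judged by
their dispersion ("SD", by default the mean absolute deviation from the
arithmetic mean Cq, the tool's documented variant) and by the Pearson
correlation of their Cq with the index — high r = stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cq_io import CqDataset
from .errors import DomainError, InsufficientDataError
from .stability import StabilityResult, rank_values

__all__ = ["BestKeeperSummary", "bestkeeper_summary", "bestkeeper_rank",
           "SD_INCONSISTENT_CUTOFF"]

#: dispersion above this many cycles flags a gene as "inconsistent"
SD_INCONSISTENT_CUTOFF = 1.0


@dataclass
class BestKeeperSummary:
    per_gene: pd.DataFrame        # geo_mean, ar_mean, min, max, sd, r
    index: pd.Series              # per-sample geometric mean Cq
    sd_variant: str               # "mad" | "sd"
    excluded_samples: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _dispersion(cq: pd.DataFrame, variant: str) -> pd.Series:
    if variant == "mad":
        return (cq - cq.mean(axis=0)).abs().mean(axis=0)
    if variant == "sd":
        return cq.std(axis=0, ddof=1)
    raise DomainError(f"unknown sd_variant {variant!r}; use 'mad' or 'sd'")


def bestkeeper_summary(ds: CqDataset, sd_variant: str = "mad",
                       sd_prefilter: bool = False) -> BestKeeperSummary:
    """Per-gene descriptive statistics and correlation with the index.

    Samples missing any gene are excluded listwise (the index mixes all
    genes).  A gene that is constant across samples has undefined r and is
    reported as missing, never silently zero.  With ``sd_prefilter`` genes
    whose dispersion exceeds :data:`SD_INCONSISTENT_CUTOFF` are left out of
    the index (off by default; the printed analyses include all genes).
    """
    cq = ds.require_collapsed()
    if cq.shape[1] < 2:
        raise InsufficientDataError("BestKeeper needs >= 2 genes")
    complete = cq.notna().all(axis=1)
    excluded = list(cq.index[~complete])
    cq = cq.loc[complete]
    if cq.shape[0] < 3:
        raise InsufficientDataError(
            f"only {cq.shape[0]} complete samples; need >= 3"
        )
    disp = _dispersion(cq, sd_variant)
    index_genes = list(cq.columns)
    if sd_prefilter:
        index_genes = [g for g in index_genes if disp[g] <= SD_INCONSISTENT_CUTOFF]
    index = np.exp(np.log(cq[index_genes]).mean(axis=1))
    index.name = "bestkeeper_index"
    r = {}
    constant = []
    index_constant = bool(np.isclose(index.std(ddof=1), 0.0))
    for g in cq.columns:
        if np.isclose(cq[g].std(ddof=1), 0.0):
            r[g] = np.nan
            constant.append(g)
        elif index_constant:
            r[g] = np.nan
        else:
            r[g] = stats.pearsonr(cq[g], index).statistic
    per_gene = pd.DataFrame({
        "geo_mean": np.exp(np.log(cq).mean(axis=0)),
        "ar_mean": cq.mean(axis=0),
        "min": cq.min(axis=0),
        "max": cq.max(axis=0),
        "sd": disp,
        "r": pd.Series(r),
        "inconsistent": disp > SD_INCONSISTENT_CUTOFF,
    })
    return BestKeeperSummary(
        per_gene=per_gene, index=index, sd_variant=sd_variant,
        excluded_samples=excluded,
        diagnostics={"constant_genes": constant, "index_genes": index_genes,
                     "index_constant": index_constant},
    )


def bestkeeper_rank(summary: BestKeeperSummary) -> StabilityResult:
    """Rank genes by descending correlation with the index.

    Genes with undefined r (constant Cq) sort last, with a diagnostic.
    """
    r = summary.per_gene["r"]
    ranks = rank_values(r, higher_is_better=True)
    return StabilityResult(
        method="bestkeeper",
        values=r,
        ranks=ranks,
        direction="higher is better",
        diagnostics={
            "sd": summary.per_gene["sd"],
            "sd_variant": summary.sd_variant,
            "inconsistent": summary.per_gene["inconsistent"],
            "undefined_r": list(r.index[r.isna()]),
        },
    )
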