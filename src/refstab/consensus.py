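"""Geometric-mean rank aggregation and reference-gene recommendation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq_io import CqDataset
from .errors import ContractError, InsufficientDataError
from .genorm import PairwiseVariationSeries
from .stability import StabilityResult

__all__ = ["ConsensusRanking", "RefGeneRecommendation",
           "comprehensive_rank", "comprehensive_rank_from_table",
           "recommend_references", "group_delta_cq_diagnostic"]


@dataclass
class ConsensusRanking:
    """Per-gene geometric mean of method ranks and the resulting re-ranking."""

    table: pd.DataFrame    # one column per method rank + geo_mean_rank + comprehensive_rank
    methods: list[str]
    ties: list[tuple] = field(default_factory=list)

    @property
    def comprehensive_rank(self) -> pd.Series:
        return self.table["comprehensive_rank"]

    @property
    def geo_mean_rank(self) -> pd.Series:
        return self.table["geo_mean_rank"]

    def ordered_genes(self) -> list:
        return list(self.table["comprehensive_rank"].sort_values().index)


def comprehensive_rank_from_table(ranks: pd.DataFrame) -> ConsensusRanking:
    """Aggregate a genes x methods table of integer ranks.

    Geometric mean across methods, then ascending re-rank.  Ties in the
    geometric mean are broken by arithmetic mean rank, then by gene name;
    tied groups are reported.
    """
    if ranks.shape[1] < 1:
        raise ContractError("need at least one method ranking")
    if ranks.isna().any().any():
        raise ContractError("rank table contains missing entries")
    geo = np.exp(np.log(ranks.astype(float)).mean(axis=1))
    mean_rank = ranks.mean(axis=1)
    order = sorted(ranks.index,
                   key=lambda g: (geo[g], mean_rank[g], str(g)))
    comp = pd.Series({g: i for i, g in enumerate(order, start=1)},
                     name="comprehensive_rank").reindex(ranks.index)
    ties = [tuple(idx) for val, idx in geo.groupby(geo).groups.items()
            if len(idx) > 1]
    table = ranks.copy()
    table["geo_mean_rank"] = geo
    table["comprehensive_rank"] = comp
    return ConsensusRanking(table=table, methods=list(ranks.columns), ties=ties)


def comprehensive_rank(results: Sequence[StabilityResult]) -> ConsensusRanking:
    """Aggregate per-method rankings into the comprehensive ranking."""
    if not results:
        raise ContractError("need at least one StabilityResult")
    gene_sets = [frozenset(r.genes) for r in results]
    if len(set(gene_sets)) > 1:
        union = set.union(*map(set, gene_sets))
        inter = set.intersection(*map(set, gene_sets))
        raise ContractError(
            f"methods rank different gene sets; union-minus-intersection: "
            f"{sorted(union - inter)}"
        )
    ranks = pd.DataFrame({f"{r.method}_rank": r.ranks for r in results})
    return comprehensive_rank_from_table(ranks)


@dataclass
class RefGeneRecommendation:
    recommended: list
    n_required: int
    excluded: dict            # gene -> reason
    audit: list[str]
    delta_cq_diagnostic: pd.DataFrame | None = None


def group_delta_cq_diagnostic(ds: CqDataset) -> pd.DataFrame:
    """Per-gene between-group mean Cq difference with a two-tailed t-test.

    Evidence backing for condition-responsiveness flags: a gene whose Cq
    differs systematically between the two groups is a poor reference
    regardless of its stability rank.
    """
    cq = ds.require_collapsed()
    if ds.groups is None:
        raise ContractError("dataset has no group labels")
    labels = list(pd.unique(ds.groups.reindex(cq.index)))
    if len(labels) != 2:
        raise InsufficientDataError(f"diagnostic needs exactly 2 groups, got {labels}")
    g1 = cq.loc[ds.groups.reindex(cq.index) == labels[0]]
    g2 = cq.loc[ds.groups.reindex(cq.index) == labels[1]]
    rows = {}
    for gene in cq.columns:
        a, b = g1[gene].dropna(), g2[gene].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows[gene] = {"mean_delta_cq": a.mean() - b.mean(),
                      "t_statistic": t, "p_value": p}
    out = pd.DataFrame(rows).T
    out.index.name = "gene"
    out.attrs["contrast"] = f"{labels[0]} - {labels[1]}"
    return out


def recommend_references(
    consensus: ConsensusRanking,
    v: PairwiseVariationSeries,
    exclusions: Mapping[str, str] | None = None,
    force_include: Sequence[str] = (),
    diagnostic: pd.DataFrame | None = None,
) -> RefGeneRecommendation:
    """Pick ``v.recommended_n`` genes from the consensus order.

    Forced inclusions come first (documented overrides, e.g. the one gene
    known to be condition-neutral); the rest fill in consensus order,
    skipping excluded genes.  Every decision is logged in ``audit``.
    """
    exclusions = dict(exclusions or {})
    n = v.recommended_n
    audit = [f"n_required={n} from pairwise-variation rule "
             f"(threshold {v.threshold})"]
    chosen: list = []
    for g in force_include:
        if g in exclusions:
            raise ContractError(f"gene {g!r} both forced and excluded")
        chosen.append(g)
        audit.append(f"include {g}: forced override")
    for g in consensus.ordered_genes():
        if len(chosen) >= n:
            break
        if g in chosen:
            continue
        if g in exclusions:
            audit.append(f"skip {g}: {exclusions[g]}")
            continue
        chosen.append(g)
        audit.append(
            f"include {g}: comprehensive rank "
            f"{int(consensus.comprehensive_rank[g])}"
        )
    if len(chosen) < n:
        raise InsufficientDataError(
            f"exclusions leave only {len(chosen)} genes; {n} required"
        )
    chosen = chosen[:n]
    diag = None
    if diagnostic is not None:
        diag = diagnostic.loc[[g for g in diagnostic.index]]
        for g in chosen:
            if g in diag.index and diag.loc[g, "p_value"] < 0.05:
                audit.append(
                    f"warning {g}: between-group delta-Cq p="
                    f"{diag.loc[g, 'p_value']:.3g} suggests condition response"
                )
    return RefGeneRecommendation(recommended=chosen, n_required=n,
                                 excluded=exclusions, audit=audit,
                                 delta_cq_diagnostic=diag)
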