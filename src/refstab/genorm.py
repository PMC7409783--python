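"""geNorm: expression stability M, normalization factors, pairwise variation V.

For genes j, k the pairwise variation ``V_jk`` is the sample standard
deviation (n-1 denominator) across samples of ``log2(q_j / q_k)``.  A gene's
stability ``M_j`` is the mean of its pairwise variations with every other
candidate; low M = stable.  Normalization factors are per-sample geometric
means of the chosen genes' quantities, and ``V_{n/n+1}`` — the standard
deviation of ``log2(NF_n / NF_{n+1})`` — drives the how-many-genes decision
(default threshold 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cq_io import QuantityMatrix
from .errors import ContractError, InsufficientDataError
from .stability import StabilityResult, rank_values

__all__ = [
    "pairwise_variation",
    "variation_matrix",
    "genorm_m",
    "genorm_stepwise",
    "normalization_factor",
    "v_series",
    "PairwiseVariationSeries",
    "STABLE_M_CUTOFF",
]

#: genes with M below this are flagged "stable"
STABLE_M_CUTOFF = 1.5

MIN_COMMON_SAMPLES = 3


def _log2q(q: QuantityMatrix | pd.DataFrame) -> pd.DataFrame:
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    return np.log2(qdf)


def _pairwise_sd(x: pd.DataFrame, gene_j: str, gene_k: str) -> float:
    for g in (gene_j, gene_k):
        if g not in x.columns:
            raise ContractError(f"gene {g!r} not in quantity matrix")
    ratio = (x[gene_j] - x[gene_k]).dropna()
    if len(ratio) < MIN_COMMON_SAMPLES:
        raise InsufficientDataError(
            f"genes {gene_j!r}/{gene_k!r} share only {len(ratio)} complete "
            f"samples; need >= {MIN_COMMON_SAMPLES}"
        )
    return float(ratio.std(ddof=1))


def pairwise_variation(q: QuantityMatrix | pd.DataFrame, gene_j: str, gene_k: str) -> float:
    """SD across samples of the per-sample log2 ratio of two genes.

    Samples missing either gene are dropped pairwise; fewer than
    ``MIN_COMMON_SAMPLES`` complete pairs is an error.
    """
    return _pairwise_sd(_log2q(q), gene_j, gene_k)


def _variation_matrix_logged(x: pd.DataFrame) -> pd.DataFrame:
    genes = list(x.columns)
    out = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i, gj in enumerate(genes):
        for gk in genes[i + 1:]:
            v = _pairwise_sd(x, gj, gk)
            out.loc[gj, gk] = out.loc[gk, gj] = v
    return out


def variation_matrix(q: QuantityMatrix | pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of pairwise variations V_jk (diagonal NaN)."""
    return _variation_matrix_logged(_log2q(q))


def genorm_m(q: QuantityMatrix | pd.DataFrame) -> StabilityResult:
    """Single-pass geNorm M over the full gene panel, ranked ascending."""
    x = _log2q(q)
    if x.shape[1] < 3:
        raise InsufficientDataError(f"geNorm needs >= 3 genes, got {x.shape[1]}")
    vmat = _variation_matrix_logged(x)
    m = vmat.mean(axis=1, skipna=True)
    m.name = "M"
    ranks = rank_values(m)
    effective_n = (x.notna().astype(int).T @ x.notna().astype(int))
    return StabilityResult(
        method="genorm",
        values=m,
        ranks=ranks,
        direction="lower is better",
        diagnostics={
            "variation_matrix": vmat,
            "stable_flag": m < STABLE_M_CUTOFF,
            "effective_n": effective_n,
        },
    )


def genorm_stepwise(q: QuantityMatrix | pd.DataFrame) -> StabilityResult:
    """Classic stepwise-exclusion geNorm ranking.

    Iteratively recomputes M on the remaining panel and drops the
    worst gene; exclusion order defines ranks.  The final two genes cannot
    be separated and share rank 1 numerically broken by input order.
    Reported values are each gene's M at the round of its exclusion.
    """
    x = _log2q(q)
    if x.shape[1] < 3:
        raise InsufficientDataError(f"geNorm needs >= 3 genes, got {x.shape[1]}")
    remaining = list(x.columns)
    exclusion_m: dict[str, float] = {}
    order: list[str] = []
    while len(remaining) > 2:
        vmat = _variation_matrix_logged(x[remaining])
        m = vmat.mean(axis=1, skipna=True)
        worst = m.idxmax()
        exclusion_m[worst] = float(m[worst])
        order.append(worst)
        remaining.remove(worst)
    final_v = _pairwise_sd(x, remaining[0], remaining[1])
    for g in remaining:
        exclusion_m[g] = final_v
    order.extend(reversed(remaining))
    ranks = pd.Series({g: r for r, g in enumerate(reversed(order), start=1)})
    values = pd.Series(exclusion_m)
    values = values.reindex(x.columns)
    ranks = ranks.reindex(x.columns)
    return StabilityResult(
        method="genorm",
        values=values,
        ranks=ranks,
        direction="lower is better",
        diagnostics={"mode": "stepwise", "final_pair": tuple(remaining)},
    )


def normalization_factor(q: QuantityMatrix | pd.DataFrame,
                         genes: Sequence[str]) -> pd.Series:
    """Per-sample geometric mean of the chosen genes' quantities."""
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    genes = list(genes)
    if not genes:
        raise ContractError("need at least one gene for a normalization factor")
    missing_genes = [g for g in genes if g not in qdf.columns]
    if missing_genes:
        raise ContractError(f"genes not in quantity matrix: {missing_genes}")
    sub = qdf[genes]
    if sub.isna().any().any():
        cells = [(s, g) for s, g in sub.stack(future_stack=True).index[
            sub.stack(future_stack=True).isna()]]
        raise InsufficientDataError(f"missing quantities at cells: {cells}")
    nf = np.exp(np.log(sub).mean(axis=1))
    nf.name = "NF"
    return nf


@dataclass
class PairwiseVariationSeries:
    """V_{n/n+1} for n = 2..n_genes-1 plus the how-many-genes decision."""

    v: pd.Series  # index n, value V_{n/n+1}
    threshold: float
    recommended_n: int
    ranking: list  # genes from most to least stable, as used to build NFs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n": self.v.index,
            "v_n_n+1": self.v.values,
            "below_threshold": self.v.values < self.threshold,
        })


def v_series(q: QuantityMatrix | pd.DataFrame, ranking: StabilityResult,
             threshold: float = 0.15) -> PairwiseVariationSeries:
    """Pairwise variation between NF_n and NF_{n+1} along a stability ranking.

    ``recommended_n`` is the smallest n whose V_{n/n+1} falls below the
    threshold, or the full panel size if none does.
    """
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    genes_by_rank = ranking.ordered_genes()
    if set(genes_by_rank) != set(qdf.columns):
        raise ContractError("ranking does not cover the quantity matrix genes")
    n_genes = len(genes_by_rank)
    if n_genes < 3:
        raise InsufficientDataError("V-series needs >= 3 genes")
    vs = {}
    for n in range(2, n_genes):
        nf_n = normalization_factor(qdf, genes_by_rank[:n])
        nf_n1 = normalization_factor(qdf, genes_by_rank[:n + 1])
        vs[n] = float(np.log2(nf_n / nf_n1).std(ddof=1))
    v = pd.Series(vs, name="V")
    below = v[v < threshold]
    recommended = int(below.index.min()) if len(below) else n_genes
    return PairwiseVariationSeries(v=v, threshold=threshold,
                                   recommended_n=recommended,
                                   ranking=genes_by_rank)
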