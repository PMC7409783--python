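"""Model-based stability: intra-group variance plus shrunken inter-group bias.

Works on log2 quantities (per-gene additive constants cancel, so feeding
``-Cq`` up to a gene-wise shift gives identical output).  For each group the
sample x gene table is double-centered; moment estimators recover per-gene
intra-group variances and the spread of inter-group deviations, which are
combined into a single per-gene stability value — low = stable.

With a single group the inter-group machinery is degenerate; the stability
value then reduces to the estimated intra-group standard deviation and a
warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cq_io import CqDataset, QuantityMatrix, to_quantities
from .errors import DomainError, InsufficientDataError
from .stability import StabilityResult, rank_values

__all__ = ["NormFinderDecomposition", "normfinder_decompose", "normfinder_stability"]


@dataclass
class NormFinderDecomposition:
    """All intermediates of the variance decomposition, for inspection."""

    x: pd.DataFrame                      # log2 quantities, samples x genes
    groups: pd.Series                    # sample -> group
    d: pd.DataFrame                      # inter-group deviation, group x gene
    d_shrunk: pd.DataFrame               # shrunken deviation, group x gene
    sigma2: pd.DataFrame                 # intra-group variance, group x gene
    gamma2: float                        # variance of inter-group deviations
    stability: pd.Series                 # per-gene stability value
    n_per_group: pd.Series = field(default=None)
    dropped_samples: list = field(default_factory=list)


def _log2_matrix(ds: CqDataset | QuantityMatrix) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(ds, QuantityMatrix):
        qm = ds
    else:
        qm = to_quantities(ds)
    if qm.groups is None:
        raise DomainError("dataset has no group labels; NormFinder needs them")
    x = np.log2(qm.q)
    groups = qm.groups.reindex(x.index)
    return x, groups


def normfinder_decompose(ds: CqDataset | QuantityMatrix) -> NormFinderDecomposition:
    """Run the inter/intra-group variance decomposition, keeping intermediates.

    Samples with any missing gene are dropped (the double-centering needs a
    complete matrix); dropped samples are recorded on the result.
    """
    x, groups = _log2_matrix(ds)
    complete = x.notna().all(axis=1)
    dropped = list(x.index[~complete])
    if dropped:
        warnings.warn(f"dropping incomplete samples: {dropped}", stacklevel=2)
        x, groups = x.loc[complete], groups.loc[complete]
    genes = list(x.columns)
    k = len(genes)
    if k < 3:
        raise DomainError(f"NormFinder needs >= 3 genes, got {k}")
    group_labels = list(pd.unique(groups))
    n_per_group = groups.value_counts().reindex(group_labels)
    single_group = len(group_labels) == 1
    if not single_group and (n_per_group < 2).any():
        small = n_per_group[n_per_group < 2]
        raise InsufficientDataError(f"groups with < 2 samples: {small.to_dict()}")
    if single_group and n_per_group.iloc[0] < 2:
        raise InsufficientDataError("need >= 2 samples")

    sigma2 = pd.DataFrame(index=group_labels, columns=genes, dtype=float)
    z = pd.DataFrame(index=group_labels, columns=genes, dtype=float)
    for g in group_labels:
        xg = x.loc[groups == g]
        n_g = len(xg)
        gene_means = xg.mean(axis=0)
        sample_means = xg.mean(axis=1)
        grand = xg.values.mean()
        resid = xg - gene_means - sample_means.values[:, None] + grand
        s = (resid ** 2).sum(axis=0) / (n_g - 1)
        s_bar = s.mean()
        # moment correction for the shared-residual structure of the
        # double-centered two-way layout
        sigma2.loc[g] = np.maximum(0.0, k / (k - 2) * (s - s_bar / (k - 1)))
        z.loc[g] = gene_means - grand

    if single_group:
        g = group_labels[0]
        stability = np.sqrt(sigma2.loc[g].astype(float))
        warnings.warn("single group supplied; stability reduces to the "
                      "intra-group standard deviation", stacklevel=2)
        return NormFinderDecomposition(
            x=x, groups=groups, d=z * 0.0, d_shrunk=z * 0.0,
            sigma2=sigma2, gamma2=0.0,
            stability=pd.Series(stability, index=genes, name="stability"),
            n_per_group=n_per_group, dropped_samples=dropped,
        )

    G = len(group_labels)
    weights = n_per_group / n_per_group.sum()
    z_wmean = (z.mul(weights, axis=0)).sum(axis=0)
    d = z - z_wmean
    sig_over_n = sigma2.div(n_per_group, axis=0)
    gamma2 = max(0.0, float((d ** 2).values.sum() / ((G - 1) * (k - 1))
                            - sig_over_n.values.mean()))
    shrink = gamma2 / (gamma2 + sig_over_n) if gamma2 > 0 else sig_over_n * 0.0
    d_shrunk = d * shrink
    intra_term = np.sqrt(gamma2 * sig_over_n / (gamma2 + sig_over_n)) \
        if gamma2 > 0 else sig_over_n * 0.0
    stability = (d_shrunk.abs() + intra_term).mean(axis=0)
    stability.name = "stability"
    return NormFinderDecomposition(
        x=x, groups=groups, d=d, d_shrunk=d_shrunk, sigma2=sigma2,
        gamma2=gamma2, stability=stability,
        n_per_group=n_per_group, dropped_samples=dropped,
    )


def normfinder_stability(ds: CqDataset | QuantityMatrix) -> StabilityResult:
    """Per-gene stability values and ranks (ascending; low = stable)."""
    dec = normfinder_decompose(ds)
    ranks = rank_values(dec.stability)
    return StabilityResult(
        method="normfinder",
        values=dec.stability,
        ranks=ranks,
        direction="lower is better",
        diagnostics={
            "gamma2": dec.gamma2,
            "intra_sd": np.sqrt(dec.sigma2.astype(float)),
            "intergroup_d": dec.d,
            "dropped_samples": dec.dropped_samples,
        },
    )
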