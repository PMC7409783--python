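"""Primer-efficiency fitting and delta-delta-Cq relative quantification.

Efficiency comes from an ordinary least-squares fit of replicate-mean Cq on
log10 of the template amount (1/dilution factor):
``efficiency_pct = (10 ** (-1/slope) - 1) * 100``, so the canonical slope
-3.3219 corresponds to exact doubling (100 %).

Quantification normalizes a target gene against the mean Cq of one or more
reference genes (equivalently the geometric mean of their quantities), then
against the control group; fold change is reported as the ratio of group
means of the per-sample exponentialized values by default.  The group test
is a two-tailed t-test on the non-transformed per-sample delta-Cq values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq_io import CqDataset
from .errors import ContractError, DomainError, InsufficientDataError

__all__ = [
    "DilutionSeries", "EfficiencyResult", "ExpressionResult",
    "fit_efficiency", "read_dilution_series",
    "delta_delta_cq", "reference_set_sensitivity",
]


# ---------------------------------------------------------------------------
# primer efficiency
# ---------------------------------------------------------------------------

@dataclass
class DilutionSeries:
    """Cq replicates at each level of a serial dilution.

    ``points`` maps dilution factor (1, 10, 100, ... = fold dilution of the
    starting template) to a list of replicate Cq values.
    """

    gene: str
    points: Mapping[float, Sequence[float]]
    fold: float = 10.0

    def __post_init__(self) -> None:
        factors = list(self.points)
        if any(f <= 0 for f in factors):
            raise DomainError("dilution factors must be positive")
        if sorted(factors) != factors:
            raise DomainError("dilution factors must be strictly increasing")


@dataclass
class EfficiencyResult:
    gene: str
    slope: float            # cycles per log10 template amount
    intercept: float
    efficiency_pct: float
    r_squared: float
    n_levels: int

    @property
    def amplification_factor(self) -> float:
        return 1.0 + self.efficiency_pct / 100.0


def fit_efficiency(series: DilutionSeries, allow_two_levels: bool = False) -> EfficiencyResult:
    """OLS of replicate-mean Cq on log10(template amount); slope -> efficiency.

    With only two levels the fit degenerates to the two-point slope; allowed
    only in diagnostic mode (``allow_two_levels``), with a warning.
    """
    levels = {f: [c for c in reps if np.isfinite(c)]
              for f, reps in series.points.items()}
    levels = {f: reps for f, reps in levels.items() if reps}
    if len(levels) < 3:
        if not (allow_two_levels and len(levels) == 2):
            raise InsufficientDataError(
                f"dilution series for {series.gene!r} has {len(levels)} usable "
                "levels; need >= 3"
            )
        warnings.warn("two-point efficiency fit is diagnostic only", stacklevel=2)
    x = np.log10(1.0 / np.array(list(levels)))          # template amount
    y = np.array([np.mean(reps) for reps in levels.values()])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise DomainError(
            f"dilution series for {series.gene!r} has non-negative slope "
            f"{fit.slope:.3f}; Cq must increase with dilution"
        )
    eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    return EfficiencyResult(
        gene=series.gene, slope=float(fit.slope), intercept=float(fit.intercept),
        efficiency_pct=float(eff), r_squared=float(fit.rvalue ** 2),
        n_levels=len(levels),
    )


def read_dilution_series(path, gene_col="gene", dilution_col="dilution",
                         cq_col="cq", sep=",") -> dict[str, DilutionSeries]:
    """Read a long table (gene, dilution factor, cq) into per-gene series."""
    df = pd.read_csv(path, sep=sep, comment="#")
    for col in (gene_col, dilution_col, cq_col):
        if col not in df.columns:
            raise ContractError(f"column {col!r} not found in {list(df.columns)}")
    out = {}
    for gene, sub in df.groupby(gene_col):
        points = {
            float(f): pd.to_numeric(chunk[cq_col], errors="coerce").dropna().tolist()
            for f, chunk in sub.groupby(dilution_col)
        }
        out[gene] = DilutionSeries(gene=gene, points=dict(sorted(points.items())))
    return out


# ---------------------------------------------------------------------------
# delta-delta-Cq
# ---------------------------------------------------------------------------

@dataclass
class ExpressionResult:
    target: str
    references: list
    control_group: str
    treatment_group: str
    relative_quantity: pd.Series      # per sample, control-group mean = unit
    delta_cq: pd.Series               # per sample, Cq scale
    fold_change: float
    sem: pd.Series                    # per group, on exponentialized values
    t_statistic: float
    p_value: float
    method: str = "mean_of_exponentialized"
    diagnostics: dict = field(default_factory=dict)


def delta_delta_cq(
    ds: CqDataset,
    target: str,
    references: Sequence[str],
    control_group: str,
    *,
    fold_method: str = "mean_of_exponentialized",
    t_test: str = "student",
    efficiency: float | Mapping[str, float] = 2.0,
) -> ExpressionResult:
    """Relative expression of ``target`` normalized to ``references``.

    delta-Cq per sample = target Cq minus the mean reference Cq; delta-delta
    anchors at the control-group mean; per-sample relative quantity is
    ``E ** (-ddCq)``.  ``fold_method`` chooses between the ratio of group
    means of exponentialized values (default) and ``exp_of_mean``
    (``E ** -(mean ddCq difference)``).  The t-test runs on the
    non-transformed delta-Cq values; ``t_test`` is "student" or "welch".
    """
    references = list(references)
    if target in references:
        raise ContractError(f"target {target!r} cannot be its own reference")
    if not references:
        raise ContractError("need at least one reference gene")
    cq = ds.require_collapsed()
    for g in [target] + references:
        if g not in cq.columns:
            raise ContractError(f"gene {g!r} not in dataset")
    if ds.groups is None:
        raise ContractError("dataset has no group labels")
    groups = ds.groups.reindex(cq.index)
    labels = list(pd.unique(groups))
    if control_group not in labels:
        raise ContractError(f"control group {control_group!r} not in {labels}")
    if len(labels) != 2:
        raise InsufficientDataError(f"need exactly 2 groups, got {labels}")
    treatment_group = next(l for l in labels if l != control_group)

    sub = cq[[target] + references]
    incomplete = sub.isna()
    if incomplete.any().any():
        cells = [(s, g) for s in sub.index for g in sub.columns
                 if pd.isna(sub.loc[s, g])]
        raise InsufficientDataError(f"missing Cq at cells: {cells}")

    if isinstance(efficiency, Mapping):
        e_target = float(efficiency[target])
        log2q = -pd.DataFrame({
            g: np.log2(float(efficiency.get(g, 2.0))) * cq[g]
            for g in [target] + references})
        # quantity-scale delta: log2 q_target - mean log2 q_refs
        dlog = log2q[target] - log2q[references].mean(axis=1)
        delta_cq = -dlog  # generalized delta-Cq in doubling units
        e_used = 2.0
    else:
        e_used = float(efficiency)
        if e_used <= 1.0:
            raise DomainError("amplification factor must exceed 1")
        delta_cq = cq[target] - cq[references].mean(axis=1)
        e_target = e_used
    ddcq = delta_cq - delta_cq[groups == control_group].mean()
    rq = e_used ** (-ddcq) if not isinstance(efficiency, Mapping) \
        else 2.0 ** (-ddcq)
    rq.name = "relative_quantity"

    rq_ctrl = rq[groups == control_group]
    rq_trt = rq[groups == treatment_group]
    if fold_method == "mean_of_exponentialized":
        fold = float(rq_trt.mean() / rq_ctrl.mean())
    elif fold_method == "exp_of_mean":
        fold = float(2.0 ** (-(ddcq[groups == treatment_group].mean()
                               - ddcq[groups == control_group].mean())))
    else:
        raise DomainError(f"unknown fold_method {fold_method!r}")

    sem = pd.Series({control_group: rq_ctrl.sem(), treatment_group: rq_trt.sem()},
                    name="sem")
    equal_var = {"student": True, "welch": False}.get(t_test)
    if equal_var is None:
        raise DomainError(f"unknown t_test {t_test!r}; use 'student' or 'welch'")
    t, p = stats.ttest_ind(delta_cq[groups == treatment_group],
                           delta_cq[groups == control_group],
                           equal_var=equal_var)
    return ExpressionResult(
        target=target, references=references, control_group=control_group,
        treatment_group=treatment_group, relative_quantity=rq,
        delta_cq=delta_cq, fold_change=fold, sem=sem,
        t_statistic=float(t), p_value=float(p), method=fold_method,
        diagnostics={"t_test": t_test, "efficiency": efficiency,
                     "e_target": e_target},
    )


def reference_set_sensitivity(
    ds: CqDataset,
    target: str,
    reference_sets: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    control_group: str,
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`delta_delta_cq` once per reference set, side by side.

    Returns one row per set with fold change, p-value, significance flag and
    whether significance or direction changed relative to the first set.
    """
    if not isinstance(reference_sets, Mapping):
        reference_sets = {f"set{i + 1}": s for i, s in enumerate(reference_sets)}
    rows = {}
    results = {}
    for name, refs in reference_sets.items():
        res = delta_delta_cq(ds, target, refs, control_group, **kwargs)
        results[name] = res
        rows[name] = {
            "references": ",".join(res.references),
            "fold_change": res.fold_change,
            "p_value": res.p_value,
            "significant": res.p_value < alpha,
            "direction": "up" if res.fold_change > 1 else "down",
        }
    out = pd.DataFrame(rows).T
    first = out.iloc[0]
    out["significance_changed"] = out["significant"] != first["significant"]
    out["direction_changed"] = out["direction"] != first["direction"]
    out.attrs["results"] = results
    out.index.name = "reference_set"
    return out
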