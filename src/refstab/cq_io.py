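"""Cq data model, readers/writers, replicate collapsing, quantity conversion.

The central object is :class:`CqDataset`: a long table of raw wells
(one row per technical replicate) plus, after :func:`collapse_replicates`,
a samples x genes matrix of per-cell mean (or median) Cq.  Quantities are
linear-scale relative expression values ``E ** (Cq_min - Cq)`` anchored at
each gene's minimum observed Cq, so the most concentrated sample has q = 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from numbers import Real
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError, SchemaError

__all__ = [
    "CqDataset",
    "QuantityMatrix",
    "DEFAULT_CQ_WINDOW",
    "read_cq_table",
    "read_cq_matrix",
    "collapse_replicates",
    "to_quantities",
    "write_collapsed",
    "write_quantities",
]

DEFAULT_CQ_WINDOW = (5.0, 40.0)

#: canonical well-table columns, in storage order
WELL_COLUMNS = ["sample", "gene", "replicate", "cq", "group", "tissue", "species"]


@dataclass
class CqDataset:
    """Annotated collection of raw Cq wells with optional collapsed matrix.

    Parameters
    ----------
    wells
        Long table with columns ``sample, gene, replicate, cq`` and optional
        ``group, tissue, species``.  ``cq`` may be NaN for recorded-but-missing
        wells (e.g. removed after an aberrant melt curve).
    collapsed
        samples x genes matrix of per-cell Cq, filled by
        :func:`collapse_replicates`.
    replicate_counts
        samples x genes matrix of contributing technical replicates.
    groups
        Mapping sample -> condition-group label.
    metadata
        Free-form annotations (tissue, species, provenance, parameters).
    """

    wells: pd.DataFrame
    collapsed: pd.DataFrame | None = None
    replicate_counts: pd.DataFrame | None = None
    groups: pd.Series | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"sample", "gene", "replicate", "cq"} - set(self.wells.columns)
        if missing:
            raise SchemaError(f"well table lacks columns: {sorted(missing)}")
        dup = self.wells.duplicated(subset=["sample", "gene", "replicate"])
        if dup.any():
            rows = self.wells.loc[dup, ["sample", "gene", "replicate"]]
            raise IntegrityError(
                "duplicate (sample, gene, replicate) wells: "
                + "; ".join(map(str, rows.itertuples(index=False, name=None)))
            )
        if self.groups is not None:
            samples = pd.unique(self.wells["sample"])
            absent = [s for s in samples if s not in self.groups.index]
            if absent:
                raise IntegrityError(f"samples without a group label: {absent}")

    @classmethod
    def from_collapsed(cls, cq: pd.DataFrame,
                       groups: Mapping | pd.Series | None = None,
                       **metadata) -> "CqDataset":
        """Build a dataset from an already-collapsed samples x genes matrix.

        Each cell becomes a single-replicate well; useful for tests and for
        data that arrives pre-averaged.
        """
        wells = (cq.stack(future_stack=True).rename("cq").reset_index())
        wells.columns = ["sample", "gene", "cq"]
        wells["replicate"] = 1
        gs = pd.Series(groups, name="group") if groups is not None else None
        if gs is not None:
            wells["group"] = wells["sample"].map(gs)
        counts = cq.notna().astype(int)
        return cls(wells=wells[[c for c in WELL_COLUMNS if c in wells.columns]],
                   collapsed=cq.copy(), replicate_counts=counts,
                   groups=gs, metadata=dict(metadata))

    # -- convenience accessors -------------------------------------------------

    @property
    def samples(self) -> list:
        if self.collapsed is not None:
            return list(self.collapsed.index)
        return list(pd.unique(self.wells["sample"]))

    @property
    def genes(self) -> list:
        if self.collapsed is not None:
            return list(self.collapsed.columns)
        return list(pd.unique(self.wells["gene"]))

    def require_collapsed(self) -> pd.DataFrame:
        if self.collapsed is None:
            raise SchemaError("dataset has no collapsed Cq matrix; "
                              "call collapse_replicates() first")
        return self.collapsed


@dataclass
class QuantityMatrix:
    """Linear-scale relative quantities derived from collapsed Cq.

    ``q.loc[s, g] = efficiency[g] ** (reference_cq[g] - Cq[s, g])`` so the
    minimum-Cq sample of each gene defines the unit (max q per gene is 1 for
    the default anchor).
    """

    q: pd.DataFrame
    efficiency: pd.Series
    reference_cq: pd.Series
    groups: pd.Series | None = None

    @property
    def samples(self) -> list:
        return list(self.q.index)

    @property
    def genes(self) -> list:
        return list(self.q.columns)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {
    "sample": "sample",
    "gene": "gene",
    "replicate": "replicate",
    "cq": "cq",
    "group": "group",
    "tissue": "tissue",
    "species": "species",
}


def _check_window(cq: pd.Series, window: tuple[float, float], policy: str,
                  metadata: dict) -> pd.Series:
    lo, hi = window
    bad = cq.notna() & ((cq < lo) | (cq > hi) | ~np.isfinite(cq.fillna(0.0)))
    if not bad.any():
        return cq
    rows = sorted(cq.index[bad])
    if policy == "error":
        raise SchemaError(
            f"Cq values outside plausible window [{lo}, {hi}] at rows {rows}; "
            "pass window_policy='flag' to drop them instead"
        )
    # flag: record and treat as missing, never silently used
    metadata.setdefault("flagged_out_of_window", []).extend(rows)
    cq = cq.copy()
    cq[bad] = np.nan
    return cq


def read_cq_table(
    path: str | Path | io.IOBase,
    schema: Mapping[str, str] | None = None,
    *,
    sep: str = ",",
    cq_window: tuple[float, float] = DEFAULT_CQ_WINDOW,
    window_policy: str = "error",
) -> CqDataset:
    """Read a long-format delimited Cq table into a :class:`CqDataset`.

    ``schema`` maps canonical names (``sample``, ``gene``, ``cq``, optionally
    ``replicate``, ``group``, ``tissue``, ``species``) to the file's column
    names.  Empty Cq cells are kept as missing wells; they are excluded from
    collapsing but preserved for audit.
    """
    schema = {**_DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    for canonical in ("sample", "gene", "cq"):
        if schema[canonical] not in df.columns:
            raise SchemaError(
                f"mandatory column {schema[canonical]!r} (for {canonical!r}) "
                f"not found; file has {list(df.columns)}"
            )
    out = pd.DataFrame({"sample": df[schema["sample"]], "gene": df[schema["gene"]]})
    raw_cq = df[schema["cq"]]
    cq = pd.to_numeric(raw_cq, errors="coerce")
    bad = cq.isna() & raw_cq.notna() & (raw_cq.astype(str).str.strip() != "")
    if bad.any():
        raise SchemaError(
            f"non-numeric Cq values at rows {sorted(bad.index[bad])}: "
            f"{raw_cq[bad].tolist()}"
        )
    metadata: dict = {"source": str(path)}
    out["cq"] = _check_window(cq, cq_window, window_policy, metadata)
    if schema["replicate"] in df.columns:
        out["replicate"] = df[schema["replicate"]]
    else:
        out["replicate"] = out.groupby(["sample", "gene"]).cumcount() + 1
    for optional in ("group", "tissue", "species"):
        if schema[optional] in df.columns:
            out[optional] = df[schema[optional]]
    groups = None
    if "group" in out.columns:
        groups = out.drop_duplicates("sample").set_index("sample")["group"]
        conflicting = out.groupby("sample")["group"].nunique()
        if (conflicting > 1).any():
            raise IntegrityError(
                f"samples with more than one group label: "
                f"{list(conflicting.index[conflicting > 1])}"
            )
    return CqDataset(wells=out[[c for c in WELL_COLUMNS if c in out.columns]],
                     groups=groups, metadata=metadata)


def read_cq_matrix(
    path: str | Path | io.IOBase,
    *,
    sample_col: str = "sample",
    group_col: str | None = "group",
    sep: str = ",",
    cq_window: tuple[float, float] = DEFAULT_CQ_WINDOW,
    window_policy: str = "error",
) -> CqDataset:
    """Read a wide matrix (one row per well, genes as columns).

    Repeated rows for the same sample are technical replicates.  Empty cells
    become missing wells.
    """
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    if sample_col not in df.columns:
        raise SchemaError(f"sample column {sample_col!r} not found in {list(df.columns)}")
    id_cols = [sample_col] + ([group_col] if group_col and group_col in df.columns else [])
    gene_cols = [c for c in df.columns if c not in id_cols]
    if not gene_cols:
        raise SchemaError("no gene columns found in wide matrix")
    long = df.melt(id_vars=id_cols, value_vars=gene_cols,
                   var_name="gene", value_name="cq")
    long = long.rename(columns={sample_col: "sample"})
    if group_col and group_col in df.columns:
        long = long.rename(columns={group_col: "group"})
    long["replicate"] = long.groupby(["sample", "gene"]).cumcount() + 1
    long["cq"] = pd.to_numeric(long["cq"], errors="coerce")
    metadata: dict = {"source": str(path)}
    long["cq"] = _check_window(long["cq"], cq_window, window_policy, metadata)
    groups = None
    if "group" in long.columns:
        groups = long.drop_duplicates("sample").set_index("sample")["group"]
    return CqDataset(wells=long[[c for c in WELL_COLUMNS if c in long.columns]],
                     groups=groups, metadata=metadata)


# ---------------------------------------------------------------------------
# collapsing and quantities
# ---------------------------------------------------------------------------

def collapse_replicates(ds: CqDataset, policy: str = "mean") -> CqDataset:
    """Collapse technical replicates into one Cq per (sample, gene).

    Missing wells are skipped; a cell with zero available replicates stays
    missing.  Cells collapsed from a single replicate are listed under
    ``metadata['low_replication']``.
    """
    if policy not in ("mean", "median"):
        raise DomainError(f"unknown collapse policy {policy!r}; use 'mean' or 'median'")
    grouped = ds.wells.groupby(["sample", "gene"])["cq"]
    collapsed_long = grouped.agg(policy)
    counts = grouped.count()
    sample_order = pd.unique(ds.wells["sample"])
    gene_order = pd.unique(ds.wells["gene"])
    collapsed = (collapsed_long.unstack("gene")
                 .reindex(index=sample_order, columns=gene_order))
    rep_counts = (counts.unstack("gene")
                  .reindex(index=sample_order, columns=gene_order)
                  .fillna(0).astype(int))
    low = [(s, g) for s, g in zip(*np.where(rep_counts.values == 1))]
    metadata = {**ds.metadata,
                "collapse_policy": policy,
                "low_replication": [
                    (rep_counts.index[s], rep_counts.columns[g]) for s, g in low
                ]}
    return replace(ds, collapsed=collapsed, replicate_counts=rep_counts,
                   metadata=metadata)


def to_quantities(
    ds: CqDataset,
    efficiency: float | Mapping[str, float] | pd.Series = 2.0,
    reference_cq: Mapping[str, float] | pd.Series | None = None,
) -> QuantityMatrix:
    """Convert collapsed Cq to linear relative quantities.

    ``q = E ** (reference_cq - Cq)`` per gene; the default reference is each
    gene's minimum observed Cq, so q is in (0, 1] with the minimum-Cq sample
    at exactly 1.  ``efficiency`` is the per-cycle amplification factor
    (2.0 = 100 % efficiency), scalar or per-gene.
    """
    cq = ds.require_collapsed()
    if isinstance(efficiency, Real):
        eff = pd.Series(float(efficiency), index=cq.columns)
    else:
        eff = pd.Series(efficiency, dtype=float).reindex(cq.columns)
        if eff.isna().any():
            raise DomainError(
                f"no efficiency given for genes: {list(eff.index[eff.isna()])}"
            )
    if (eff <= 1.0).any() or (eff > 2.2).any():
        raise DomainError(
            "amplification factor must be in (1, 2.2]; got "
            + str(eff[(eff <= 1.0) | (eff > 2.2)].to_dict())
        )
    if reference_cq is None:
        ref = cq.min(axis=0)
    else:
        ref = pd.Series(reference_cq, dtype=float).reindex(cq.columns)
    q = eff.values[np.newaxis, :] ** (ref.values[np.newaxis, :] - cq.values)
    qdf = pd.DataFrame(q, index=cq.index, columns=cq.columns)
    return QuantityMatrix(q=qdf, efficiency=eff, reference_cq=ref, groups=ds.groups)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _header_comment(params: Mapping[str, object]) -> str:
    from . import __version__
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# refstab v{__version__} {items}".rstrip() + "\n"


def write_collapsed(ds: CqDataset, path: str | Path, **params) -> None:
    """Write the collapsed Cq matrix as TSV with a provenance comment line."""
    cq = ds.require_collapsed()
    with open(path, "w") as fh:
        fh.write(_header_comment({"table": "collapsed_cq", **params}))
        cq.to_csv(fh, sep="\t", index_label="sample")


def write_quantities(qm: QuantityMatrix, path: str | Path, **params) -> None:
    """Write a quantity matrix as TSV with a provenance comment line."""
    with open(path, "w") as fh:
        fh.write(_header_comment({"table": "quantities", **params}))
        qm.q.to_csv(fh, sep="\t", index_label="sample")
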