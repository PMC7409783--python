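"""Synthetic Cq generator with known ground-truth stability structure.

Noise model, all on the Cq (cycle) scale::

    Cq[sample i, gene j, replicate r] = baseline_j
                                        + delta_j * 1[group(i) == treatment]
                                        + L_i                 # loading offset
                                        + eps_ij              # biological noise
                                        + tau_ijr             # technical noise

with ``L_i ~ N(0, sample_loading_sd)``, ``eps_ij ~ N(0, gene_noise_sd_j)``
and ``tau_ijr ~ N(0, replicate_sd)``.  Wells are dropped independently at
``missing_rate``.  The planted stability order is ascending
``sqrt(delta_j**2 + gene_noise_sd_j**2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq_io import CqDataset, collapse_replicates
from .errors import ContractError, DomainError
from .stability import StabilityResult

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_cq",
           "rank_recovery", "preset", "PRESETS"]


@dataclass
class SimulationConfig:
    n_genes: int = 8
    n_per_group: int = 5
    groups: tuple[str, str] = ("isolated", "crowded")
    baseline_cq: Sequence[float] | None = None      # default: spread over 18..28
    condition_effect: Sequence[float] | None = None  # delta per gene, cycles
    sample_loading_sd: float = 0.5
    gene_noise_sd: Sequence[float] | float = 0.3
    tech_replicates: int = 2
    replicate_sd: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if self.n_per_group < 2:
            problems.append("n_per_group must be >= 2")
        if len(self.groups) < 1:
            problems.append("need at least one group label")
        if self.tech_replicates < 1:
            problems.append("tech_replicates must be >= 1")
        if not 0 <= self.missing_rate < 1:
            problems.append("missing_rate must be in [0, 1)")
        for name in ("sample_loading_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if np.any(np.asarray(self.gene_noise_sd) < 0):
            problems.append("gene_noise_sd must be >= 0")
        for name in ("baseline_cq", "condition_effect"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_genes:
                problems.append(f"{name} must have length n_genes={self.n_genes}")
        if problems:
            raise DomainError("invalid simulation config: " + "; ".join(problems))
        return self

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genes)]

    def resolved_baselines(self) -> np.ndarray:
        if self.baseline_cq is not None:
            return np.asarray(self.baseline_cq, dtype=float)
        return np.linspace(18.0, 28.0, self.n_genes)

    def resolved_deltas(self) -> np.ndarray:
        if self.condition_effect is not None:
            return np.asarray(self.condition_effect, dtype=float)
        return np.zeros(self.n_genes)

    def resolved_noise_sd(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.gene_noise_sd, dtype=float),
                               (self.n_genes,)).copy()

    def planted_stability(self) -> pd.Series:
        """Ground-truth instability score per gene (lower = more stable)."""
        score = np.sqrt(self.resolved_deltas() ** 2 + self.resolved_noise_sd() ** 2)
        return pd.Series(score, index=self.gene_names, name="planted_instability")


@dataclass
class SyntheticDataset:
    dataset: CqDataset
    config: SimulationConfig
    loading_offsets: pd.Series = field(default=None)


def simulate_cq(cfg: SimulationConfig) -> SyntheticDataset:
    """Draw a reproducible synthetic Cq dataset (raw wells, uncollapsed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    baselines = cfg.resolved_baselines()
    deltas = cfg.resolved_deltas()
    noise_sd = cfg.resolved_noise_sd()
    genes = cfg.gene_names
    treatment = cfg.groups[-1]

    samples, group_of = [], {}
    for g, label in enumerate(cfg.groups):
        for i in range(cfg.n_per_group):
            sid = f"{label}_{i + 1}"
            samples.append(sid)
            group_of[sid] = label
    loading = rng.normal(0.0, cfg.sample_loading_sd, size=len(samples))
    eps = rng.normal(0.0, 1.0, size=(len(samples), cfg.n_genes)) * noise_sd

    rows = []
    for si, sid in enumerate(samples):
        is_trt = group_of[sid] == treatment
        for gj, gene in enumerate(genes):
            mu = baselines[gj] + (deltas[gj] if is_trt else 0.0) \
                 + loading[si] + eps[si, gj]
            for r in range(1, cfg.tech_replicates + 1):
                cq = mu + rng.normal(0.0, cfg.replicate_sd)
                if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
                    cq = np.nan
                rows.append((sid, gene, r, cq, group_of[sid]))
    wells = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "cq", "group"])
    groups = pd.Series(group_of, name="group")
    groups.index.name = "sample"
    ds = CqDataset(wells=wells, groups=groups,
                   metadata={"source": "simulate_cq", "seed": cfg.seed})
    return SyntheticDataset(
        dataset=ds, config=cfg,
        loading_offsets=pd.Series(loading, index=samples, name="loading"),
    )


def rank_recovery(truth: SyntheticDataset, result: StabilityResult) -> dict:
    """Compare a method's ranking against the planted stability order."""
    planted = truth.config.planted_stability()
    if set(planted.index) != set(result.genes):
        raise ContractError(
            f"gene sets differ: planted {sorted(planted.index)} vs "
            f"result {sorted(result.genes)}"
        )
    planted_rank = planted.rank(method="average")
    method_rank = result.ranks.reindex(planted.index).astype(float)
    if planted.nunique() == 1:
        rho = np.nan  # planted order is a total tie; correlation undefined
    else:
        rho = float(stats.spearmanr(planted_rank, method_rank).statistic)
    k = max(1, len(planted) // 2)
    top_planted = set(planted.sort_values(kind="stable").index[:k])
    top_method = set(method_rank.sort_values(kind="stable").index[:k])
    worst_planted = planted.sort_values(kind="stable").index[-1]
    return {
        "spearman_rho": rho,
        "top_k": k,
        "top_k_hit_rate": len(top_planted & top_method) / k,
        "worst_gene_identified":
            bool(method_rank[worst_planted] == len(planted)),
    }


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named scenario configs; overrides are applied on top."""
    if name not in PRESETS:
        raise ContractError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = replace(PRESETS[name], seed=seed)
    return replace(cfg, **overrides).validate()


PRESETS = {
    # everything stable and quiet
    "ideal": SimulationConfig(
        n_genes=8, condition_effect=[0.0] * 8,
        sample_loading_sd=0.4, gene_noise_sd=0.15, replicate_sd=0.05,
    ),
    # one planted condition-responsive gene
    "one-bad-gene": SimulationConfig(
        n_genes=8, condition_effect=[0.0] * 7 + [1.0],
        sample_loading_sd=0.5, gene_noise_sd=0.3, replicate_sd=0.1,
    ),
    # correlated condition-responsive block: most genes shift together, the
    # sole truly neutral gene looks like the odd one out to ratio-based
    # methods and gets ranked near the bottom
    "piceifrons-like": SimulationConfig(
        n_genes=8,
        condition_effect=[1.0, 0.9, 1.1, 0.95, 1.05, 0.85, 1.0, 0.0],
        sample_loading_sd=0.5, gene_noise_sd=0.25, replicate_sd=0.1,
    ),
    # all stable with moderate noise
    "americana-like": SimulationConfig(
        n_genes=8, condition_effect=[0.0] * 8,
        sample_loading_sd=0.5, gene_noise_sd=0.35, replicate_sd=0.1,
    ),
}


def simulate_collapsed(cfg: SimulationConfig) -> SyntheticDataset:
    """Convenience: simulate and collapse technical replicates by mean."""
    out = simulate_cq(cfg)
    return replace(out, dataset=collapse_replicates(out.dataset))
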