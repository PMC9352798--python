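"""Synthetic case/control expression data with known planted structure.

The generator emulates the statistical features the analysis pipeline
assumes of a (log2-scale, pre-normalized) expression matrix:

* independent Gaussian background genes (per-gene baseline mean drawn
  once from a uniform range, noise sd σ);
* one or more co-expressed modules driven by a single latent factor per
  sample — a module gene in an active group follows μ_g + λ·f_s + ε, so
  any two genes in one module share population correlation λ²/(λ²+σ²);
* differentially expressed genes: a constant +δ shift added to the case
  group mean of designated background genes;
* optionally a hub: one gene belonging to two modules at once, which
  raises its degree in the recovered network.

Everything is reproducible from the seed via ``numpy.random.default_rng``
(PCG64, one stream; draws happen in a fixed documented order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .build import MicroarrayExperimentSituation
from .errors import ValidationError
from .game import LRIScoreTable


@dataclass(frozen=True)
class ModuleSpec:
    """One co-expressed module: member count, factor loading λ, and the
    group(s) in which the factor is active."""

    size: int
    loading: float
    active_in: Literal["case-only", "both"] = "case-only"

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValidationError("module size must be at least 2")
        if self.loading < 0:
            raise ValidationError("module loading must be non-negative")
        if self.active_in not in ("case-only", "both"):
            raise ValidationError(f"unknown active_in {self.active_in!r}")


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe the benchmark condition used throughout the test
    suite: a 1000-gene panel with a single tightly co-expressed 10-gene
    module active in the case group (λ=3, σ=0.5 → population within-module
    correlation 9/9.25 ≈ 0.973), 20 shifted DEG genes (δ=3), and 100
    samples per group.
    """

    n_genes: int = 1000
    n_case: int = 100
    n_control: int = 100
    modules: Sequence[ModuleSpec] = field(
        default_factory=lambda: (ModuleSpec(10, 3.0, "case-only"),)
    )
    n_deg: int = 20
    shift: float = 3.0
    sigma: float = 0.5
    baseline_range: tuple[float, float] = (4.0, 12.0)
    shared_hub: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_case, self.n_control) < 1:
            raise ValidationError("gene and sample counts must be positive")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.n_deg < 0:
            raise ValidationError("n_deg must be non-negative")
        if self.baseline_range[0] > self.baseline_range[1]:
            raise ValidationError("baseline_range must be (low, high)")
        self.modules = tuple(
            m if isinstance(m, ModuleSpec) else ModuleSpec(**m) for m in self.modules
        )
        total = sum(m.size for m in self.modules)
        if total + self.n_deg > self.n_genes:
            raise ValidationError(
                "module members plus DEG genes exceed the gene panel"
            )
        if self.shared_hub and len(self.modules) < 2:
            raise ValidationError("shared_hub requires at least two modules")

    @classmethod
    def from_mapping(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "baseline_range" in data:
            data["baseline_range"] = tuple(data["baseline_range"])
        return cls(**data)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure: module memberships, hub genes, shifted genes,
    and each module's population within-module correlation."""

    module_members: tuple[tuple[str, ...], ...]
    hub_genes: tuple[str, ...]
    deg_genes: tuple[str, ...]
    module_correlations: tuple[float, ...]

    @property
    def planted_genes(self) -> frozenset[str]:
        return frozenset(g for mod in self.module_members for g in mod)


def simulate(
    config: SimulationConfig,
) -> tuple[MicroarrayExperimentSituation, SyntheticTruth]:
    """Draw one experiment situation plus its ground truth.

    Gene ids are G0001… in panel order; module members occupy the first
    rows, then DEG genes, then background. Sample ids are case C001… and
    control N001….
    """
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{k + 1:0{width}d}" for k in range(config.n_genes)]
    case_ids = [f"C{k + 1:03d}" for k in range(config.n_case)]
    ctrl_ids = [f"N{k + 1:03d}" for k in range(config.n_control)]

    lo, hi = config.baseline_range
    mu = rng.uniform(lo, hi, size=config.n_genes)
    case = mu[:, None] + rng.normal(0.0, config.sigma, (config.n_genes, config.n_case))
    ctrl = mu[:, None] + rng.normal(
        0.0, config.sigma, (config.n_genes, config.n_control)
    )

    # module membership: consecutive blocks from the top of the panel
    members: list[list[int]] = []
    cursor = 0
    for mod in config.modules:
        members.append(list(range(cursor, cursor + mod.size)))
        cursor += mod.size
    hub_idx: list[int] = []
    if config.shared_hub:
        # first gene of the first module also joins the second module
        hub = members[0][0]
        members[1].append(hub)
        hub_idx.append(hub)

    for mod, rows in zip(config.modules, members):
        f_case = rng.normal(0.0, 1.0, config.n_case)
        case[rows] += mod.loading * f_case[None, :]
        f_ctrl = rng.normal(0.0, 1.0, config.n_control)
        if mod.active_in == "both":
            ctrl[rows] += mod.loading * f_ctrl[None, :]

    deg_rows = list(range(cursor, cursor + config.n_deg))
    case[deg_rows] += config.shift

    mes = MicroarrayExperimentSituation(
        pd.DataFrame(case, index=genes, columns=case_ids),
        pd.DataFrame(ctrl, index=genes, columns=ctrl_ids),
    )
    truth = SyntheticTruth(
        module_members=tuple(
            tuple(genes[r] for r in rows) for rows in members
        ),
        hub_genes=tuple(genes[r] for r in hub_idx),
        deg_genes=tuple(genes[r] for r in deg_rows),
        module_correlations=tuple(
            m.loading**2 / (m.loading**2 + config.sigma**2) for m in config.modules
        ),
    )
    return mes, truth


def recovery_report(scores: LRIScoreTable, truth: SyntheticTruth) -> dict:
    """Rank-based recovery of the planted module genes by LRI score.

    Reports the AUC of module membership against score, precision among
    the top-k ranked genes for k = number of planted genes, and whether
    every hub gene lands in the top decile of the ranking.
    """
    planted = truth.planted_genes
    if not planted:
        raise ValidationError("truth contains no planted module genes")
    y = np.array([g in planted for g in scores.genes], dtype=int)
    if y.all() or not y.any():
        raise ValidationError("scores must cover planted and background genes")
    x = np.array([float(s) for s in scores.scores])
    auc = float(roc_auc_score(y, x))

    ranked = scores.ranked()
    k = len(planted & set(scores.genes))
    topk = {g for _, g, _, _ in ranked[:k]}
    precision = len(topk & planted) / k if k else float("nan")

    hubs_top_decile = None
    if truth.hub_genes:
        decile = max(1, len(ranked) // 10)
        top = {g for _, g, _, _ in ranked[:decile]}
        hubs_top_decile = all(h in top for h in truth.hub_genes)
    return {
        "auc": auc,
        "top_k_precision": precision,
        "k": k,
        "hubs_in_top_decile": hubs_top_decile,
    }
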