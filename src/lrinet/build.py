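"""Construct co-expression networks from case/control expression data.

The expression data come as a *microarray experiment situation*: a gene
panel N with a diseased-sample matrix A^{S_D} and a reference-sample
matrix A^{S_R}, both genes × samples on the log2 scale. Which pairs of
genes count as "co-expressed" is a modelling choice; two deterministic
rules are offered:

``case-correlation``
    link i–j iff |corr(i, j)| over the diseased samples ≥ τ (the default;
    with a high τ this yields the sparse, hub-bearing networks the LRI
    analysis targets).
``differential-correlation``
    link i–j iff |corr_case(i, j) − corr_reference(i, j)| ≥ τ, selecting
    pairs whose co-regulation changes with disease state.

Both are monotone in τ and fully deterministic, so edge lists are
reproducible byte for byte.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .network import CoexpressionNetwork

logger = logging.getLogger(__name__)


@dataclass
class MicroarrayExperimentSituation:
    """E = ⟨N; S_D; S_R; A^{S_D}; A^{S_R}⟩.

    ``diseased`` and ``reference`` are genes × samples DataFrames sharing
    the same gene index (log2 expression); sample id sets must be
    disjoint.
    """

    diseased: pd.DataFrame
    reference: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.diseased.index.equals(self.reference.index):
            raise ValidationError("case and control matrices must share the gene index")
        if self.diseased.index.has_duplicates:
            dup = self.diseased.index[self.diseased.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        overlap = set(self.diseased.columns) & set(self.reference.columns)
        if overlap:
            raise ValidationError(
                f"sample ids present in both groups: {sorted(overlap)[:5]}"
            )
        for name, mat in (("case", self.diseased), ("control", self.reference)):
            if not np.isfinite(mat.to_numpy(dtype=float)).all():
                raise ValidationError(f"non-finite values in the {name} matrix")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.diseased.index)

    @property
    def diseased_samples(self) -> tuple[str, ...]:
        return tuple(self.diseased.columns)

    @property
    def reference_samples(self) -> tuple[str, ...]:
        return tuple(self.reference.columns)

    @classmethod
    def from_frames(
        cls, expression: pd.DataFrame, metadata: pd.DataFrame
    ) -> "MicroarrayExperimentSituation":
        """Split one genes × samples matrix by a metadata table with
        columns ``sample`` and ``group`` (case/control)."""
        meta = metadata.set_index("sample")["group"]
        bad = set(meta.unique()) - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        missing = [s for s in expression.columns if s not in meta.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing[:5]}")
        case_cols = [s for s in expression.columns if meta[s] == "case"]
        ctrl_cols = [s for s in expression.columns if meta[s] == "control"]
        return cls(expression[case_cols], expression[ctrl_cols])


@dataclass
class NetworkBuildConfig:
    method: Literal["case-correlation", "differential-correlation"] = "case-correlation"
    correlation: Literal["pearson", "spearman"] = "pearson"
    threshold: float = 0.9
    min_variance: float = 0.0
    gene_subset: Sequence[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValidationError("threshold must lie in (0, 1]")
        if self.min_variance < 0:
            raise ValidationError("min_variance must be non-negative")
        if self.method not in ("case-correlation", "differential-correlation"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.correlation not in ("pearson", "spearman"):
            raise ValidationError(f"unknown correlation {self.correlation!r}")


def _corr_matrix(mat: np.ndarray, kind: str) -> np.ndarray:
    if kind == "spearman":
        # rank-transform rows, then pearson on ranks
        mat = stats.rankdata(mat, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(mat)
    return c


def build_network(
    mes: MicroarrayExperimentSituation, config: NetworkBuildConfig | None = None
) -> CoexpressionNetwork:
    """Build g^E from the experiment situation under ``config``.

    Genes below the variance floor (or with exactly zero variance, where
    correlation is undefined) take part in no edge; they stay in the node
    set as isolated genes.
    """
    config = config or NetworkBuildConfig()
    genes = list(mes.genes)
    if config.gene_subset is not None:
        keep = set(config.gene_subset)
        unknown = keep - set(genes)
        if unknown:
            raise ValidationError(f"gene_subset ids not in matrix: {sorted(unknown)[:5]}")
        genes = [g for g in genes if g in keep]

    case = mes.diseased.loc[genes].to_numpy(dtype=float)
    need_ref = config.method == "differential-correlation"
    if case.shape[1] < 3:
        raise InsufficientDataError("need at least 3 case samples for correlation")
    if need_ref and mes.reference.shape[1] < 3:
        raise InsufficientDataError("need at least 3 control samples for correlation")

    var_case = case.var(axis=1, ddof=1)
    usable = var_case >= max(config.min_variance, 0.0)
    nonconstant = var_case > 0
    if need_ref:
        ref = mes.reference.loc[genes].to_numpy(dtype=float)
        nonconstant &= ref.var(axis=1, ddof=1) > 0
    usable &= nonconstant
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.warning(
            "%d gene(s) skipped (variance below floor or constant); they stay isolated",
            n_skipped,
        )
    if usable.sum() < 2:
        return CoexpressionNetwork(genes, [])

    idx = np.flatnonzero(usable)
    sub = case[idx]
    if config.method == "case-correlation":
        score = np.abs(_corr_matrix(sub, config.correlation))
    else:
        score = np.abs(
            _corr_matrix(sub, config.correlation)
            - _corr_matrix(ref[idx], config.correlation)
        )
    ii, jj = np.nonzero(np.triu(score >= config.threshold, k=1))
    edges = [(genes[idx[a]], genes[idx[b]]) for a, b in zip(ii, jj)]
    return CoexpressionNetwork(genes, edges)


def network_summary(network: CoexpressionNetwork) -> dict:
    """Node/edge counts, degree histogram and component sizes."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.edges)
    degrees = [network.degree(n) for n in network.nodes]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    comps = sorted(
        (len(c) for c in nx.connected_components(g) if len(c) > 1), reverse=True
    )
    return {
        "n_nodes": len(network.nodes),
        "n_active": network.n_active,
        "n_edges": network.n_edges,
        "degree_histogram": hist,
        "component_sizes": comps,
    }
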