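"""Salient-gene selection and downstream comparisons.

"Salient" genes are those with a strictly positive LRI — equivalently,
genes incident to at least one co-expression link. This module turns a
score table into the analysis deliverables: the ranked salient list,
score-distribution statistics and plots, set overlaps against marker or
DEG lists, right-sided hypergeometric enrichment over user-supplied GMT
gene sets, and Cohen's kappa between terms for grouping redundant
enrichment results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust
from .errors import ValidationError
from .game import LRIScoreTable


# ---------------------------------------------------------------------------
# selection & distribution
# ---------------------------------------------------------------------------


def select_salient(scores: LRIScoreTable, threshold: float | Fraction = 0) -> list[str]:
    """Genes with LRI strictly greater than ``threshold`` (default 0),
    in descending score order (lexicographic on ties)."""
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    return [g for _, g, s, _ in scores.ranked() if s > threshold]


def score_distribution(scores: LRIScoreTable) -> dict:
    """Summary statistics of the *positive* scores (zeros are the
    non-salient genes and are excluded)."""
    pos = np.array([float(s) for s in scores.scores if s > 0])
    if pos.size == 0:
        warnings.warn("no positive LRI scores; empty distribution summary")
        return {"count": 0}
    q1, med, q3 = np.percentile(pos, [25, 50, 75])
    return {
        "count": int(pos.size),
        "mean": float(pos.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(pos.min()),
        "max": float(pos.max()),
    }


def plot_score_distribution(scores: LRIScoreTable, out_dir: str | Path) -> list[Path]:
    """Violin, normal Q–Q and histogram plots of the positive scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = np.array([float(s) for s in scores.scores if s > 0])
    if pos.size == 0:
        warnings.warn("no positive LRI scores; nothing to plot")
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    fig, ax = plt.subplots()
    ax.violinplot(pos, showmedians=True)
    ax.set_ylabel("LRI score")
    paths.append(out_dir / "lri_violin.png")
    fig.savefig(paths[-1], dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots()
    stats.probplot(pos, dist="norm", plot=ax)
    paths.append(out_dir / "lri_qq.png")
    fig.savefig(paths[-1], dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.hist(pos, bins=min(30, max(5, pos.size // 4)))
    ax.set_xlabel("LRI score")
    ax.set_ylabel("genes")
    paths.append(out_dir / "lri_hist.png")
    fig.savefig(paths[-1], dpi=100)
    plt.close(fig)
    return paths


# ---------------------------------------------------------------------------
# overlaps
# ---------------------------------------------------------------------------


def _normalize(genes: Iterable[str], case_fold: bool) -> list[str]:
    out = []
    for g in genes:
        g = g.strip()
        out.append(g.casefold() if case_fold else g)
    return out


def set_overlap(a: Iterable[str], b: Iterable[str], case_fold: bool = False) -> dict:
    """Intersection record between two gene lists after id normalization
    (whitespace trim; optional case folding)."""
    sa = set(_normalize(a, case_fold))
    sb = set(_normalize(b, case_fold))
    inter = sorted(sa & sb)
    return {
        "n_common": len(inter),
        "n_only_a": len(sa - sb),
        "n_only_b": len(sb - sa),
        "common": inter,
    }


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) over a background universe."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    @classmethod
    def from_sets(
        cls,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str],
        descriptions: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        uni = frozenset(s.strip() for s in universe)
        clean = {k: frozenset(g.strip() for g in v) for k, v in sets.items()}
        desc = dict(descriptions or {})
        return cls(clean, {k: desc.get(k, "") for k in clean}, uni)


def hypergeom_pvalue(overlap: int, universe: int, term: int, query: int) -> float:
    """Right-tail hypergeometric P(X ≥ overlap) for the 2×2 margin
    (universe, term, query)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, term, query))


def hypergeom_enrichment(
    query: Sequence[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Right-sided hypergeometric over-representation of ``query`` in each
    set, BH-adjusted across all tested terms.

    Terms overlapping the query in fewer than ``min_genes`` genes are
    dropped after testing. Columns: term, overlap, term_size, query_size,
    universe_size, pvalue, adj_pvalue, significant, genes.
    """
    if min_genes < 1:
        raise ValidationError("min_genes must be at least 1")
    q = [g.strip() for g in query]
    if len(set(q)) != len(q):
        raise ValidationError("duplicate ids in query")
    outside = sorted(set(q) - sets.universe)
    if outside:
        raise ValidationError(
            f"query genes absent from the universe: {outside[:10]}"
        )
    qset = frozenset(q)
    m = len(sets.universe)
    rows = []
    for name in sorted(sets.sets):
        members = sets.sets[name] & sets.universe
        inter = sorted(qset & members)
        p = hypergeom_pvalue(len(inter), m, len(members), len(qset))
        rows.append((name, len(inter), len(members), p, inter))
    adj = bh_adjust([r[3] for r in rows]) if rows else np.array([])
    df = pd.DataFrame(
        {
            "term": [r[0] for r in rows],
            "overlap": [r[1] for r in rows],
            "term_size": [r[2] for r in rows],
            "query_size": len(qset),
            "universe_size": m,
            "pvalue": [r[3] for r in rows],
            "adj_pvalue": adj,
            "genes": [",".join(r[4]) for r in rows],
        }
    )
    df = df[df["overlap"] >= min_genes].copy()
    df["significant"] = df["adj_pvalue"] <= alpha
    return df.sort_values(["adj_pvalue", "term"]).reset_index(drop=True)


def term_kappa(
    term_a: Iterable[str], term_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Cohen's kappa between two terms' gene-membership indicators over
    the universe — the agreement score used to group redundant terms.

    Identical terms score 1.0 by convention even when chance agreement is
    perfect (both terms equal to the whole universe).
    """
    uni = frozenset(universe)
    a = frozenset(term_a)
    b = frozenset(term_b)
    if not a <= uni or not b <= uni:
        raise ValidationError("terms must be subsets of the universe")
    n = len(uni)
    if n == 0:
        raise ValidationError("empty universe")
    if a == b:
        return 1.0
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = n - n11 - n10 - n01
    po = (n11 + n00) / n
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    if pe == 1.0:
        raise ValidationError("chance agreement is 1 for non-identical terms")
    return (po - pe) / (1 - pe)


def kappa_groups(
    sets: GeneSetCollection, terms: Sequence[str], threshold: float = 0.4
) -> list[list[str]]:
    """Group terms whose pairwise kappa reaches ``threshold`` (single
    linkage over the kappa graph), the grouping rule used to collapse
    redundant enrichment terms."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(terms)
    for i, ta in enumerate(terms):
        for tb in terms[i + 1 :]:
            if term_kappa(sets.sets[ta], sets.sets[tb], sets.universe) >= threshold:
                g.add_edge(ta, tb)
    return [sorted(c) for c in nx.connected_components(g)]
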