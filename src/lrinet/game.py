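"""Microarray network games and the Link Relevance Index (LRI).

Given a co-expression network (N, g^E), the microarray network game
(g, v, g^E) is a cooperative game whose players are the *links*. Its
characteristic function averages unanimity games anchored at each active
gene's star::

    v(g) = (1/n(g^E)) * sum_{i in N(g^E)} u_{g_i^E}(g)

where the unanimity game ``u_T(g)`` is 1 iff T ⊆ g. The LRI of gene i is
the position value of this game: half the Shapley value of each of i's
incident links, summed. It admits a closed form over degrees::

    F_i = (1 / (2 n(g^E))) * (1 + sum_{j ~ i} 1 / deg(j))

for active genes (0 for isolated genes), and an equivalent star-sum form.
This module implements the value function and all three routes to the
allocation — closed form, star-sum form, and a brute-force link-Shapley
oracle — in exact rational arithmetic, plus checks of the four axioms the
allocation rule satisfies (efficiency, superfluous link, anonymity,
additivity).
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .errors import CapacityError, DegenerateGameError
from .network import CoexpressionNetwork, Edge, canonical_edge

ORACLE_LINK_CAP = 16  # 2^16 coalitions; brute force stays well under a minute


# ---------------------------------------------------------------------------
# score table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LRIScoreTable:
    """Per-gene LRI allocation with exact-rational and float views.

    Rows follow the node order of the scored network. Ranking is dense on
    ties (tied genes share the same rank, competition style) with
    lexicographic gene id as the secondary sort key.
    """

    genes: tuple[str, ...]
    scores: tuple[Fraction, ...]
    degrees: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.genes) == len(self.scores) == len(self.degrees)):
            raise ValueError("genes, scores and degrees must align")

    @property
    def total(self) -> Fraction:
        return sum(self.scores, Fraction(0))

    def as_dict(self) -> dict[str, Fraction]:
        return dict(zip(self.genes, self.scores))

    def score_of(self, gene: str) -> Fraction:
        return self.as_dict()[gene]

    def ranked(self) -> list[tuple[int, str, Fraction, int]]:
        """(rank, gene, score, degree) sorted by descending score.

        Competition ranking: after k tied genes the next rank jumps by k.
        """
        order = sorted(
            zip(self.genes, self.scores, self.degrees),
            key=lambda r: (-r[1], r[0]),
        )
        out: list[tuple[int, str, Fraction, int]] = []
        for pos, (gene, score, deg) in enumerate(order):
            if pos and score == out[-1][2]:
                rank = out[-1][0]
            else:
                rank = pos + 1
            out.append((rank, gene, score, deg))
        return out

    def to_dataframe(self, precision: int = 6) -> pd.DataFrame:
        """Ranked table with columns gene, lri_exact, lri_float, degree, rank."""
        rows = self.ranked()
        return pd.DataFrame(
            {
                "gene": [g for _, g, _, _ in rows],
                "lri_exact": [f"{s.numerator}/{s.denominator}" for _, _, s, _ in rows],
                "lri_float": [round(float(s), precision) for _, _, s, _ in rows],
                "degree": [d for _, _, _, d in rows],
                "rank": [r for r, _, _, _ in rows],
            }
        )


# ---------------------------------------------------------------------------
# the game
# ---------------------------------------------------------------------------


def unanimity_value(star_links: Iterable[Edge], g: Iterable[Edge]) -> int:
    """u_T(g): 1 iff every link of ``star_links`` lies in ``g``, else 0.

    The empty star is a subset of anything, so it returns 1 for any g.
    """
    return 1 if frozenset(star_links) <= frozenset(g) else 0


class MicroarrayNetworkGame:
    """The link game (g, v, g^E) built from a co-expression network.

    ``value`` is defined on any link set g ⊆ g^N (links outside g^E are
    simply never part of a star, so they never help a unanimity game).
    """

    def __init__(self, base_network: CoexpressionNetwork):
        self.base_network = base_network
        self._stars: dict[str, frozenset[Edge]] = {
            i: base_network.star(i) for i in base_network.active_players
        }

    @property
    def n_active(self) -> int:
        return len(self._stars)

    @property
    def unanimity_terms(self) -> dict[frozenset[Edge], int]:
        """Distinct stars with their multiplicities ᾱ (how many active
        genes share that exact star)."""
        terms: dict[frozenset[Edge], int] = {}
        for s in self._stars.values():
            terms[s] = terms.get(s, 0) + 1
        return terms

    def value(self, g: Iterable[tuple[str, str]]) -> Fraction:
        """v(g): the fraction of active genes whose full star lies in g."""
        if not self._stars:
            raise DegenerateGameError(
                "value function undefined: the base network has no links"
            )
        gset = frozenset(canonical_edge(a, b) for a, b in g)
        hits = sum(1 for s in self._stars.values() if s <= gset)
        return Fraction(hits, self.n_active)


def game_value(game: MicroarrayNetworkGame, g: Iterable[tuple[str, str]]) -> Fraction:
    """Functional alias for :meth:`MicroarrayNetworkGame.value`."""
    return game.value(g)


# ---------------------------------------------------------------------------
# allocations
# ---------------------------------------------------------------------------


def _empty_scores(network: CoexpressionNetwork, include_isolated: bool) -> LRIScoreTable:
    warnings.warn(
        "network has no links: every LRI score is zero", stacklevel=3
    )
    if include_isolated:
        genes = network.nodes
    else:
        genes = ()
    return LRIScoreTable(genes, (Fraction(0),) * len(genes), (0,) * len(genes))


def lri_closed(
    network: CoexpressionNetwork, include_isolated: bool = True
) -> LRIScoreTable:
    """LRI via the closed form F_i = (1 + Σ_{j~i} 1/deg(j)) / (2 n(g^E)).

    Isolated genes score 0 and are included in the table by default
    (``include_isolated=False`` drops them).
    """
    if network.n_edges == 0:
        return _empty_scores(network, include_isolated)
    n = network.n_active
    genes, scores, degrees = [], [], []
    for i in network.nodes:
        deg = network.degree(i)
        if deg == 0:
            if include_isolated:
                genes.append(i)
                scores.append(Fraction(0))
                degrees.append(0)
            continue
        acc = Fraction(1)
        for j in network.neighbors(i):
            acc += Fraction(1, network.degree(j))
        genes.append(i)
        scores.append(acc / (2 * n))
        degrees.append(deg)
    return LRIScoreTable(tuple(genes), tuple(scores), tuple(degrees))


def lri_sum(
    network: CoexpressionNetwork, include_isolated: bool = True
) -> LRIScoreTable:
    """LRI via the star-sum form.

    F_i = (1/n(g^E)) Σ_{j ∈ N(g_i^E)} |g'_i| / (2 |g_j^E|), where the sum
    runs over every gene j incident to a link of i's star (including i
    itself) and |g'_i| counts i's neighbours within j's star. Computed
    literally from stars, independent of the degree-based closed form.
    """
    if network.n_edges == 0:
        return _empty_scores(network, include_isolated)
    n = network.n_active
    genes, scores, degrees = [], [], []
    for i in network.nodes:
        star_i = network.star(i)
        if not star_i:
            if include_isolated:
                genes.append(i)
                scores.append(Fraction(0))
                degrees.append(0)
            continue
        incident = {g for e in star_i for g in e}  # N(g_i^E), includes i
        acc = Fraction(0)
        for j in sorted(incident):
            star_j = network.star(j)
            # neighbours k of i whose link ik lies within j's star
            n_within = sum(
                1
                for e in star_j
                if i in e  # edge ik with k the other endpoint
            )
            acc += Fraction(n_within, 2 * len(star_j))
        genes.append(i)
        scores.append(acc / n)
        degrees.append(len(star_i))
    return LRIScoreTable(tuple(genes), tuple(scores), tuple(degrees))


# ---------------------------------------------------------------------------
# brute-force position-value oracle
# ---------------------------------------------------------------------------


def link_shapley(
    players: Sequence[Edge], value: Callable[[frozenset[Edge]], Fraction]
) -> dict[Edge, Fraction]:
    """Exact Shapley value of each link-player under an arbitrary value map.

    Enumerates all 2^m coalitions with factorial weights; exact rationals
    throughout. Used by the axiom checks, where the value function need not
    be a single microarray network game (e.g. sums of games).
    """
    m = len(players)
    if m > ORACLE_LINK_CAP:
        raise CapacityError(
            f"{m} links exceeds the brute-force cap of {ORACLE_LINK_CAP}; "
            "use the closed form instead"
        )
    vals: list[Fraction] = [
        value(frozenset(p for k, p in enumerate(players) if mask >> k & 1))
        for mask in range(1 << m)
    ]
    w = [math.factorial(s) * math.factorial(m - s - 1) for s in range(m)]
    fm = math.factorial(m)
    out: dict[Edge, Fraction] = {}
    for k, link in enumerate(players):
        bit = 1 << k
        acc = Fraction(0)
        for mask in range(1 << m):
            if mask & bit:
                continue
            acc += w[mask.bit_count()] * (vals[mask | bit] - vals[mask])
        out[link] = acc / fm
    return out


def _link_shapley_counts(game: MicroarrayNetworkGame) -> dict[Edge, Fraction]:
    """Fast integer path of :func:`link_shapley` for a single game.

    v is (hit count)/n, so marginal sums accumulate as integers and the
    single division by m!·n happens at the end.
    """
    links = list(game.base_network.edges)
    m = len(links)
    star_masks = []
    idx = {e: k for k, e in enumerate(links)}
    for star in game.unanimity_terms:
        mask = 0
        for e in star:
            mask |= 1 << idx[e]
        star_masks.append((mask, game.unanimity_terms[star]))
    counts = [0] * (1 << m)
    for mask in range(1 << m):
        counts[mask] = sum(
            mult for smask, mult in star_masks if smask & mask == smask
        )
    w = [math.factorial(s) * math.factorial(m - s - 1) for s in range(m)]
    denom = math.factorial(m) * game.n_active
    out: dict[Edge, Fraction] = {}
    for k, link in enumerate(links):
        bit = 1 << k
        num = 0
        for mask in range(1 << m):
            if mask & bit:
                continue
            num += w[mask.bit_count()] * (counts[mask | bit] - counts[mask])
        out[link] = Fraction(num, denom)
    return out


def position_value_oracle(
    game: MicroarrayNetworkGame | CoexpressionNetwork,
    include_isolated: bool = True,
    cap: int = ORACLE_LINK_CAP,
) -> LRIScoreTable:
    """Brute-force LRI: each gene gets half the Shapley value of each
    incident link in the link game.

    Independent of both formula routes; exponential in the link count
    (capped at ``cap`` links).
    """
    if isinstance(game, CoexpressionNetwork):
        network = game
        if network.n_edges == 0:
            return _empty_scores(network, include_isolated)
        game = MicroarrayNetworkGame(network)
    else:
        network = game.base_network
        if network.n_edges == 0:
            return _empty_scores(network, include_isolated)
    if network.n_edges > cap:
        raise CapacityError(
            f"{network.n_edges} links exceeds the brute-force cap of {cap}; "
            "use the closed form instead"
        )
    shapley = _link_shapley_counts(game)
    genes, scores, degrees = [], [], []
    for i in network.nodes:
        deg = network.degree(i)
        if deg == 0 and not include_isolated:
            continue
        acc = Fraction(0)
        for e in network.star(i):
            acc += shapley[e] / 2
        genes.append(i)
        scores.append(acc)
        degrees.append(deg)
    return LRIScoreTable(tuple(genes), tuple(scores), tuple(degrees))


# ---------------------------------------------------------------------------
# axiom checks
# ---------------------------------------------------------------------------


@dataclass
class AxiomReport:
    """Pass/fail record for the four LRI axioms; failures are recorded,
    never raised."""

    efficiency: bool
    superfluous_link: bool
    anonymity: bool
    additivity: bool
    details: dict = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return (
            self.efficiency
            and self.superfluous_link
            and self.anonymity
            and self.additivity
        )


def _complete_links(nodes: Sequence[str]) -> list[Edge]:
    return [
        canonical_edge(a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
    ]


def check_axioms(
    network: CoexpressionNetwork, trials: int = 10, seed: int = 0
) -> AxiomReport:
    """Verify efficiency, superfluous-link invariance, anonymity and
    additivity on ``network``.

    Anonymity uses ``trials`` random relabelings; the superfluous-link and
    additivity checks go through the brute-force link-Shapley, so the
    network must be small enough for the oracle.
    """
    rng = random.Random(seed)
    game = MicroarrayNetworkGame(network)
    base = lri_closed(network)
    details: dict = {}

    # efficiency: Σ F_i = v(g^E)
    efficiency = base.total == game.value(network.edges)
    details["total"] = base.total

    # superfluous link: evaluating on a supernetwork g ⊃ g^E (extra links
    # belong to no star) leaves every allocation unchanged.
    extras = [e for e in _complete_links(list(network.nodes)) if e not in set(network.edges)]
    rng.shuffle(extras)
    extras = extras[: max(0, min(len(extras), ORACLE_LINK_CAP - network.n_edges, 3))]
    players = list(network.edges) + extras
    shap = link_shapley(players, game.value)
    super_scores = {
        i: sum((shap[e] / 2 for e in network.star(i)), Fraction(0))
        + sum((shap[e] / 2 for e in extras if i in e), Fraction(0))
        for i in network.nodes
    }
    superfluous = all(super_scores[i] == base.score_of(i) for i in network.nodes)
    details["extra_links"] = extras

    # anonymity: relabeling genes permutes scores identically
    anonymity = True
    labels = list(network.nodes)
    for _ in range(trials):
        perm = labels[:]
        rng.shuffle(perm)
        mapping = dict(zip(labels, perm))
        relabeled = lri_closed(network.relabel(mapping))
        if any(
            relabeled.score_of(mapping[i]) != base.score_of(i) for i in labels
        ):
            anonymity = False
            break

    # additivity: split g^E into two component-disjoint link games; the
    # Shapley allocation of v1+v2 equals the sum of the separate ones.
    edges = list(network.edges)
    cut = rng.randrange(len(edges) + 1)
    rng.shuffle(edges)
    e1, e2 = edges[:cut], edges[cut:]
    net1 = CoexpressionNetwork(network.nodes, e1)
    net2 = CoexpressionNetwork(network.nodes, e2)

    def value_of(net: CoexpressionNetwork) -> Callable[[frozenset[Edge]], Fraction]:
        if net.n_edges == 0:
            return lambda g: Fraction(0)
        return MicroarrayNetworkGame(net).value

    v1, v2 = value_of(net1), value_of(net2)
    shap_sum = link_shapley(edges, lambda g: v1(g) + v2(g))
    shap1 = link_shapley(edges, v1)
    shap2 = link_shapley(edges, v2)
    additivity = all(
        shap_sum[e] == shap1[e] + shap2[e] for e in edges
    )

    return AxiomReport(efficiency, superfluous, anonymity, additivity, details)
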