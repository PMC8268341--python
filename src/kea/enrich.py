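"""Overlap-aware two-directional kinase enrichment on ranked site lists.

Each kinase defines a set of measured substrate sites.  For both the
over- and the under-activity ranking of the site universe, every set is
scored with the exact minimum-hypergeometric (mHG) test — a cutoff-free
ranked-list enrichment statistic (see :mod:`kea._mhg`).  Because substrate
sets overlap heavily (shared substrates, kinase families), a set can reach
significance purely through sites it shares with a genuinely active
kinase.  Such false positives are eliminated through a set-dependence
graph: an edge A -> B records that B loses significance once A's members
are removed from both B and the universe, and a node is discarded when the
union of its explaining neighbours accounts for all of its signal.
Retained kinases are ranked by a PageRank-style centrality on the reversed
dependence graph, so sets that explain others accumulate score.

Family-wise correction is Bonferroni over the number of sets tested; the
per-kinase FDR is estimated by Monte-Carlo permutation of the ranked list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._mhg import mhg_test
from .io import base_site_key
from .ksdb import KinaseSubstrateDB

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KinaseSet:
    """A kinase's substrate sites restricted to the measured universe."""

    name: str
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


def build_sets(
    db: KinaseSubstrateDB,
    universe: set[str] | list[str],
    min_set_size: int = 2,
) -> list[KinaseSet]:
    """Intersect each kinase's substrates with the measured site universe.

    Universe keys may carry multiplicity suffixes; matching is on the base
    (gene, residue, position) key, and members are reported as universe
    keys.  Sets smaller than ``min_set_size`` are dropped.
    """
    universe = list(universe)
    by_base: dict[str, list[str]] = {}
    for key in universe:
        by_base.setdefault(base_site_key(key), []).append(key)
    sets: list[KinaseSet] = []
    n_dropped = 0
    for kinase in db.kinases:
        members = frozenset(
            m for sub in db.associations[kinase] for m in by_base.get(sub, ())
        )
        if len(members) >= min_set_size:
            sets.append(KinaseSet(name=kinase, members=members))
        else:
            n_dropped += 1
    if n_dropped:
        log.info("build_sets: dropped %d kinases below min_set_size", n_dropped)
    if not sets:
        raise ValueError("no kinase has enough measured substrates")
    return sets


def primary_set_pvalue(ranked, s: KinaseSet) -> float:
    """Exact mHG p-value of one kinase set against a ranked site list."""
    _, p = _set_stat_p(ranked.index(), len(ranked), s.members)
    return p


def _set_stat_p(
    rank_of: dict[str, int], N: int, members
) -> tuple[float, float]:
    positions = np.array(sorted(rank_of[m] for m in members), dtype=np.int64)
    if positions.size == 0:
        raise ValueError("set has no members in the ranked universe")
    return mhg_test(positions, N)


def eliminate_overlaps(
    sets: list[KinaseSet],
    pvalues: dict[str, float],
    ranked,
    set_p_cutoff: float = 0.01,
) -> nx.DiGraph:
    """Build the set-dependence graph among significant kinase sets.

    Nodes are sets with primary p <= ``set_p_cutoff``.  For every ordered
    pair (A, B) with overlapping members, B's p-value is recomputed on
    B \\ A over the universe with A's members removed; if significance is
    lost, an edge A -> B marks B as (partly) explained by A.  A node is
    discarded only when removing the union of all its explainers destroys
    its significance.  The procedure is deterministic and independent of
    the input order of the sets.
    """
    sig = sorted(
        (s for s in sets if pvalues[s.name] <= set_p_cutoff), key=lambda s: s.name
    )
    g = nx.DiGraph()
    ranked_sites = list(ranked.sites)
    rank_of = ranked.index()
    for s in sig:
        g.add_node(s.name, primary_p=pvalues[s.name], n_members=len(s), retained=True)
    by_name = {s.name: s for s in sig}

    for a in sig:
        for b in sig:
            if a.name == b.name or not (a.members & b.members):
                continue
            p_reduced = _pvalue_without(b, a.members, ranked_sites, rank_of)
            if p_reduced > set_p_cutoff:
                g.add_edge(a.name, b.name, p_without=p_reduced)

    # mutually explaining pairs: only the stronger set (smaller primary p,
    # ties by name) may explain the weaker one, otherwise both would vanish
    for a_name, b_name in list(g.edges):
        if g.has_edge(b_name, a_name):
            pa, pb = pvalues[a_name], pvalues[b_name]
            if (pa, a_name) < (pb, b_name):
                g.remove_edge(b_name, a_name)

    for name in g.nodes:
        explainers = list(g.predecessors(name))
        if not explainers:
            continue
        removed = frozenset().union(*(by_name[e].members for e in explainers))
        p_all = _pvalue_without(by_name[name], removed, ranked_sites, rank_of)
        if p_all > set_p_cutoff:
            g.nodes[name]["retained"] = False
        g.nodes[name]["p_without_explainers"] = p_all
    return g


def _pvalue_without(
    s: KinaseSet,
    removed: frozenset[str],
    ranked_sites: list[str],
    rank_of: dict[str, int],
) -> float:
    """p-value of s with ``removed`` sites deleted from set and universe."""
    kept_members = s.members - removed
    if not kept_members:
        return 1.0
    # ranks within the reduced universe: original rank minus removed sites above
    removed_positions = np.array(sorted(rank_of[r] for r in removed), dtype=np.int64)
    N = len(ranked_sites) - len(removed_positions)
    positions = np.array(sorted(rank_of[m] for m in kept_members), dtype=np.int64)
    shift = np.searchsorted(removed_positions, positions)
    _, p = mhg_test(positions - shift, N)
    return p


def rank_score(g: nx.DiGraph, damping: float = 0.85) -> dict[str, float]:
    """PageRank centrality on the reversed dependence graph.

    Edges point from explaining to explained sets, so on the reversed graph
    score flows toward the explainers; an edgeless graph yields uniform
    scores.  Scores sum to 1 over the nodes.
    """
    if g.number_of_nodes() == 0:
        return {}
    return nx.pagerank(g.reverse(copy=True), alpha=damping, tol=1e-10, max_iter=1000)


def correct_and_fdr(
    sets: list[KinaseSet],
    pvalues: dict[str, float],
    ranked,
    n_sets_tested: int | None = None,
    b_null: int = 100,
    seed: int | None = None,
    p_cutoff: float = 0.01,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni correction and Monte-Carlo FDR for the primary p-values.

    The null distribution is generated by ``b_null`` random permutations of
    the ranked list (one shared permutation per replicate, preserving the
    overlap structure of the sets); the FDR at each observed p is the mean
    null count of sets at least as significant divided by the observed
    count, clipped to [0, 1].  A kinase is flagged ``significant`` when
    primary p <= ``p_cutoff`` and FDR <= ``fdr_cutoff``.
    """
    if n_sets_tested is None:
        n_sets_tested = len(sets)
    if b_null < 10:
        warnings.warn("b_null < 10: FDR estimate is unstable")
    rng = np.random.default_rng(seed)
    N = len(ranked)
    rank_of = ranked.index()
    member_positions = [
        np.array(sorted(rank_of[m] for m in s.members), dtype=np.int64) for s in sets
    ]
    obs = np.array([pvalues[s.name] for s in sets])

    null_ps = np.empty((b_null, len(sets)))
    for b in range(b_null):
        perm = rng.permutation(N)
        for j, pos in enumerate(member_positions):
            _, null_ps[b, j] = mhg_test(perm[pos], N)

    fdr = np.empty(len(sets))
    for j, p in enumerate(obs):
        null_count = (null_ps <= p).sum() / b_null
        obs_count = (obs <= p).sum()
        fdr[j] = min(1.0, null_count / obs_count) if obs_count else 1.0
    corrected = np.minimum(1.0, obs * n_sets_tested)
    out = pd.DataFrame(
        {
            "kinase": [s.name for s in sets],
            "primary_p": obs,
            "corrected_p": corrected,
            "fdr": fdr,
            "n_members": [len(s) for s in sets],
            "significant": (obs <= p_cutoff) & (fdr <= fdr_cutoff),
        }
    ).set_index("kinase")
    return out


def _leading_members(ranked, s: KinaseSet) -> list[str]:
    """Members inside the prefix attaining the minimum hypergeometric tail."""
    from ._mhg import _hg_upper_tail

    rank_of = ranked.index()
    N = len(ranked)
    positions = sorted(rank_of[m] for m in s.members)
    K = len(positions)
    best, best_j = 1.0, -1
    for j, pos in enumerate(positions):
        tail = _hg_upper_tail(N, K, pos + 1, j + 1)
        if tail < best:
            best, best_j = tail, j
    inv = {v: k for k, v in rank_of.items()}
    return [inv[p] for p in positions[: best_j + 1]]


def enrich_direction(
    ranked,
    sets: list[KinaseSet],
    set_p_cutoff: float = 0.01,
    fdr_cutoff: float = 0.05,
    b_null: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full enrichment for one direction: mHG, overlap graph, scores, FDR."""
    pvalues = {s.name: primary_set_pvalue(ranked, s) for s in sets}
    graph = eliminate_overlaps(sets, pvalues, ranked, set_p_cutoff=set_p_cutoff)
    scores = rank_score(graph)
    stats = correct_and_fdr(
        sets, pvalues, ranked,
        b_null=b_null, seed=seed, p_cutoff=set_p_cutoff, fdr_cutoff=fdr_cutoff,
    )
    by_name = {s.name: s for s in sets}
    stats["rank_score"] = [scores.get(k, 0.0) for k in stats.index]
    stats["retained"] = [
        bool(graph.nodes[k]["retained"]) if k in graph else False for k in stats.index
    ]
    stats["explained_by"] = [
        ";".join(sorted(graph.predecessors(k))) if k in graph else ""
        for k in stats.index
    ]
    stats["leading_members"] = [
        ";".join(_leading_members(ranked, by_name[k])) if stats.loc[k, "significant"] else ""
        for k in stats.index
    ]
    stats["direction"] = ranked.direction
    return stats.sort_values(["significant", "primary_p"], ascending=[False, True])


def enrich_kinases(
    diff: pd.DataFrame,
    db: KinaseSubstrateDB,
    min_set_size: int = 2,
    set_p_cutoff: float = 0.01,
    fdr_cutoff: float = 0.05,
    b_null: int = 100,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Two-directional kinase enrichment from a differential site table.

    Runs the over- and under-activity rankings through set construction,
    exact mHG testing, overlap elimination, dependence-graph scoring and
    FDR estimation.  Both directions share the same seed, which makes the
    output exactly antisymmetric under negation of all fold changes.
    """
    from .diffexp import rank_sites

    universe = list(diff.index)
    sets = build_sets(db, universe, min_set_size=min_set_size)
    out = {}
    for direction in ("over", "under"):
        ranked = rank_sites(diff, direction)
        out[direction] = enrich_direction(
            ranked, sets,
            set_p_cutoff=set_p_cutoff, fdr_cutoff=fdr_cutoff,
            b_null=b_null, seed=seed,
        )
    return out


def reported_kinases(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Kinases passing the significance thresholds and overlap elimination."""
    frames = []
    for direction, table in results.items():
        keep = table[table["significant"] & table["retained"]].copy()
        frames.append(keep)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames)
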