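"""Consensus coabundance networks and guild extraction.

For every unordered taxon pair the clr abundance of one taxon is regressed
(robustly) on the other within each study; per-study slopes are pooled with
random-effects models and, per focal taxon, Bonferroni-corrected over its
partners.  A pair is coabundant -- an undirected edge -- when the pooled
estimate is positive with q below a stringent threshold (default 0.001) in
at least one focal direction.  Node centralities (degree, shortest-path
betweenness, eigenvector hub score) describe how core a taxon is; a guild
is a taxon subset in which every member is linked to at least a stated
fraction (default 50%) of the other members, extracted by greedily peeling
the lowest-internal-degree member until the condition holds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .meta import (
    EffectEstimate,
    MetaSummary,
    bonferroni_adjust,
    consistency_score,
    permutation_test_re,
    random_effects_pool,
    robust_linear_fit,
)
from .profiles import StudyCollection, ValidationError, clr_transform

__all__ = [
    "PairAssociation",
    "GuildResult",
    "pairwise_taxon_associations",
    "build_consensus_network",
    "node_centralities",
    "per_study_networks",
    "compare_centrality_groups",
    "extract_guild",
]

logger = logging.getLogger(__name__)


@dataclass
class PairAssociation:
    """Pooled association of an unordered taxon pair, one record per focal
    direction (focal taxon regressed on partner)."""

    focal: str
    partner: str
    meta: MetaSummary
    q_value: float = float("nan")


@dataclass
class GuildResult:
    members: list
    internal_degree: dict = field(default_factory=dict)
    density_ok: bool = False


def _clr_tables(collection: StudyCollection, pseudocount) -> dict:
    return {
        s: (t if t.scale == "clr" else clr_transform(t, pseudocount))
        for s, t in collection.tables.items()
    }


def pairwise_taxon_associations(
    collection: StudyCollection,
    taxa,
    min_n: int = 10,
    pseudocount: float | str = "auto",
    detected_only: bool = True,
) -> list[PairAssociation]:
    """Random-effects pooled pairwise associations between clr abundances.

    For each ordered pair (focal, partner) and each study, a robust fit of
    clr(focal) on clr(partner); pooled across studies; per focal taxon the
    pooled p-values over all partners are Bonferroni-corrected.  A study is
    skipped for a pair (with a log entry) when either taxon is undetected
    there, or when fewer than ``min_n`` samples are available.
    """
    taxa = sorted(set(taxa))
    if len(collection.tables) < 2:
        raise ValidationError("pairwise associations require >= 2 studies")
    clr_tables = _clr_tables(collection, pseudocount)
    detected: dict[str, dict[str, bool]] = {}
    for study, table in collection.tables.items():
        if table.scale in ("counts", "relative"):
            det = (table.values > 0).any(axis=1)
        else:
            det = pd.Series(True, index=table.values.index)
        detected[study] = det.to_dict()

    # per study, extract the taxa submatrix once
    arrays = {}
    for study in collection.study_ids:
        table = clr_tables[study]
        present = [t for t in taxa if t in table.values.index]
        arrays[study] = table.values.loc[present]

    effects: dict[tuple[str, str], list[EffectEstimate]] = {}
    for i, j in itertools.combinations(taxa, 2):
        for study in collection.study_ids:
            sub = arrays[study]
            if i not in sub.index or j not in sub.index:
                continue
            if detected_only and not (detected[study].get(i) and detected[study].get(j)):
                logger.info("pair (%s, %s): study %s skipped (undetected)", i, j, study)
                continue
            xi = sub.loc[i].to_numpy(dtype=float)
            xj = sub.loc[j].to_numpy(dtype=float)
            if xi.size < min_n:
                continue
            for focal, partner, y, x in ((i, j, xi, xj), (j, i, xj, xi)):
                try:
                    fit = robust_linear_fit(y, x)
                except ValidationError:
                    continue
                effects.setdefault((focal, partner), []).append(
                    EffectEstimate(focal, study, fit.estimate, fit.std_error, fit.p_value, fit.n)
                )
    out: list[PairAssociation] = []
    by_focal: dict[str, list[PairAssociation]] = {}
    for (focal, partner), effs in sorted(effects.items()):
        ms = random_effects_pool(effs)
        if ms.pooled_estimate != 0:
            ms.consistency = consistency_score(effs, ms.pooled_estimate)
        pa = PairAssociation(focal, partner, ms)
        out.append(pa)
        by_focal.setdefault(focal, []).append(pa)
    for focal, pas in by_focal.items():
        qs = bonferroni_adjust([pa.meta.p_value for pa in pas])
        for pa, q in zip(pas, qs):
            pa.q_value = float(q)
            pa.meta.q_value = float(q)
    return out


def build_consensus_network(
    pair_meta: list[PairAssociation],
    edge_q: float = 0.001,
    groups: dict | None = None,
    require_both: bool = False,
    nodes=None,
) -> nx.Graph:
    """Undirected consensus network from pooled pair associations.

    An edge joins a pair when the pooled estimate is positive and q <=
    ``edge_q`` in at least one focal direction (both directions when
    ``require_both``).  Nodes may be annotated with taxon-group labels.
    """
    g = nx.Graph()
    taxa = set()
    for pa in pair_meta:
        taxa.update((pa.focal, pa.partner))
    if nodes is not None:
        taxa.update(nodes)
    for t in sorted(taxa):
        g.add_node(t, group=(groups or {}).get(t, "other"))
    passed: dict[tuple[str, str], list[PairAssociation]] = {}
    for pa in pair_meta:
        key = tuple(sorted((pa.focal, pa.partner)))
        if pa.q_value <= edge_q and pa.meta.pooled_estimate > 0:
            passed.setdefault(key, []).append(pa)
    for (a, b), pas in sorted(passed.items()):
        if require_both and len(pas) < 2:
            continue
        est = float(np.mean([pa.meta.pooled_estimate for pa in pas]))
        g.add_edge(a, b, pooled_estimate=est, q_value=float(min(pa.q_value for pa in pas)))
    if g.number_of_edges() == 0:
        logger.warning("consensus network has no edges at q <= %g", edge_q)
    return g


def node_centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, shortest-path betweenness and eigenvector hub score per node.

    The hub score is the principal-eigenvector centrality of the adjacency
    structure normalised to max 1 (hub and authority coincide for undirected
    graphs); isolated nodes and edgeless graphs score 0.
    """
    nodes = sorted(net.nodes)
    degree = {n: net.degree(n) for n in nodes}
    betweenness = nx.betweenness_centrality(net, normalized=False)
    hub = dict.fromkeys(nodes, 0.0)
    if net.number_of_edges() > 0:
        # principal eigenvector of the whole adjacency matrix (dense eigh:
        # robust where ARPACK fails on tiny graphs); mass concentrates on the
        # dominant component, peripheral components score near zero
        adj = nx.to_numpy_array(net, nodelist=nodes)
        w, v = np.linalg.eigh(adj)
        vec = np.abs(v[:, np.argmax(w)])
        top = vec.max()
        if top > 0:
            vec = vec / top
        hub = {n: float(val) for n, val in zip(nodes, vec)}
    out = pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=int),
            "betweenness": pd.Series(betweenness, dtype=float),
            "hub_score": pd.Series(hub, dtype=float),
        }
    ).loc[nodes]
    out.index.name = "taxon"
    return out


def per_study_networks(
    collection: StudyCollection,
    taxa,
    edge_q: float = 0.001,
    min_n: int = 10,
    pseudocount: float | str = "auto",
) -> dict[str, nx.Graph]:
    """One coabundance network per study (single-study fits, Bonferroni per
    focal taxon within the study)."""
    taxa = sorted(set(taxa))
    clr_tables = _clr_tables(collection, pseudocount)
    out = {}
    for study in collection.study_ids:
        table = clr_tables[study]
        present = [t for t in taxa if t in table.values.index]
        sub = table.values.loc[present]
        if sub.shape[1] < min_n:
            logger.info("study %s skipped (n=%d)", study, sub.shape[1])
            continue
        pas: list[PairAssociation] = []
        by_focal: dict[str, list[PairAssociation]] = {}
        for i, j in itertools.combinations(present, 2):
            xi = sub.loc[i].to_numpy(dtype=float)
            xj = sub.loc[j].to_numpy(dtype=float)
            for focal, partner, y, x in ((i, j, xi, xj), (j, i, xj, xi)):
                try:
                    fit = robust_linear_fit(y, x)
                except ValidationError:
                    continue
                ms = MetaSummary(
                    feature=focal, pooled_estimate=fit.estimate, tau2=0.0, cochran_q=0.0,
                    p_value=fit.p_value, k=1, se_pooled=fit.std_error,
                )
                pa = PairAssociation(focal, partner, ms)
                pas.append(pa)
                by_focal.setdefault(focal, []).append(pa)
        for focal, fl in by_focal.items():
            qs = bonferroni_adjust([pa.meta.p_value for pa in fl])
            for pa, q in zip(fl, qs):
                pa.q_value = float(q)
        out[study] = build_consensus_network(pas, edge_q=edge_q, nodes=present)
    return out


def compare_centrality_groups(
    per_study_nets: dict[str, nx.Graph],
    group_a,
    group_b,
    measure: str = "degree",
    B: int = 999,
    rng=None,
) -> MetaSummary:
    """Random-effects comparison of a centrality measure between two rosters.

    Per study, the standardised mean difference (group_a minus group_b) of
    the chosen centrality is the study effect; effects are pooled with a
    DL model, a sign-flip permutation p and directional consistency are
    attached.  Studies missing either roster are skipped with a log entry.
    With a single usable study the permutation test is refused (p_perm NaN).
    """
    group_a, group_b = list(group_a), list(group_b)
    effects = []
    for study, net in sorted(per_study_nets.items()):
        cent = node_centralities(net)[measure]
        a = cent.reindex([t for t in group_a if t in cent.index]).dropna()
        b = cent.reindex([t for t in group_b if t in cent.index]).dropna()
        if a.empty or b.empty:
            logger.info("study %s skipped (roster absent from network)", study)
            continue
        pooled_sd = float(np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2))
        if not np.isfinite(pooled_sd) or pooled_sd == 0:
            pooled_sd = 1.0
        diff = float(a.mean() - b.mean()) / pooled_sd
        se = float(np.sqrt(1 / len(a) + 1 / len(b)))
        effects.append(EffectEstimate(measure, study, diff, se, 1.0, max(len(a) + len(b), 3)))
    if not effects:
        raise ValidationError("no studies with both rosters present")
    ms = random_effects_pool(effects)
    if ms.pooled_estimate != 0:
        ms.consistency = consistency_score(effects, ms.pooled_estimate)
    if len(effects) >= 2:
        ms.p_perm = permutation_test_re(effects, B=B, rng=rng)
    else:
        ms.p_perm = float("nan")  # permutation refused for k < 2
    return ms


def extract_guild(net: nx.Graph, seed_roster, frac: float = 0.5) -> GuildResult:
    """Maximal subset of a roster in which every member is adjacent to at
    least ``frac`` of the other members.

    Greedy peel: repeatedly drop the member with the lowest internal degree
    (ties broken lexicographically by taxon id) while any member is adjacent
    to fewer than ``ceil(frac * (m - 1))`` of the other remaining members.
    """
    if not 0 < frac <= 1:
        raise ValidationError("frac must lie in (0, 1]")
    members = sorted(set(seed_roster))
    missing = [t for t in members if t not in net]
    if missing:
        raise ValidationError(f"roster taxa absent from network: {missing[:5]}")

    def internal_degree(ms: list) -> dict:
        mset = set(ms)
        return {t: sum(1 for nb in net.neighbors(t) if nb in mset) for t in ms}

    while members:
        deg = internal_degree(members)
        need = int(np.ceil(frac * (len(members) - 1)))
        if all(d >= need for d in deg.values()):
            return GuildResult(members=members, internal_degree=deg, density_ok=True)
        worst = min(members, key=lambda t: (deg[t], t))
        members = [t for t in members if t != worst]
    return GuildResult(members=[], internal_degree={}, density_ok=False)
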