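"""Shared fixtures: small named graphs, a session-scoped synthetic bundle
and its pipeline run, plus the brute-force all-pairs geodesic oracle used
to validate the shortest-path metrics."""

from __future__ import annotations

import itertools
import math
from collections import deque

import networkx as nx
import pytest

from netprio import SyntheticConfig, generate_bundle, write_bundle
from netprio.pipeline import PipelineConfig, run_pipeline


# ---------------------------------------------------------------------------
# Small named graphs
# ---------------------------------------------------------------------------

@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture
def star5():
    """Star: center X with 4 leaves."""
    g = nx.Graph()
    g.add_edges_from([("X", c) for c in "ABCD"])
    return g


@pytest.fixture
def paw():
    """Triangle A,B,C with pendant D attached to A."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C"), ("A", "D")])
    return g


@pytest.fixture
def cycle4():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
    return g


# ---------------------------------------------------------------------------
# Brute-force geodesic oracle
# ---------------------------------------------------------------------------

def _all_geodesics(g: nx.Graph, s, t):
    """Every shortest s-t path, by BFS distance + DFS back-enumeration."""
    dist = {s: 0}
    q = deque([s])
    while q:
        v = q.popleft()
        for w in g.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    if t not in dist:
        return []
    paths = []

    def walk(node, acc):
        if node == s:
            paths.append(list(reversed(acc + [s])))
            return
        for u in g.neighbors(node):
            if dist.get(u, math.inf) == dist[node] - 1:
                walk(u, acc + [node])

    walk(t, [])
    return paths


def brute_force_path_metrics(g: nx.Graph):
    """Stress / normalized betweenness / average shortest path length by
    exhaustive enumeration of every geodesic of every unordered pair."""
    nodes = sorted(g.nodes())
    stress = {v: 0 for v in nodes}
    bet = {v: 0.0 for v in nodes}
    dist_sum = {v: 0 for v in nodes}
    reached = {v: 0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_geodesics(g, s, t)
        if not paths:
            continue
        d = len(paths[0]) - 1
        dist_sum[s] += d
        dist_sum[t] += d
        reached[s] += 1
        reached[t] += 1
        through = {}
        for p in paths:
            for v in p[1:-1]:
                through[v] = through.get(v, 0) + 1
        for v, c in through.items():
            stress[v] += c
            bet[v] += c / len(paths)
    comp_size = {}
    for comp in nx.connected_components(g):
        for v in comp:
            comp_size[v] = len(comp)
    bet_norm = {}
    for v in nodes:
        norm = (comp_size[v] - 1) * (comp_size[v] - 2) / 2
        bet_norm[v] = bet[v] / norm if norm > 0 else 0.0
    aspl = {v: dist_sum[v] / reached[v] if reached[v] else math.nan
            for v in nodes}
    return stress, bet_norm, aspl


@pytest.fixture
def geodesic_oracle():
    return brute_force_path_metrics


# ---------------------------------------------------------------------------
# Session-scoped synthetic bundle and pipeline run
# ---------------------------------------------------------------------------

BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle(SyntheticConfig(seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(default_bundle, d)
    return d


@pytest.fixture(scope="session")
def pipeline_report(bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig(
        edges=str(bundle_dir / "edges.tsv"),
        ontology=str(bundle_dir / "ontology.obo"),
        annotations=str(bundle_dir / "annotations.tsv"),
        phenotypes=str(bundle_dir / "phenotypes.tsv"),
        curated=str(bundle_dir / "curated_genes.txt"),
        generic=str(bundle_dir / "generic_genes.txt"),
        categories=str(bundle_dir / "term_categories.tsv"),
        outdir=str(out),
        seed=BUNDLE_SEED,
    )
    return run_pipeline(cfg)
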