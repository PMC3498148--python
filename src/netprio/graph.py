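"""Interactome construction and node-level network metrics.

The interactome is a simple undirected graph of gene symbols (a
:class:`networkx.Graph`). This module builds it from an edge-list file or
in-memory rows, extracts the giant component, computes the seven node
metrics used for hub ranking (degree, neighborhood connectivity, stress,
betweenness, average shortest path length, clustering coefficient,
topological coefficient), and fits power laws to metric distributions by
maximum likelihood with a Kolmogorov-Smirnov choice of the lower cutoff.

Metric conventions
------------------
* Stress counts each geodesic once per unordered endpoint pair.
* Betweenness is the Freeman/Brandes pair-ratio sum normalized by
  ``(N-1)(N-2)/2`` where ``N`` is the size of the node's connected
  component; pairs in different components contribute nothing.
* Values that are undefined for a node (neighborhood connectivity at
  degree 0, clustering coefficient at degree < 2, average shortest path
  length for isolated nodes) are ``NaN`` in the metrics table and written
  as ``NA`` on disk. The topological coefficient is defined as 0 for
  degree <= 1 nodes, following common interactome-tool convention.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import zeta

logger = logging.getLogger(__name__)

#: Column order of the metrics table (and of the TSV written by
#: :func:`write_metrics`).
METRIC_COLUMNS = [
    "degree",
    "neigh_conn",
    "stress",
    "betweenness",
    "avg_short_path",
    "clust_coeff",
    "topo_coeff",
]


class EdgeListParseError(ValueError):
    """A malformed row in a two-column edge-list file."""


# ---------------------------------------------------------------------------
# Interactome construction
# ---------------------------------------------------------------------------

def build_interactome(
    edge_rows: Iterable[Sequence[str]],
    node_filter: set[str] | None = None,
) -> nx.Graph:
    """Build a simple undirected interactome from gene-symbol pairs.

    Self-pairs are dropped and duplicate pairs (in either order) are
    collapsed; counts of both are logged and stored in the graph metadata
    (``g.graph['n_self_dropped']``, ``g.graph['n_dup_dropped']``).

    Parameters
    ----------
    edge_rows
        Iterable of ``(gene_a, gene_b)`` pairs.
    node_filter
        If given, only edges with *both* endpoints in the filter are kept,
        and every filter gene appears as a node (isolated if it has no
        surviving interaction).
    """
    g = nx.Graph()
    n_self = n_dup = n_filtered = 0
    for i, row in enumerate(edge_rows):
        if len(row) != 2:
            raise EdgeListParseError(
                f"row {i + 1}: expected 2 columns, got {len(row)}"
            )
        a, b = row
        if not a or not b:
            raise EdgeListParseError(f"row {i + 1}: empty gene symbol")
        if a == b:
            n_self += 1
            continue
        if node_filter is not None and (a not in node_filter or b not in node_filter):
            n_filtered += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if node_filter is not None:
        g.add_nodes_from(node_filter)
    g.graph["n_self_dropped"] = n_self
    g.graph["n_dup_dropped"] = n_dup
    g.graph["n_filter_dropped"] = n_filtered
    if n_self or n_dup or n_filtered:
        logger.info(
            "build_interactome: dropped %d self-pairs, %d duplicates, "
            "%d rows outside node filter",
            n_self, n_dup, n_filtered,
        )
    return g


def read_edge_list(path) -> nx.Graph:
    """Read a 2-column TSV edge list ('#' comment lines ignored)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            rows.append(parts)
    return build_interactome(rows)


def write_edge_list(g: nx.Graph, path) -> None:
    """Write the interactome as a sorted, deterministic 2-column TSV."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


@dataclass(frozen=True)
class ComponentReport:
    """Connected-component census of an interactome."""

    n_components: int
    n_isolated: int
    giant_size: int


def giant_component(g: nx.Graph) -> tuple[nx.Graph, ComponentReport]:
    """Return the largest connected component as a new graph.

    Ties on size are broken by the lexicographically smallest member gene.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty interactome has no giant component")
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda c: (-len(c), min(c)))
    giant = comps[0]
    report = ComponentReport(
        n_components=len(comps),
        n_isolated=sum(1 for c in comps if len(c) == 1),
        giant_size=len(giant),
    )
    return g.subgraph(giant).copy(), report


# ---------------------------------------------------------------------------
# Degree and local metrics
# ---------------------------------------------------------------------------

def degree_metrics(g: nx.Graph) -> tuple[dict[str, int], dict[int, float]]:
    """Per-gene degree and the degree distribution P(k) = n_k / n."""
    k = {v: g.degree(v) for v in g.nodes()}
    n = len(k)
    dist: dict[int, float] = {}
    for kv in k.values():
        dist[kv] = dist.get(kv, 0) + 1
    return k, {kv: c / n for kv, c in sorted(dist.items())}


def neighborhood_connectivity(g: nx.Graph, v: str) -> float:
    """Mean degree of v's neighbors; NaN for an isolated node."""
    if v not in g:
        raise KeyError(f"unknown gene: {v!r}")
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return math.nan
    return sum(g.degree(u) for u in nbrs) / len(nbrs)


def clustering_coefficient(g: nx.Graph, v: str) -> float:
    """C_v = 2 e_v / (k_v (k_v - 1)); NaN when the node has degree < 2."""
    if v not in g:
        raise KeyError(f"unknown gene: {v!r}")
    nbrs = list(g.neighbors(v))
    kv = len(nbrs)
    if kv < 2:
        return math.nan
    e = 0
    nbr_set = set(nbrs)
    for u in nbrs:
        e += sum(1 for w in g.neighbors(u) if w in nbr_set)
    e //= 2
    return 2.0 * e / (kv * (kv - 1))


def topological_coefficient(g: nx.Graph, v: str) -> float:
    """Mean shared-neighbor count with other nodes, normalized by degree.

    For every node j != v sharing at least one neighbor with v,
    ``J(v, j) = |shared neighbors| (+1 if the v-j edge exists)``;
    ``T(v) = mean(J) / k_v``. Zero when k_v <= 1 or no node qualifies.
    """
    if v not in g:
        raise KeyError(f"unknown gene: {v!r}")
    nbrs = set(g.neighbors(v))
    kv = len(nbrs)
    if kv <= 1:
        return 0.0
    shared: dict[str, int] = {}
    for u in nbrs:
        for j in g.neighbors(u):
            if j != v:
                shared[j] = shared.get(j, 0) + 1
    if not shared:
        return 0.0
    total = sum(c + (1 if j in nbrs else 0) for j, c in shared.items())
    return total / len(shared) / kv


# ---------------------------------------------------------------------------
# Shortest-path metrics (Brandes-style single-source accumulation)
# ---------------------------------------------------------------------------

def shortest_path_metrics(
    g: nx.Graph,
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Stress, normalized betweenness and average shortest path length.

    One breadth-first pass per source accumulates geodesic counts
    (sigma), and a reverse sweep over the BFS order accumulates both the
    pair-ratio dependencies (betweenness) and the raw geodesic-count
    dependencies (stress). Ordered-pair sums are halved to count each
    unordered pair once. Betweenness is normalized per connected component
    by (N-1)(N-2)/2; components of size < 3 have betweenness 0.
    """
    nodes = sorted(g.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in g.edges():
        adj[idx[a]].append(idx[b])
        adj[idx[b]].append(idx[a])
    for lst in adj:
        lst.sort()

    bet = [0.0] * n
    stress = [0.0] * n
    dist_total = [0.0] * n
    n_reached = [0] * n

    for s in range(n):
        dist = [-1] * n
        sigma = [0.0] * n
        dist[s] = 0
        sigma[s] = 1.0
        order: list[int] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            dv = dist[v]
            sv = sigma[v]
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dv + 1
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sv
        delta_b = [0.0] * n
        delta_s = [0.0] * n
        for w in reversed(order):
            dw = dist[w]
            coef_b = (1.0 + delta_b[w]) / sigma[w]
            coef_s = 1.0 + delta_s[w] / sigma[w]
            for v in adj[w]:
                if dist[v] == dw - 1:
                    delta_b[v] += sigma[v] * coef_b
                    delta_s[v] += sigma[v] * coef_s
            if w != s:
                bet[w] += delta_b[w]
                stress[w] += delta_s[w]
                dist_total[s] += dw
                n_reached[s] += 1

    # Per-component normalization for betweenness.
    comp_size = [0] * n
    for comp in nx.connected_components(g):
        for v in comp:
            comp_size[idx[v]] = len(comp)

    stress_d: dict[str, float] = {}
    bet_d: dict[str, float] = {}
    aspl_d: dict[str, float] = {}
    for v, i in idx.items():
        stress_d[v] = stress[i] / 2.0
        nc = comp_size[i]
        norm = (nc - 1) * (nc - 2) / 2.0
        bet_d[v] = (bet[i] / 2.0) / norm if norm > 0 else 0.0
        aspl_d[v] = dist_total[i] / n_reached[i] if n_reached[i] else math.nan
    return stress_d, bet_d, aspl_d


# ---------------------------------------------------------------------------
# Metrics table
# ---------------------------------------------------------------------------

def compute_metrics(g: nx.Graph) -> pd.DataFrame:
    """All seven node metrics as a DataFrame indexed by gene symbol.

    Undefined values are NaN. Rows are in lexicographic gene order.
    """
    nodes = sorted(g.nodes())
    k, _ = degree_metrics(g)
    stress, bet, aspl = shortest_path_metrics(g)
    rows = {
        "degree": [k[v] for v in nodes],
        "neigh_conn": [neighborhood_connectivity(g, v) for v in nodes],
        "stress": [stress[v] for v in nodes],
        "betweenness": [bet[v] for v in nodes],
        "avg_short_path": [aspl[v] for v in nodes],
        "clust_coeff": [clustering_coefficient(g, v) for v in nodes],
        "topo_coeff": [topological_coefficient(g, v) for v in nodes],
    }
    df = pd.DataFrame(rows, index=pd.Index(nodes, name="gene"))
    return df[METRIC_COLUMNS]


def write_metrics(metrics: pd.DataFrame, path) -> None:
    """Write the metrics table as TSV; undefined values become ``NA``."""
    metrics.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_metrics(path) -> pd.DataFrame:
    """Read a metrics TSV written by :func:`write_metrics`."""
    return pd.read_csv(path, sep="\t", index_col="gene", na_values=["NA"])


# ---------------------------------------------------------------------------
# Power-law fitting (maximum likelihood + Kolmogorov-Smirnov cutoff)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLawFit:
    """MLE power-law fit with KS-selected lower cutoff.

    ``alpha`` is reported with the negative sign convention used for
    degree-distribution plots: an exponent of magnitude 2.85 is stored as
    -2.85. ``n_tail`` is the number of observations >= xmin.
    """

    alpha: float
    xmin: float
    ks_statistic: float
    n_tail: int

    @property
    def alpha_magnitude(self) -> float:
        return abs(self.alpha)

    @property
    def alpha_stderr(self) -> float:
        """Asymptotic MLE standard error (|alpha| - 1) / sqrt(n_tail)."""
        return (abs(self.alpha) - 1.0) / math.sqrt(self.n_tail)


class PowerLawFitError(ValueError):
    """Raised when the tail is too small for a meaningful fit."""


def _discrete_alpha_mle(x: np.ndarray, xmin: int) -> float:
    """Discrete MLE: maximize -n ln zeta(a, xmin) - a sum ln x."""
    from scipy.optimize import minimize_scalar

    slog = np.log(x).sum()
    n = len(x)

    # zeta(a, q) is the Hurwitz zeta function
    def negloglik(a: float) -> float:
        return n * math.log(zeta(a, xmin)) + a * slog

    res = minimize_scalar(negloglik, bounds=(1.01, 8.0), method="bounded")
    return float(res.x)


def _ks_discrete(x: np.ndarray, alpha: float, xmin: int) -> float:
    """KS distance between the tail ECDF and the discrete model CDF."""
    kmax = int(x.max())
    ks = np.arange(xmin, kmax + 1)
    pmf = ks.astype(float) ** (-alpha) / zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    ecdf = np.searchsorted(np.sort(x), ks, side="right") / len(x)
    return float(np.max(np.abs(ecdf - cdf)))


def _ks_continuous(x: np.ndarray, alpha: float, xmin: float) -> float:
    xs = np.sort(x)
    cdf = 1.0 - (xs / xmin) ** (1.0 - alpha)
    ecdf_hi = np.arange(1, len(xs) + 1) / len(xs)
    ecdf_lo = np.arange(0, len(xs)) / len(xs)
    return float(max(np.max(np.abs(ecdf_hi - cdf)), np.max(np.abs(ecdf_lo - cdf))))


def fit_power_law(
    values: Sequence[float],
    discrete: bool = False,
    min_values: int = 50,
    xmin: float | None = None,
) -> PowerLawFit:
    """Fit a power-law tail by MLE, choosing xmin to minimize KS distance.

    Candidate xmin values are all distinct observed values; ties in KS
    are broken toward the smaller xmin. For discrete (integer) data the
    exponent maximizes the zeta-function likelihood; for continuous data
    the closed form ``alpha = 1 + n / sum(ln(x_i / xmin))`` is used.
    Passing ``xmin`` fixes the cutoff instead of scanning.

    Returns a :class:`PowerLawFit`; ``alpha`` carries a negative sign
    (plot convention).
    """
    x = np.asarray([v for v in values if v > 0], dtype=float)
    if len(x) < min_values:
        raise PowerLawFitError(
            f"need >= {min_values} positive values for a meaningful fit, got {len(x)}"
        )
    if xmin is not None:
        tail = x[x >= xmin]
        if len(tail) < 2:
            raise PowerLawFitError("fewer than 2 tail values at fixed xmin")
        if discrete:
            xm = int(round(xmin))
            alpha = _discrete_alpha_mle(tail, xm)
            ks = _ks_discrete(tail, alpha, xm)
        else:
            alpha = 1.0 + len(tail) / np.log(tail / xmin).sum()
            ks = _ks_continuous(tail, alpha, xmin)
        return PowerLawFit(alpha=-alpha, xmin=float(xmin),
                           ks_statistic=ks, n_tail=len(tail))
    candidates = np.unique(x)[:-1]  # xmin = max leaves an empty tail
    best: tuple[float, float, float, int] | None = None  # ks, alpha, xmin, ntail
    for xmin in candidates:
        tail = x[x >= xmin]
        if len(np.unique(tail)) < 2:
            continue
        if discrete:
            xm = int(round(xmin))
            alpha = _discrete_alpha_mle(tail, xm)
            ks = _ks_discrete(tail, alpha, xm)
        else:
            alpha = 1.0 + len(tail) / np.log(tail / xmin).sum()
            ks = _ks_continuous(tail, alpha, xmin)
        if best is None or ks < best[0] - 1e-15:
            best = (ks, alpha, float(xmin), len(tail))
    if best is None:
        raise PowerLawFitError("fewer than 2 distinct tail values at every cutoff")
    ks, alpha, xmin, n_tail = best
    return PowerLawFit(alpha=-alpha, xmin=xmin, ks_statistic=ks, n_tail=n_tail)


def sample_power_law(
    n: int,
    alpha: float,
    xmin: float,
    rng: np.random.Generator,
    discrete: bool = False,
) -> np.ndarray:
    """Draw n samples from a (discrete or continuous) power law.

    Continuous sampling inverts the CDF; discrete sampling inverts the
    exact zeta-normalized CDF tabulated to negligible tail mass.
    """
    u = rng.random(n)
    a = abs(alpha)
    if not discrete:
        return xmin * (1.0 - u) ** (-1.0 / (a - 1.0))
    xm = int(round(xmin))
    kmax = xm
    z = zeta(a, xm)
    # extend support until the un-tabulated mass is negligible
    while zeta(a, kmax + 1) / z > 1e-10:
        kmax = max(kmax + 1, int(kmax * 2))
    ks = np.arange(xm, kmax + 1)
    cdf = np.cumsum(ks.astype(float) ** (-a) / z)
    cdf[-1] = 1.0
    return ks[np.searchsorted(cdf, u, side="right").clip(0, len(ks) - 1)].astype(float)
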