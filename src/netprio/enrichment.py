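"""Hypergeometric GO overrepresentation against a configurable universe.

The test follows the two-unranked-lists design: a target gene set is
tested against a background universe (here the cancer-gene interactome's
gene set). For each term, with N = universe size, B = universe genes
annotated with the term (after true-path propagation), n = target-set
size and b = annotated target genes, the p-value is the upper tail
P(X >= b) of Hypergeometric(N, B, n). A term passes the filters when
p <= p_cutoff (default 0.001) and B <= B_max (default 100); no
multiple-testing correction is applied to the filter (a
Benjamini-Hochberg column is emitted for information only). Enrichment
is computed per namespace (biological_process / molecular_function /
cellular_component).

N deliberately counts *all* universe genes, including those without any
annotation, keeping the background independent of annotation coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

RELATIONS = ("is_a", "part_of")


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

@dataclass
class Ontology:
    """A DAG of terms linked child -> parent by is_a / part_of."""

    names: dict[str, str]
    namespaces: dict[str, str]
    parents: dict[str, set[str]]

    def __post_init__(self):
        for t, ps in self.parents.items():
            missing = ps - self.names.keys()
            if missing:
                raise ValueError(f"term {t}: unresolved parents {sorted(missing)}")
        dg = nx.DiGraph(
            (t, p) for t, ps in self.parents.items() for p in ps
        )
        if not nx.is_directed_acyclic_graph(dg):
            raise ValueError("ontology parent links contain a cycle")

    def __contains__(self, term: str) -> bool:
        return term in self.names

    def __len__(self) -> int:
        return len(self.names)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` via is_a/part_of (excl. itself)."""
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        return out


def read_obo(path) -> Ontology:
    """Read an OBO 1.2 file (is_a and part_of links; obsolete terms skipped)."""
    import obonet

    g = obonet.read_obo(path)
    names = {t: d.get("name", t) for t, d in g.nodes(data=True)}
    namespaces = {t: d.get("namespace", "biological_process")
                  for t, d in g.nodes(data=True)}
    parents: dict[str, set[str]] = {t: set() for t in names}
    for u, v, key in g.edges(keys=True):
        if key in RELATIONS:
            parents[u].add(v)
    return Ontology(names=names, namespaces=namespaces, parents=parents)


def write_obo(onto: Ontology, path) -> None:
    """Write the ontology as a minimal OBO 1.2 document (deterministic)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(onto.names):
            fh.write(f"\n[Term]\nid: {term}\nname: {onto.names[term]}\n")
            fh.write(f"namespace: {onto.namespaces[term]}\n")
            for p in sorted(onto.parents.get(term, ())):
                fh.write(f"is_a: {p} ! {onto.names[p]}\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """gene -> set of term IDs, optionally true-path propagated."""

    gene_terms: dict[str, set[str]]
    propagated: bool = False
    #: rows rejected at load/propagation time (unknown terms)
    errors: list[str] = field(default_factory=list)

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}

    def terms_in_use(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out


def propagate_annotations(onto: Ontology, direct: AnnotationMap) -> AnnotationMap:
    """True-path closure: annotate every gene to all ancestors of its terms.

    Annotations to unknown terms are skipped and reported in the result's
    ``errors`` list. Idempotent.
    """
    anc_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    errors: list[str] = []
    for gene in sorted(direct.gene_terms):
        closed: set[str] = set()
        for t in sorted(direct.gene_terms[gene]):
            if t not in onto:
                errors.append(f"{gene}\t{t}\tunknown term")
                continue
            if t not in anc_cache:
                anc_cache[t] = onto.ancestors(t)
            closed.add(t)
            closed |= anc_cache[t]
        out[gene] = closed
    if errors:
        logger.warning("propagate_annotations: %d annotations to unknown terms "
                       "skipped", len(errors))
    return AnnotationMap(gene_terms=out, propagated=True, errors=errors)


def read_annotations(path) -> AnnotationMap:
    """Read gene->term annotations from 2-column TSV or GAF 2.x.

    GAF rows (detected by the ``!gaf-version`` header or >=15 columns) use
    columns 3 (symbol) and 5 (term); rows with a NOT qualifier are skipped.
    """
    gene_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            parts = line.split("\t")
            if len(parts) >= 15:  # GAF 2.x
                if "NOT" in parts[3].split("|"):
                    continue
                gene, term = parts[2], parts[4]
            elif len(parts) == 2:
                gene, term = parts
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 (TSV) or >=15 (GAF) "
                    f"columns, got {len(parts)}"
                )
            gene_terms.setdefault(gene, set()).add(term)
    return AnnotationMap(gene_terms=gene_terms, propagated=False)


def write_annotations(annot: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annot.gene_terms):
            for term in sorted(annot.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Hypergeometric test
# ---------------------------------------------------------------------------

def hypergeometric_upper_tail(N: int, B: int, n: int, b: int) -> float:
    """P(X >= b) for X ~ Hypergeometric(N, B, n).

    Evaluated through the survival function of
    :class:`scipy.stats.hypergeom`, which works in log-space factorials
    and is numerically stable far into the tail.
    """
    if not (0 <= b <= min(B, n) and 0 <= B <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N} B={B} n={n} b={b}")
    if b == 0:
        return 1.0
    return float(hypergeom.sf(b - 1, N, B, n))


# ---------------------------------------------------------------------------
# Two-list enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term overrepresentation counts and upper-tail p-value."""

    term_id: str
    name: str
    namespace: str
    N: int
    B: int
    n: int
    b: int
    p_value: float
    passes_filters: bool
    p_bh: float = float("nan")  # informational only; filters use raw p


def enrich_two_lists(
    target: set[str],
    universe: set[str],
    annot: AnnotationMap,
    onto: Ontology | None = None,
    p_cutoff: float = 0.001,
    B_max: int = 100,
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of ``target`` within ``universe``.

    ``annot`` must be propagated. Target genes outside the universe are
    dropped with a warning. One result is produced for every term
    annotating at least one universe gene; results are sorted by
    ascending p-value (term ID as tie-break). ``passes_filters`` is
    ``p <= p_cutoff and B <= B_max``; the raw p-value is used, matching
    the two-unranked-lists overrepresentation design. A BH-adjusted
    p-value is attached for information only.
    """
    if not annot.propagated:
        raise ValueError("enrich_two_lists requires a propagated AnnotationMap")
    if not universe:
        raise ValueError("empty universe")
    dropped = target - universe
    if dropped:
        logger.warning("enrich_two_lists: %d target genes outside universe dropped",
                       len(dropped))
    target = target & universe
    if not target:
        raise ValueError("target set empty after intersection with universe")

    N = len(universe)
    n = len(target)
    term_universe_genes: dict[str, int] = {}
    term_target_genes: dict[str, int] = {}
    for gene, terms in annot.gene_terms.items():
        if gene not in universe:
            continue
        in_target = gene in target
        for t in terms:
            term_universe_genes[t] = term_universe_genes.get(t, 0) + 1
            if in_target:
                term_target_genes[t] = term_target_genes.get(t, 0) + 1

    results = []
    for term in sorted(term_universe_genes):
        B = term_universe_genes[term]
        b = term_target_genes.get(term, 0)
        p = hypergeometric_upper_tail(N, B, n, b)
        name = onto.names.get(term, term) if onto is not None else term
        ns = onto.namespaces.get(term, "biological_process") if onto is not None \
            else "biological_process"
        results.append(EnrichmentResult(
            term_id=term, name=name, namespace=ns,
            N=N, B=B, n=n, b=b, p_value=p,
            passes_filters=(p <= p_cutoff and B <= B_max),
        ))
    results.sort(key=lambda r: (r.p_value, r.term_id))

    # Benjamini-Hochberg within each namespace (the test itself is run per
    # namespace; the column is informational, filters use the raw p-value).
    out: list[EnrichmentResult] = []
    for ns in {r.namespace for r in results}:
        group = [r for r in results if r.namespace == ns]
        m = len(group)
        adj = []
        running = 1.0
        for i in range(m - 1, -1, -1):
            running = min(running, group[i].p_value * m / (i + 1))
            adj.append(running)
        adj.reverse()
        out.extend(
            EnrichmentResult(**{**r.__dict__, "p_bh": a})
            for r, a in zip(group, adj)
        )
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out


def enriched_gene_set(
    results: list[EnrichmentResult],
    annot: AnnotationMap,
    universe: set[str],
) -> set[str]:
    """Universe genes annotated with at least one filter-passing term."""
    passing = {r.term_id for r in results if r.passes_filters}
    if not passing:
        return set()
    return {
        g for g in universe
        if annot.gene_terms.get(g, set()) & passing
    }


def write_enrichment_results(results: list[EnrichmentResult], path) -> None:
    """TSV: term_id name namespace N B n b p_value p_bh passes_filters."""
    with open(path, "w") as fh:
        fh.write("term_id\tname\tnamespace\tN\tB\tn\tb\tp_value\tp_bh\t"
                 "passes_filters\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.name}\t{r.namespace}\t{r.N}\t{r.B}\t{r.n}\t"
                f"{r.b}\t{r.p_value:.6g}\t{r.p_bh:.6g}\t"
                f"{str(r.passes_filters).lower()}\n"
            )
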