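"""Seed-reproducible synthetic input bundles with planted ground truth.

The generator emulates the statistical structure the analysis assumes,
so the whole pipeline can run — and be validated against known truth —
without any external downloads:

* a scale-free interactome grown by preferential attachment (degree
  exponent near 2.85 at the default size);
* a random is_a DAG per GO namespace with baseline leaf-term annotation;
* a curated disease-gene analog whose members draw "bone-like" and
  "metastasis-like" planted terms at an elevated rate, so those terms
  are genuinely overrepresented against the gene universe;
* a generic-mechanism gene list biased toward high-degree nodes (hubs
  overlap it far above chance);
* mouse-phenotype lethality labels whose probability increases with
  degree rank (hub essentiality far above the ~49% background);
* planted target genes — non-generic, sub-hub genes annotated with at
  least one bone-like and one metastasis-like term — which the full
  pipeline should recover.

To keep the planted targets identifiable, every other gene is assigned a
single allowed planted-term category (bone or metastasis), so dual
bone+metastasis annotation arises only by construction. Real annotation
data has no such exclusivity; see the methods note for what this does
and does not validate.

All randomness flows from a single mandatory seed through named
:class:`numpy.random.SeedSequence` spawns, and every iteration order is
sorted, so bundles are bit-reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import graph as graph_mod
from . import hubs as hubs_mod
from .enrichment import AnnotationMap, Ontology, write_annotations, write_obo
from .targets import TermCategories, write_term_categories

_NS_PREFIX = {"biological_process": 1, "molecular_function": 2,
              "cellular_component": 3}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic input bundle.

    Defaults are scaled from the magnitudes of the real study: a
    2000-gene universe (vs 2665), 300 curated disease genes (vs 391),
    250 generic-mechanism genes (vs 328), degree exponent target 2.85,
    49.34% essential prevalence, and 10 bone-like / 21 metastasis-like
    planted terms (vs the 10 + 21 relevant-term split).
    """

    seed: int
    n_genes: int = 2000
    attachment_m: int = 4  # edges per new node; mean degree ~ 2m
    degree_exponent: float = 2.85  # target for the fitted exponent
    frac_essential: float = 0.4934
    essentiality_strength: float = 4.5  # logistic slope on degree-rank quantile
    n_terms_per_namespace: int = 40
    ontology_depth: int = 4
    n_curated: int | None = None  # default: 15% of the universe
    n_generic: int | None = None  # default: 12.5% of the universe
    generic_degree_bias: float = 2.0  # sampling weight (degree+1)**bias
    base_annotation_low: float = 0.004  # per-leaf baseline annotation rates
    base_annotation_high: float = 0.04
    planted_base_rate: float = 0.02  # planted-term rate for non-curated genes
    planted_effect_size: float = 8.0  # curated-gene rate multiplier
    n_planted_bone: int = 10
    n_planted_metastasis: int = 21
    n_planted_dual_targets: int | None = None  # default: universe / 80
    hub_exclusion_rank: int | None = None  # targets drawn below this degree rank

    def __post_init__(self):
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        # size defaults scale with the universe (300 / 250 / 25 / 300 at the
        # default 2000-gene universe)
        if self.n_curated is None:
            object.__setattr__(self, "n_curated", round(0.15 * self.n_genes))
        if self.n_generic is None:
            object.__setattr__(self, "n_generic", round(0.125 * self.n_genes))
        if self.n_planted_dual_targets is None:
            object.__setattr__(self, "n_planted_dual_targets",
                               max(4, self.n_genes // 80))
        if self.hub_exclusion_rank is None:
            object.__setattr__(self, "hub_exclusion_rank",
                               max(75, round(0.15 * self.n_genes)))
        if self.attachment_m < 1 or self.attachment_m >= self.n_genes:
            raise ValueError("attachment_m must be in [1, n_genes)")
        for name in ("frac_essential", "base_annotation_low",
                     "base_annotation_high", "planted_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_curated + self.n_generic > self.n_genes:
            raise ValueError("curated + generic lists exceed the gene universe")
        if self.n_planted_dual_targets < 1:
            raise ValueError("need at least one planted target")
        if self.planted_base_rate * self.planted_effect_size > 1.0:
            raise ValueError("planted rate * effect size exceeds 1")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    planted_bone_terms: frozenset[str]
    planted_metastasis_terms: frozenset[str]
    planted_target_genes: frozenset[str]
    planted_generic_genes: frozenset[str]  # the degree-biased generic list


@dataclass
class SyntheticBundle:
    """A complete, internally consistent set of pipeline inputs."""

    config: SyntheticConfig
    graph: nx.Graph
    ontology: Ontology
    annotations: AnnotationMap  # direct (unpropagated)
    phenotypes: dict[str, set[str]]
    curated: set[str]
    generic: set[str]
    categories: TermCategories
    ground_truth: GroundTruth


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

def generate_interactome(cfg: SyntheticConfig,
                         rng: np.random.Generator | None = None) -> nx.Graph:
    """Grow a simple scale-free interactome by preferential attachment.

    Each new gene attaches to ``attachment_m`` distinct existing genes
    chosen with probability proportional to their current degree,
    starting from a small complete seed graph. Gene symbols are synthetic
    (``G000001`` ...).
    """
    if rng is None:
        rng = _rngs(cfg.seed, 6)[0]
    m = cfg.attachment_m
    g = nx.Graph()
    names = [f"G{i + 1:06d}" for i in range(cfg.n_genes)]
    # complete seed graph on the first m+1 genes
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            g.add_edge(names[i], names[j])
    # endpoint multiset for degree-proportional choice
    endpoints: list[int] = []
    for i in range(m + 1):
        endpoints.extend([i] * m)
    for i in range(m + 1, cfg.n_genes):
        chosen: set[int] = set()
        while len(chosen) < m:
            chosen.add(endpoints[rng.integers(len(endpoints))])
        for j in sorted(chosen):
            g.add_edge(names[i], names[j])
            endpoints.append(j)
        endpoints.extend([i] * m)
    g.graph["n_self_dropped"] = 0
    g.graph["n_dup_dropped"] = 0
    return g


# ---------------------------------------------------------------------------
# Gene-set selection
# ---------------------------------------------------------------------------

def _degree_rank(g: nx.Graph) -> list[str]:
    """Genes by descending degree, lexicographic tie-break."""
    return [v for v, _ in sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))]


def select_gene_sets(
    cfg: SyntheticConfig, g: nx.Graph, rng: np.random.Generator,
) -> tuple[set[str], set[str], set[str]]:
    """Choose the generic list, planted targets and curated list.

    Generic genes are sampled without replacement with weight
    ``(degree+1)**generic_degree_bias`` (hub-biased). Planted targets are
    uniform draws from non-generic genes below the hub-exclusion degree
    rank. The curated list is a uniform draw that always contains half of
    the planted targets (the rest stay outside, so targets arise from
    both the curated-overlap and enrichment-only Venn regions).
    """
    ranked = _degree_rank(g)
    genes = sorted(g.nodes())
    deg = dict(g.degree())
    w = np.array([(deg[v] + 1.0) ** cfg.generic_degree_bias for v in genes])
    idx = rng.choice(len(genes), size=cfg.n_generic, replace=False, p=w / w.sum())
    generic = {genes[i] for i in idx}

    sub_hub = [v for v in ranked[cfg.hub_exclusion_rank:] if v not in generic]
    pick = rng.choice(len(sub_hub), size=cfg.n_planted_dual_targets, replace=False)
    targets = {sub_hub[i] for i in sorted(pick)}

    targets_sorted = sorted(targets)
    half = len(targets_sorted) // 2
    in_curated = set(targets_sorted[:half])
    pool = [v for v in genes if v not in targets]
    pick = rng.choice(len(pool), size=cfg.n_curated - len(in_curated),
                      replace=False)
    curated = in_curated | {pool[i] for i in sorted(pick)}
    return curated, generic, targets


# ---------------------------------------------------------------------------
# Ontology + annotations
# ---------------------------------------------------------------------------

def generate_ontology_annotations(
    cfg: SyntheticConfig,
    g: nx.Graph,
    curated: set[str],
    planted_targets: set[str],
    rng: np.random.Generator,
) -> tuple[Ontology, AnnotationMap, TermCategories, frozenset[str]]:
    """Build the term DAG, baseline annotations and planted enrichment.

    Each namespace is a random DAG: a root, then levels whose terms each
    take 1-2 parents from the level above. Baseline annotation draws each
    gene x leaf-term pair at a term-specific rate (two deliberately
    common terms per namespace exceed the B-filter threshold). Planted
    bone-like and metastasis-like leaf terms are drawn by curated genes
    at ``planted_base_rate * planted_effect_size`` and by others at the
    base rate — but each non-target gene may only draw from its single
    allowed category, so dual annotation marks exactly the planted
    targets, which are forced to carry both.
    """
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    leaves: dict[str, list[str]] = {}

    for ns, prefix in _NS_PREFIX.items():
        counter = 0

        def new_term() -> str:
            nonlocal counter
            counter += 1
            return f"GO:{prefix}{counter:06d}"

        levels: list[list[str]] = [[new_term()]]
        remaining = cfg.n_terms_per_namespace - 1
        width = 2
        while remaining > 0:
            size = min(width, remaining)
            levels.append([new_term() for _ in range(size)])
            remaining -= size
            width *= 2
            if len(levels) >= cfg.ontology_depth and remaining > 0:
                levels.append([new_term() for _ in range(remaining)])
                remaining = 0
        has_child: set[str] = set()
        for term in levels[0]:
            names[term] = f"{ns} root"
            namespaces[term] = ns
            parents[term] = set()
        for li in range(1, len(levels)):
            for term in levels[li]:
                names[term] = f"synthetic {ns} term {term[3:]}"
                namespaces[term] = ns
                k = int(rng.integers(1, 3))
                above = levels[li - 1]
                pick = rng.choice(len(above), size=min(k, len(above)),
                                  replace=False)
                parents[term] = {above[i] for i in pick}
                has_child.update(parents[term])
        leaves[ns] = sorted(t for lvl in levels for t in lvl
                            if t not in has_child)

    # baseline internal terms per namespace, fixed before planting so a
    # planted term can never become an ancestor of another planted term
    internal = {ns: sorted(t for t in names
                           if namespaces[t] == ns and t not in leaves[ns])
                for ns in _NS_PREFIX}

    # planted leaf terms: bone-like under BP; metastasis-like split BP/MF
    def plant(prefix: int, count: int, ns: str, label: str) -> list[str]:
        out = []
        ns_nonleaf = internal[ns]
        for i in range(count):
            term = f"GO:{prefix}{i + 1:06d}"
            names[term] = f"synthetic {label} term {i + 1}"
            namespaces[term] = ns
            pick = rng.integers(len(ns_nonleaf))
            parents[term] = {ns_nonleaf[pick]}
            out.append(term)
        return out

    bone_terms = plant(4, cfg.n_planted_bone, "biological_process", "bone-like")
    n_met_bp = (cfg.n_planted_metastasis + 1) // 2
    met_terms = plant(5, n_met_bp, "biological_process", "metastasis-like")
    met_terms += plant(6, cfg.n_planted_metastasis - n_met_bp,
                       "molecular_function", "metastasis-like")

    onto = Ontology(names=names, namespaces=namespaces, parents=parents)
    cats = TermCategories(bone_terms=frozenset(bone_terms),
                          metastasis_terms=frozenset(met_terms))

    genes = sorted(g.nodes())
    gene_terms: dict[str, set[str]] = {v: set() for v in genes}

    # baseline annotation over non-planted leaves, term-specific rates
    for ns in sorted(leaves):
        for j, term in enumerate(leaves[ns]):
            if j < 2:  # two common terms per namespace (exceed B_max)
                rate = 0.08
            else:
                rate = rng.uniform(cfg.base_annotation_low,
                                   cfg.base_annotation_high)
            hits = rng.random(len(genes)) < rate
            for v, h in zip(genes, hits):
                if h:
                    gene_terms[v].add(term)

    # planted-category annotation with per-gene category exclusivity
    allowed_bone = rng.random(len(genes)) < 0.5
    hi = cfg.planted_base_rate * cfg.planted_effect_size
    for cat_terms, is_bone in ((bone_terms, True), (met_terms, False)):
        for term in cat_terms:
            draws = rng.random(len(genes))
            for v, ok_bone, u in zip(genes, allowed_bone, draws):
                if v in planted_targets:
                    continue  # handled below
                if ok_bone != is_bone:
                    continue
                rate = hi if v in curated else cfg.planted_base_rate
                if u < rate:
                    gene_terms[v].add(term)

    # planted dual targets: force >=1 term from each category
    for v in sorted(planted_targets):
        nb = int(rng.integers(1, 3))
        nm = int(rng.integers(1, 3))
        pick_b = rng.choice(len(bone_terms), size=nb, replace=False)
        pick_m = rng.choice(len(met_terms), size=nm, replace=False)
        gene_terms[v].update(bone_terms[i] for i in pick_b)
        gene_terms[v].update(met_terms[i] for i in pick_m)

    annot = AnnotationMap(gene_terms=gene_terms, propagated=False)
    return onto, annot, cats, frozenset(bone_terms) | frozenset(met_terms)


# ---------------------------------------------------------------------------
# Essentiality / phenotype table
# ---------------------------------------------------------------------------

#: Synthetic non-lethal phenotype terms for padding the table.
_NONLETHAL_TERMS = tuple(f"MP:{3000000 + i:07d}" for i in range(1, 13))


def generate_phenotypes(
    cfg: SyntheticConfig, g: nx.Graph, rng: np.random.Generator,
) -> dict[str, set[str]]:
    """Assign lethality phenotypes with probability increasing in centrality.

    The essentiality probability of the gene at degree-rank quantile
    ``q`` (1 = most connected) is ``sigmoid(b0 + strength * q)``, with
    ``b0`` solved so the expected overall essential fraction equals the
    configured value. Essential genes receive one lethality MP term (plus
    possible non-lethal terms); ~10% of non-essential genes are absent
    from the table entirely, as in real phenotype data.
    """
    ranked = _degree_rank(g)
    n = len(ranked)
    q = 1.0 - np.arange(n) / max(n - 1, 1)
    s = cfg.essentiality_strength

    if s == 0.0:
        p = np.full(n, cfg.frac_essential)
    else:
        f = lambda b0: expit(b0 + s * q).mean() - cfg.frac_essential
        b0 = brentq(f, -50.0, 50.0)
        p = expit(b0 + s * q)

    essential = rng.random(n) < p
    lethal = hubs_mod.DEFAULT_LETHAL_TERMS
    out: dict[str, set[str]] = {}
    for v, is_ess in zip(ranked, essential):
        terms: set[str] = set()
        if is_ess:
            terms.add(lethal[rng.integers(len(lethal))])
            if rng.random() < 0.5:
                terms.add(_NONLETHAL_TERMS[rng.integers(len(_NONLETHAL_TERMS))])
        else:
            if rng.random() < 0.9:
                for _ in range(int(rng.integers(1, 4))):
                    terms.add(_NONLETHAL_TERMS[rng.integers(len(_NONLETHAL_TERMS))])
        if terms:
            out[v] = terms
    return out


# ---------------------------------------------------------------------------
# Bundle assembly and serialization
# ---------------------------------------------------------------------------

def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete input bundle, deterministically from the seed."""
    r_graph, r_sets, r_onto, r_phen, _, _ = _rngs(cfg.seed, 6)
    g = generate_interactome(cfg, r_graph)
    curated, generic, targets = select_gene_sets(cfg, g, r_sets)
    onto, annot, cats, planted = generate_ontology_annotations(
        cfg, g, curated, targets, r_onto)
    phenotypes = generate_phenotypes(cfg, g, r_phen)
    truth = GroundTruth(
        planted_bone_terms=cats.bone_terms,
        planted_metastasis_terms=cats.metastasis_terms,
        planted_target_genes=frozenset(targets),
        planted_generic_genes=frozenset(generic),
    )
    return SyntheticBundle(
        config=cfg, graph=g, ontology=onto, annotations=annot,
        phenotypes=phenotypes, curated=curated, generic=generic,
        categories=cats, ground_truth=truth,
    )


BUNDLE_FILES = {
    "edges": "edges.tsv",
    "ontology": "ontology.obo",
    "annotations": "annotations.tsv",
    "phenotypes": "phenotypes.tsv",
    "curated": "curated_genes.txt",
    "generic": "generic_genes.txt",
    "categories": "term_categories.tsv",
}


def write_bundle(bundle: SyntheticBundle, directory) -> dict:
    """Write every input file plus a JSON manifest; returns the manifest.

    Serialization is deterministic: two writes of the same bundle are
    byte-identical. The planted ground truth goes to ``ground_truth.json``
    alongside (it is not a pipeline input, so it is not in the file list).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    graph_mod.write_edge_list(bundle.graph, directory / BUNDLE_FILES["edges"])
    # isolated nodes (degree 0) would be lost from a pure edge list; the
    # generator never produces them, but guard the round-trip anyway
    assert all(d > 0 for _, d in bundle.graph.degree())
    write_obo(bundle.ontology, directory / BUNDLE_FILES["ontology"])
    write_annotations(bundle.annotations, directory / BUNDLE_FILES["annotations"])
    hubs_mod.write_phenotype_table(bundle.phenotypes,
                                   directory / BUNDLE_FILES["phenotypes"])
    hubs_mod.write_gene_list(bundle.curated, directory / BUNDLE_FILES["curated"])
    hubs_mod.write_gene_list(bundle.generic, directory / BUNDLE_FILES["generic"])
    write_term_categories(bundle.categories,
                          directory / BUNDLE_FILES["categories"])

    truth = {
        "planted_bone_terms": sorted(bundle.ground_truth.planted_bone_terms),
        "planted_metastasis_terms":
            sorted(bundle.ground_truth.planted_metastasis_terms),
        "planted_target_genes": sorted(bundle.ground_truth.planted_target_genes),
        "planted_generic_genes": sorted(bundle.ground_truth.planted_generic_genes),
    }
    (directory / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n")

    manifest = {
        "seed": bundle.config.seed,
        "config": asdict(bundle.config),
        "files": {
            key: {"path": fname,
                  "bytes": (directory / fname).stat().st_size}
            for key, fname in sorted(BUNDLE_FILES.items())
        },
        "ground_truth": "ground_truth.json",
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
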