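"""Set-logic refinement of disease-specific candidate targets.

Three gene sets — A: network hubs, B: literature-curated disease genes,
C: genes annotated with enrichment-derived characteristic terms — are
decomposed into the seven disjoint Venn regions (Set-a, Set-b, Set-c,
Set-ab, Set-bc, Set-ac, Set-abc). Hubs mark generic disease machinery,
and B alone cannot reveal novel genes, so the source pool of candidate
targets is Set-c (union) Set-bc. The pool is refined in three steps:

1. keep genes annotated (on propagated annotations) with at least one
   term from the relevant bone or metastasis category lists;
2. remove genes on the generic-mechanism reference list (exact symbol
   match);
3. classify survivors as bone / metastasis / both from which category
   lists their terms hit — the ``both`` class is the final predicted
   target set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .enrichment import AnnotationMap

logger = logging.getLogger(__name__)

#: Bone-process GO terms used by default for target refinement:
#: osteoblast differentiation, bone remodeling regulation, endochondral /
#: replacement ossification, bone mineralization, ossification, cartilage
#: development, vitamin D response, collagen metabolism / fibril
#: organization.
DEFAULT_BONE_TERMS = (
    "GO:0001649", "GO:0046850", "GO:0001958", "GO:0036075", "GO:0030282",
    "GO:0001503", "GO:0051216", "GO:0033280", "GO:0032963", "GO:0030199",
)

#: Metastasis-mechanism GO terms used by default: leukocyte migration and
#: chemotaxis regulation, cell-cell adhesion regulation, angiogenesis,
#: catenin nuclear import, and binding activities toward extracellular
#: matrix components (laminin, fibronectin, collagen, integrin,
#: glycosaminoglycan, carbohydrate), growth-factor receptors and
#: cytokines.
DEFAULT_METASTASIS_TERMS = (
    "GO:0050900", "GO:0016337", "GO:0001525", "GO:0045785", "GO:0007162",
    "GO:0002687", "GO:0002688", "GO:0002690", "GO:0035413",
    "GO:0043236", "GO:0001968", "GO:0005104", "GO:0048407", "GO:0050840",
    "GO:0005518", "GO:0005178", "GO:0005539", "GO:0005125", "GO:0030246",
)

REGIONS = ("Set-a", "Set-b", "Set-c", "Set-ab", "Set-bc", "Set-ac", "Set-abc")


@dataclass(frozen=True)
class TermCategories:
    """Disjoint bone-process and metastasis-mechanism term lists."""

    bone_terms: frozenset[str]
    metastasis_terms: frozenset[str]

    def __post_init__(self):
        if not self.bone_terms or not self.metastasis_terms:
            raise ValueError("both category lists must be nonempty")
        overlap = self.bone_terms & self.metastasis_terms
        if overlap:
            raise ValueError(f"category lists overlap: {sorted(overlap)}")

    @classmethod
    def default(cls) -> "TermCategories":
        return cls(
            bone_terms=frozenset(DEFAULT_BONE_TERMS),
            metastasis_terms=frozenset(DEFAULT_METASTASIS_TERMS),
        )


def read_term_categories(path) -> TermCategories:
    """Read a TSV of ``GO:XXXXXXX<TAB>bone|metastasis`` rows."""
    bone, met = set(), set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("bone", "metastasis"):
                raise ValueError(f"{path}: line {lineno}: expected "
                                 "'GO:XXXXXXX<TAB>bone|metastasis'")
            (bone if parts[1] == "bone" else met).add(parts[0])
    return TermCategories(bone_terms=frozenset(bone), metastasis_terms=frozenset(met))


def write_term_categories(cats: TermCategories, path) -> None:
    with open(path, "w") as fh:
        for t in sorted(cats.bone_terms):
            fh.write(f"{t}\tbone\n")
        for t in sorted(cats.metastasis_terms):
            fh.write(f"{t}\tmetastasis\n")


# ---------------------------------------------------------------------------
# Venn decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VennPartition:
    """The seven disjoint regions of a three-set Venn decomposition."""

    regions: dict[str, frozenset[str]]

    def __getitem__(self, region: str) -> frozenset[str]:
        return self.regions[region]

    def sizes(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in REGIONS}


def venn_partition(A: set[str], B: set[str], C: set[str]) -> VennPartition:
    """Exact set-algebra decomposition of A (hubs), B (curated), C (enriched)."""
    abc = A & B & C
    regions = {
        "Set-a": frozenset(A - B - C),
        "Set-b": frozenset(B - A - C),
        "Set-c": frozenset(C - A - B),
        "Set-ab": frozenset((A & B) - C),
        "Set-ac": frozenset((A & C) - B),
        "Set-bc": frozenset((B & C) - A),
        "Set-abc": frozenset(abc),
    }
    return VennPartition(regions=regions)


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetRecord:
    """One refined candidate with its source region and category evidence."""

    gene: str
    region: str  # Set-c or Set-bc
    category: str  # bone | metastasis | both
    bone_terms: frozenset[str]
    metastasis_terms: frozenset[str]


def refine_targets(
    partition: VennPartition,
    annot: AnnotationMap,
    cats: TermCategories,
    generic_genes: set[str],
) -> list[TargetRecord]:
    """Refine the Set-c + Set-bc pool into categorized candidate targets.

    Step 1 keeps pool genes annotated with >= 1 relevant term; step 2
    removes generic genes; step 3 assigns the bone / metastasis / both
    category. Step counts are logged. Records are sorted by gene symbol.
    """
    relevant = cats.bone_terms | cats.metastasis_terms
    pool = {g: "Set-bc" for g in partition["Set-bc"]}
    pool.update({g: "Set-c" for g in partition["Set-c"]})

    annotated = {
        g: annot.gene_terms.get(g, set()) & relevant
        for g in pool
        if annot.gene_terms.get(g, set()) & relevant
    }
    survivors = {g for g in annotated if g not in generic_genes}
    logger.info(
        "refine_targets: pool=%d, relevant-annotated=%d, after generic "
        "removal=%d", len(pool), len(annotated), len(survivors),
    )

    records = []
    for gene in sorted(survivors):
        hits = annotated[gene]
        bone = frozenset(hits & cats.bone_terms)
        met = frozenset(hits & cats.metastasis_terms)
        category = "both" if (bone and met) else ("bone" if bone else "metastasis")
        records.append(TargetRecord(
            gene=gene, region=pool[gene], category=category,
            bone_terms=bone, metastasis_terms=met,
        ))
    return records


@dataclass(frozen=True)
class SelectionSummary:
    """Region sizes, per-step survivor counts and category tallies."""

    region_sizes: dict[str, int]
    pool_size: int
    n_relevant_annotated: int
    n_after_generic_removal: int
    n_bone: int
    n_metastasis: int
    n_both: int

    @property
    def n_total(self) -> int:
        return self.n_bone + self.n_metastasis + self.n_both

    def to_dict(self) -> dict:
        return {
            "region_sizes": dict(self.region_sizes),
            "pool_size": self.pool_size,
            "n_relevant_annotated": self.n_relevant_annotated,
            "n_after_generic_removal": self.n_after_generic_removal,
            "category_tallies": {
                "bone": self.n_bone,
                "metastasis": self.n_metastasis,
                "both": self.n_both,
                "total": self.n_total,
            },
        }


def summarize_selection(
    records: list[TargetRecord],
    partition: VennPartition,
    n_relevant_annotated: int | None = None,
) -> SelectionSummary:
    """Tally the refinement outcome; category counts partition the total.

    ``n_relevant_annotated`` (the step-1 survivor count, before generic
    removal) cannot be recomputed from the records alone; when omitted it
    is reported as the record count.
    """
    n_bone = sum(1 for r in records if r.category == "bone")
    n_met = sum(1 for r in records if r.category == "metastasis")
    n_both = sum(1 for r in records if r.category == "both")
    sizes = partition.sizes()
    return SelectionSummary(
        region_sizes=sizes,
        pool_size=sizes["Set-c"] + sizes["Set-bc"],
        n_relevant_annotated=(n_relevant_annotated
                              if n_relevant_annotated is not None
                              else len(records)),
        n_after_generic_removal=len(records),
        n_bone=n_bone,
        n_metastasis=n_met,
        n_both=n_both,
    )


def predicted_targets(records: list[TargetRecord]) -> set[str]:
    """The final predicted target genes: category ``both``."""
    return {r.gene for r in records if r.category == "both"}


def write_target_report(records: list[TargetRecord], path) -> None:
    """TSV: gene region category bone_terms metastasis_terms."""
    with open(path, "w") as fh:
        fh.write("gene\tregion\tcategory\tbone_terms\tmetastasis_terms\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.region}\t{r.category}\t"
                f"{','.join(sorted(r.bone_terms))}\t"
                f"{','.join(sorted(r.metastasis_terms))}\n"
            )
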