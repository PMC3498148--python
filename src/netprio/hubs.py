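"""Hub identification, controls, and essentiality statistics.

Genes are ranked per metric (descending value, lexicographic tie-break);
the TopK hub gene-set is the union of the first K genes of each chosen
metric's ranking (so it may hold up to 3K genes for the default triple of
degree, betweenness and stress). Negative controls take the bottom K of
each ranking; random controls draw 1000 same-sized samples from the
analysis universe. Essentiality is classified from mouse-phenotype
lethality annotations: a gene is essential when at least one of its MP
terms is in the configured lethal-term list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mouse-phenotype lethality classes defining gene essentiality:
#: neonatal, embryonic, perinatal and postnatal lethality plus the
#: aggregate lethality terms used by MGI.
DEFAULT_LETHAL_TERMS = (
    "MP:0002058",
    "MP:0002080",
    "MP:0002081",
    "MP:0002082",
    "MP:0005373",
    "MP:0005374",
    "MP:0006204",
    "MP:0006205",
    "MP:0006206",
)

#: Metrics used for hub identification unless configured otherwise.
DEFAULT_HUB_METRICS = ("degree", "betweenness", "stress")

#: Hub cutoff thresholds explored by the pipeline.
DEFAULT_K_VALUES = (25, 50, 75, 100, 125, 150, 175, 200)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_genes(metrics: pd.DataFrame, metric_name: str) -> list[str]:
    """Genes ordered by a metric, descending; ties broken lexicographically.

    Genes whose value for the metric is undefined (NaN) are excluded.
    """
    if metric_name not in metrics.columns:
        raise KeyError(
            f"unknown metric {metric_name!r}; have {list(metrics.columns)}"
        )
    col = metrics[metric_name].dropna()
    n_dropped = len(metrics) - len(col)
    if n_dropped:
        logger.info("rank_genes(%s): %d genes with undefined values excluded",
                    metric_name, n_dropped)
    order = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in order]


@dataclass
class HubSet:
    """Union of per-metric TopK genes with provenance."""

    k: int
    genes: set[str]
    #: gene -> set of metric names that admitted it
    provenance: dict[str, set[str]] = field(default_factory=dict)
    #: gene -> {metric: rank} (1-based) for admitting metrics
    ranks: dict[str, dict[str, int]] = field(default_factory=dict)


def build_hub_set(ranked_lists: dict[str, list[str]], k: int) -> HubSet:
    """Union of the top-K genes of each metric's ranking."""
    if k < 1:
        raise ValueError("K must be >= 1")
    hub = HubSet(k=k, genes=set())
    for metric, ranking in ranked_lists.items():
        kk = k
        if k > len(ranking):
            logger.warning("K=%d exceeds %s ranking length %d; capped",
                           k, metric, len(ranking))
            kk = len(ranking)
        for rank, gene in enumerate(ranking[:kk], start=1):
            hub.genes.add(gene)
            hub.provenance.setdefault(gene, set()).add(metric)
            hub.ranks.setdefault(gene, {})[metric] = rank
    return hub


def build_negative_control(ranked_lists: dict[str, list[str]], k: int) -> set[str]:
    """Union of the bottom-K genes of each metric's ranking."""
    if k < 1:
        raise ValueError("K must be >= 1")
    out: set[str] = set()
    for metric, ranking in ranked_lists.items():
        kk = min(k, len(ranking))
        if kk < k:
            logger.warning("K=%d exceeds %s ranking length %d; capped",
                           k, metric, len(ranking))
        out.update(ranking[-kk:] if kk else [])
    return out


def write_hub_report(hub: HubSet, path) -> None:
    """TSV report: gene, admitting metrics, per-metric rank."""
    with open(path, "w") as fh:
        fh.write("gene\tmetrics\tranks\n")
        for gene in sorted(hub.genes):
            mets = sorted(hub.provenance[gene])
            ranks = ",".join(str(hub.ranks[gene][m]) for m in mets)
            fh.write(f"{gene}\t{','.join(mets)}\t{ranks}\n")


# ---------------------------------------------------------------------------
# Random controls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ControlStats:
    """Summary of a random-sampling control experiment."""

    n_samples: int
    sample_size: int
    values: tuple[float, ...]
    mean: float
    stderr: float  # sd of the mean: sample_sd / sqrt(n_samples)
    sample_sd: float  # spread of the control distribution itself
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "sample_size": self.sample_size,
            "mean": self.mean,
            "stderr": self.stderr,
            "sample_sd": self.sample_sd,
            "seed": self.seed,
        }


def sample_random_controls(
    universe: set[str],
    size: int,
    n_samples: int,
    seed: int,
    statistic,
) -> ControlStats:
    """Evaluate a statistic on uniform without-replacement gene samples.

    ``statistic`` is called with each sampled gene set and must return a
    number. Standard error is sd / sqrt(n_samples) (0 when it would be
    undefined for a single sample or zero-variance draws).
    """
    if size > len(universe):
        raise ValueError(f"sample size {size} exceeds universe size {len(universe)}")
    pool = sorted(universe)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_samples):
        pick = rng.choice(len(pool), size=size, replace=False)
        vals.append(float(statistic({pool[i] for i in pick})))
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if n_samples > 1 else 0.0
    return ControlStats(
        n_samples=n_samples,
        sample_size=size,
        values=tuple(vals),
        mean=float(arr.mean()),
        stderr=sd / math.sqrt(n_samples) if n_samples > 1 else 0.0,
        sample_sd=sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Overlap and essentiality
# ---------------------------------------------------------------------------

def overlap_with_reference(gene_set: set[str], reference: set[str]) -> tuple[int, float]:
    """Count and percentage of ``gene_set`` found in ``reference``.

    The percentage is taken over the gene-set size; NaN for an empty set.
    """
    count = len(gene_set & reference)
    if not gene_set:
        return 0, math.nan
    return count, 100.0 * count / len(gene_set)


@dataclass(frozen=True)
class EssentialityMap:
    """Per-gene phenotype annotations and the derived essential flag."""

    phenotypes: dict[str, frozenset[str]]
    essential: frozenset[str]
    lethal_terms: frozenset[str]

    def is_essential(self, gene: str) -> bool:
        return gene in self.essential


def classify_essential(
    phenotypes: dict[str, set[str]],
    lethal_terms=DEFAULT_LETHAL_TERMS,
) -> EssentialityMap:
    """Mark genes essential when any phenotype term is a lethality class.

    Genes absent from the phenotype table are non-essential (their count
    is logged). Term IDs not prefixed ``MP:`` draw a parse warning.
    """
    lethal = frozenset(lethal_terms)
    ess = set()
    for gene, terms in phenotypes.items():
        for t in terms:
            if not t.startswith("MP:"):
                logger.warning("gene %s: malformed phenotype term %r", gene, t)
        if terms & lethal:
            ess.add(gene)
    return EssentialityMap(
        phenotypes={g: frozenset(t) for g, t in phenotypes.items()},
        essential=frozenset(ess),
        lethal_terms=lethal,
    )


def essentiality_fraction(gene_set: set[str], ess: EssentialityMap) -> float:
    """Percentage of the set classified essential, to 2 decimals."""
    if not gene_set:
        raise ValueError("essentiality fraction of an empty gene set")
    n_ess = sum(1 for g in gene_set if ess.is_essential(g))
    return round(100.0 * n_ess / len(gene_set), 2)


def read_phenotype_table(path) -> dict[str, set[str]]:
    """Read a TSV of ``gene<TAB>MP:XXXXXXX`` rows (one row per pair)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            gene, term = parts
            out.setdefault(gene, set()).add(term)
    return out


def write_phenotype_table(phenotypes: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(phenotypes):
            for term in sorted(phenotypes[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_gene_list(path) -> set[str]:
    """One gene symbol per line, case preserved; '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_list(genes: set[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
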