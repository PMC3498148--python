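"""End-to-end orchestration: files in, per-stage outputs and a run report out.

The pipeline wires the stages in method order: interactome construction
(optionally restricted to the giant component) -> node metrics -> hub
gene-sets with negative and random controls -> essentiality statistics ->
hypergeometric enrichment of the curated disease genes against the
interactome universe -> enrichment-derived gene set -> three-set Venn
decomposition -> category refinement into predicted targets.

Configuration is a flat ``key = value`` text file (CLI flags override
file values); every stage writes its documented format so stages can be
re-run independently on each other's outputs. The run report (JSON)
echoes the configuration, the seed and SHA-256 input digests, so a run
is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from . import graph as graph_mod
from . import hubs as hubs_mod
from . import enrichment as enr_mod
from . import targets as tgt_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and bookkeeping for a full pipeline run."""

    edges: str
    ontology: str
    annotations: str
    phenotypes: str
    curated: str
    generic: str
    categories: str | None = None  # packaged defaults when omitted
    outdir: str = "netprio_out"
    hub_metrics: tuple[str, ...] = hubs_mod.DEFAULT_HUB_METRICS
    k_values: tuple[int, ...] = hubs_mod.DEFAULT_K_VALUES
    hub_k: int = 75  # threshold used for target selection
    p_cutoff: float = 0.001
    b_max: int = 100
    lethal_terms: tuple[str, ...] = hubs_mod.DEFAULT_LETHAL_TERMS
    n_control_samples: int = 1000
    seed: int = 0
    giant_only: bool = False
    direct_only: bool = False  # skip true-path propagation in refinement

    def __post_init__(self):
        if self.hub_k < 1 or any(k < 1 for k in self.k_values):
            raise ValueError("hub thresholds must be positive")
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must be in (0, 1]")
        if self.b_max < 1:
            raise ValueError("b_max must be positive")

    _INT_FIELDS = ("hub_k", "b_max", "n_control_samples", "seed")
    _FLOAT_FIELDS = ("p_cutoff",)
    _BOOL_FIELDS = ("giant_only", "direct_only")
    _TUPLE_FIELDS = ("hub_metrics", "lethal_terms")
    _INT_TUPLE_FIELDS = ("k_values",)

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; kwargs take precedence."""
        values: dict = {}
        known = {f.name for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: line {lineno}: expected key = value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
                if key in cls._INT_FIELDS:
                    values[key] = int(val)
                elif key in cls._FLOAT_FIELDS:
                    values[key] = float(val)
                elif key in cls._BOOL_FIELDS:
                    values[key] = val.lower() in ("1", "true", "yes")
                elif key in cls._TUPLE_FIELDS:
                    values[key] = tuple(s.strip() for s in val.split(","))
                elif key in cls._INT_TUPLE_FIELDS:
                    values[key] = tuple(int(s) for s in val.split(","))
                else:
                    values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, write per-stage outputs, return the run report.

    The report is also written to ``<outdir>/run_report.json``. Identical
    configuration and seed give a byte-identical report.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "netprio",
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "input_sha256": {},
        "stages": {},
    }
    for key in ("edges", "ontology", "annotations", "phenotypes",
                "curated", "generic", "categories"):
        path = getattr(cfg, key)
        if path is not None:
            report["input_sha256"][key] = _sha256(path)

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    # --- network ----------------------------------------------------------
    name = stage("build-network")
    try:
        g = graph_mod.read_edge_list(cfg.edges)
        full_nodes = g.number_of_nodes()
        giant, comp = graph_mod.giant_component(g)
        if cfg.giant_only:
            g = giant
        report["stages"]["network"] = {
            "n_nodes_input": full_nodes,
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "n_components": comp.n_components,
            "n_isolated": comp.n_isolated,
            "giant_size": comp.giant_size,
        }
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(name, e) from e

    # --- metrics ----------------------------------------------------------
    name = stage("metrics")
    try:
        metrics = graph_mod.compute_metrics(g)
        graph_mod.write_metrics(metrics, out / "metrics.tsv")
    except Exception as e:
        raise StageError(name, e) from e

    # --- hubs + controls --------------------------------------------------
    name = stage("hubs")
    try:
        universe = set(g.nodes())
        generic = hubs_mod.read_gene_list(cfg.generic)
        curated = hubs_mod.read_gene_list(cfg.curated)
        phen = hubs_mod.read_phenotype_table(cfg.phenotypes)
        ess = hubs_mod.classify_essential(phen, cfg.lethal_terms)

        ranked = {m: hubs_mod.rank_genes(metrics, m) for m in cfg.hub_metrics}
        hub_sets = {k: hubs_mod.build_hub_set(ranked, k) for k in cfg.k_values}
        hub = hub_sets.get(cfg.hub_k) or hubs_mod.build_hub_set(ranked, cfg.hub_k)
        negative = hubs_mod.build_negative_control(ranked, cfg.hub_k)
        hubs_mod.write_hub_report(hub, out / "hubs.tsv")
        hubs_mod.write_gene_list(negative, out / "negative_control.txt")

        overlap_stat = lambda s: hubs_mod.overlap_with_reference(s, generic)[1]
        ess_stat = lambda s: hubs_mod.essentiality_fraction(s, ess)
        ctrl_overlap = hubs_mod.sample_random_controls(
            universe, len(hub.genes), cfg.n_control_samples, cfg.seed,
            overlap_stat)
        ctrl_ess = hubs_mod.sample_random_controls(
            universe, len(hub.genes), cfg.n_control_samples, cfg.seed + 1,
            ess_stat)
        (out / "controls.json").write_text(json.dumps({
            "overlap_with_generic": ctrl_overlap.to_dict(),
            "essentiality": ctrl_ess.to_dict(),
        }, indent=1, sort_keys=True) + "\n")

        non_hub = universe - hub.genes
        report["stages"]["hubs"] = {
            "hub_set_sizes": {str(k): len(h.genes)
                              for k, h in sorted(hub_sets.items())},
            "hub_k": cfg.hub_k,
            "hub_set_size": len(hub.genes),
            "negative_control_size": len(negative),
            "hub_overlap_generic_pct":
                hubs_mod.overlap_with_reference(hub.genes, generic)[1],
            "negative_overlap_generic_pct":
                hubs_mod.overlap_with_reference(negative, generic)[1],
            "random_overlap_generic_pct": ctrl_overlap.mean,
            "random_overlap_generic_se": ctrl_overlap.stderr,
            "random_overlap_generic_sd": ctrl_overlap.sample_sd,
            "hub_essential_pct": hubs_mod.essentiality_fraction(hub.genes, ess),
            "non_hub_essential_pct":
                hubs_mod.essentiality_fraction(non_hub, ess) if non_hub else None,
            "universe_essential_pct":
                hubs_mod.essentiality_fraction(universe, ess),
            "random_essential_pct": ctrl_ess.mean,
            "random_essential_se": ctrl_ess.stderr,
            "random_essential_sd": ctrl_ess.sample_sd,
        }
    except Exception as e:
        raise StageError(name, e) from e

    # --- enrichment -------------------------------------------------------
    name = stage("enrich")
    try:
        onto = enr_mod.read_obo(cfg.ontology)
        direct = enr_mod.read_annotations(cfg.annotations)
        annot = enr_mod.propagate_annotations(onto, direct)
        results = enr_mod.enrich_two_lists(
            curated, universe, annot, onto,
            p_cutoff=cfg.p_cutoff, B_max=cfg.b_max)
        enr_mod.write_enrichment_results(results, out / "enrichment.tsv")
        enriched = enr_mod.enriched_gene_set(results, annot, universe)
        hubs_mod.write_gene_list(enriched, out / "enriched_genes.txt")
        passing = [r for r in results if r.passes_filters]
        by_ns: dict[str, int] = {}
        for r in passing:
            by_ns[r.namespace] = by_ns.get(r.namespace, 0) + 1
        report["stages"]["enrichment"] = {
            "n_terms_tested": len(results),
            "n_passing": len(passing),
            "n_passing_by_namespace": dict(sorted(by_ns.items())),
            "n_enriched_genes": len(enriched),
        }
    except Exception as e:
        raise StageError(name, e) from e

    # --- venn + targets ---------------------------------------------------
    name = stage("targets")
    try:
        cats = (tgt_mod.read_term_categories(cfg.categories)
                if cfg.categories else tgt_mod.TermCategories.default())
        partition = tgt_mod.venn_partition(hub.genes, curated, enriched)
        refine_annot = annot if not cfg.direct_only else direct
        relevant = cats.bone_terms | cats.metastasis_terms
        pool = set(partition["Set-c"]) | set(partition["Set-bc"])
        n_step1 = sum(
            1 for v in pool
            if refine_annot.gene_terms.get(v, set()) & relevant)
        records = tgt_mod.refine_targets(partition, refine_annot, cats, generic)
        tgt_mod.write_target_report(records, out / "targets.tsv")
        summary = tgt_mod.summarize_selection(records, partition,
                                              n_relevant_annotated=n_step1)
        report["stages"]["targets"] = summary.to_dict()
        report["stages"]["targets"]["predicted_targets"] = sorted(
            tgt_mod.predicted_targets(records))
    except Exception as e:
        raise StageError(name, e) from e

    (out / "run_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
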