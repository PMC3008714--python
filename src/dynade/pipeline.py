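"""End-to-end orchestration: select -> cluster -> enrich -> group ->
cluster-enrich, with optional pathway and qPCR stages.

A run consumes a flat key=value config, writes one TSV per stage into the
run directory plus a manifest recording the config, seeds, package version
and per-stage row counts.  Identical config and seeds reproduce the run
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from . import cluster as cluster_mod
from . import enrichment as enr
from . import io as io_mod
from . import qpcr as qpcr_mod
from . import selection as sel_mod

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclasses.dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds of a full run."""

    expression: str = ""
    annotations: str = ""
    ontology: str = ""
    ontology_dialect: str = "edge-tsv"
    gmt: str = ""
    ct_matrix: str = ""
    qpcr_times: str = ""  # comma-separated minutes for the CT columns

    fdr_level: float = 0.05
    enrichment_alpha: float = 0.0025
    cluster_enrichment_alpha: float = 0.05
    qpcr_alpha: float = 0.05
    qpcr_ct_sd: float = 0.25
    k: int = 7
    n_init: int = 50
    n_mc: int = 10000
    n_bins: int = 10
    seed: int = 0
    cluster_seed: int = 1
    qpcr_seed: int = 2

    def __post_init__(self) -> None:
        for name in ("fdr_level", "enrichment_alpha", "cluster_enrichment_alpha", "qpcr_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file (# comments allowed)."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: line {lineno}: expected key = value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields:
                    raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
                kwargs[key] = value
        typed: dict[str, object] = {}
        defaults = cls()
        for key, value in kwargs.items():
            current = getattr(defaults, key)
            if isinstance(current, bool):
                typed[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                typed[key] = int(value)
            elif isinstance(current, float):
                typed[key] = float(value)
            else:
                typed[key] = value
        return cls(**typed)

    def to_items(self) -> list[tuple[str, str]]:
        return [(f.name, str(getattr(self, f.name))) for f in dataclasses.fields(self)]


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with the stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike) -> dict[str, int]:
    """Execute the configured stages and write results + manifest.

    Returns the per-stage row counts recorded in the manifest.
    """
    os.makedirs(out_dir, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}

    with _stage("selection"):
        exp = io_mod.read_expression_tsv(config.expression)
        result = sel_mod.select_genes(
            exp,
            fdr_level=config.fdr_level,
            n_mc=config.n_mc,
            n_bins=config.n_bins,
            seed=config.seed,
        )
        tables["selection"] = result.to_frame()
        counts["selection_genes"] = exp.n_genes
        counts["selection_selected"] = result.n_selected

    selected_genes = result.selected_genes()
    model = None
    if len(selected_genes) >= config.k:
        with _stage("clustering"):
            idx = np.flatnonzero(result.selected)
            profiles = exp.diff()[idx]
            model = cluster_mod.kmeans_profiles(
                profiles,
                gene_ids=selected_genes,
                k=config.k,
                n_init=config.n_init,
                seed=config.cluster_seed,
            )
            tables["clusters"] = model.to_frame()
            tables["centroids"] = cluster_mod.cluster_summary(
                model, exp.times, profiles=profiles, gene_ids=selected_genes
            )
            counts["clusters_k"] = model.k
            counts["clusters_unclustered"] = len(model.unclustered)
    else:
        logger.info("fewer selected genes (%d) than k=%d; skipping clustering",
                    len(selected_genes), config.k)

    groups: list[enr.GOGroup] = []
    ann = None
    if config.annotations:
        with _stage("enrichment"):
            if not config.ontology:
                raise FileNotFoundError("enrichment requires an ontology file")
            dag = io_mod.read_ontology(config.ontology, dialect=config.ontology_dialect)
            ann = io_mod.read_annotations(config.annotations, dag, propagate=True)
            selected_set = set(selected_genes) & ann.genes
            results = enr.elim_enrichment(
                dag, ann, selected_set, alpha=config.enrichment_alpha
            )
            tables["enriched_terms"] = enr.enrichment_to_frame(results)
            enriched_terms = {r.term for r in results if r.enriched}
            counts["enrichment_terms_tested"] = len(results)
            counts["enrichment_enriched"] = len(enriched_terms)
        with _stage("grouping"):
            groups = enr.group_enriched_terms(dag, enriched_terms)
            tables["groups"] = enr.groups_to_frame(groups)
            counts["groups"] = len(groups)
        if groups and model is not None:
            with _stage("cluster_enrichment"):
                tables["cluster_group_enrichment"] = enr.cluster_group_enrichment(
                    groups,
                    ann,
                    set(selected_genes),
                    model.labels(),
                    alpha=config.cluster_enrichment_alpha,
                )
                counts["cluster_group_cells"] = len(tables["cluster_group_enrichment"])

    if config.gmt:
        with _stage("pathways"):
            gene_sets = io_mod.read_gmt(config.gmt)
            universe = set(exp.gene_ids)
            tables["pathways"] = enr.pathway_enrichment(
                gene_sets, set(selected_genes), universe
            )
            counts["pathways_tested"] = len(tables["pathways"])

    if config.ct_matrix:
        with _stage("qpcr"):
            ct = pd.read_csv(config.ct_matrix, sep="\t", index_col=0)
            if config.qpcr_times:
                times = [float(x) for x in config.qpcr_times.split(",")]
            else:
                times = [float(c) for c in ct.columns]
            plate = qpcr_mod.compute_rq(ct)
            qres = qpcr_mod.select_qpcr_genes(
                plate,
                times,
                alpha=config.qpcr_alpha,
                ct_replicate_sd=config.qpcr_ct_sd,
                n_mc=config.n_mc,
                seed=config.qpcr_seed,
            )
            tables["qpcr_rq"] = plate.rq.reset_index()
            tables["qpcr_selection"] = qres.to_frame()
            counts["qpcr_selected"] = qres.n_selected
            shared = sorted(set(qres.gene_ids) & set(exp.gene_ids))
            if shared:
                affy_calls = dict(zip(result.gene_ids, map(bool, result.selected)))
                qpcr_calls = dict(zip(qres.gene_ids, map(bool, qres.selected)))
                table = qpcr_mod.concordance(
                    {g: affy_calls[g] for g in shared},
                    {g: qpcr_calls[g] for g in shared},
                )
                tables["qpcr_concordance"] = table.to_frame()
                counts["qpcr_concordance_genes"] = table.total

    written = io_mod.write_results(tables, out_dir)
    logger.info("wrote %d result tables to %s", len(written), out_dir)

    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"dynade_version\t{__version__}\n")
        for key, value in config.to_items():
            fh.write(f"config.{key}\t{value}\n")
        for key, value in sorted(counts.items()):
            fh.write(f"count.{key}\t{value}\n")
    return counts
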