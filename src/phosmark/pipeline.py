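"""End-to-end pipeline orchestration: phospho -> markers -> DE -> integration.

The pipeline is a pure function of its configuration and input files;
identical config and inputs produce byte-identical outputs, and every run
writes a manifest with a configuration hash and per-stage counts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .de import differential_expression, load_expression, select_resistance_genes
from .design import default_design
from .markers import classify_dataset, marker_predictions, select_markers
from .network import (
    build_network,
    export_graph,
    hypergeometric_enrichment,
    read_edge_list,
    read_gmt,
)
from .phospho import class1_fraction, filter_class1, read_phosphosite_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and design options for one pipeline run."""

    phospho_tables: Dict[str, str] = field(default_factory=dict)  # timepoint -> path
    expression: Optional[str] = None
    sample_sheet: Optional[str] = None
    edges: Optional[str] = None
    gene_sets_gmt: Optional[str] = None
    kinases: Optional[str] = None  # newline-separated symbol list
    out_dir: str = "results"
    class1_threshold: float = 0.75
    silac_cutoff: float = 1.5
    q_max: float = 0.05
    fc_min: float = 2.0
    de_shrink: float = 4.0  # prior df of the variance moderation; 0 = plain pooled t
    min_overlap: int = 2
    swap_labels: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.class1_threshold < 1.0:
            raise ValueError("class1_threshold must lie in (0, 1)")
        if self.silac_cutoff <= 1.0:
            raise ValueError("silac_cutoff must exceed 1")
        if not 0.0 < self.q_max < 1.0:
            raise ValueError("q_max must lie in (0, 1)")
        if self.fc_min <= 1.0:
            raise ValueError("fc_min must exceed 1")
        if self.de_shrink < 0:
            raise ValueError("de_shrink must be non-negative")
        if self.min_overlap not in (2, 3):
            raise ValueError(f"min_overlap must be 2 or 3, got {self.min_overlap}")
        if not self.phospho_tables:
            raise ValueError("no phosphosite tables configured")
        for tp, path in self.phospho_tables.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"phospho table for {tp} not found: {path}")
        for name in ("expression", "sample_sheet", "edges", "gene_sets_gmt", "kinases"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} file not found: {value}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (inputs, thresholds,
        design); the output location does not influence results."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages and write the result bundle plus a manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "counts": {},
    }
    counts = manifest["counts"]

    stage = "phospho"
    try:
        design = default_design(
            timepoints=sorted(config.phospho_tables), swapped=config.swap_labels
        )
        tables = {}
        for tp in design.timepoints:
            records = read_phosphosite_table(config.phospho_tables[tp])
            counts[f"sites_read_{tp}"] = len(records)
            counts[f"class1_fraction_{tp}"] = round(class1_fraction(records), 4)
            tables[tp] = filter_class1(records, config.class1_threshold)
            counts[f"sites_class1_{tp}"] = len(tables[tp])

        stage = "markers"
        results = classify_dataset(
            tables, design, cutoff=config.silac_cutoff, min_overlap=config.min_overlap
        )
        markers = select_markers(results)
        counts.update({f"markers_{k}": v for k, v in markers.summary.items()})
        markers.table.to_csv(
            out_dir / "markers.tsv", sep="\t", index=False, float_format="%.6g"
        )
        (out_dir / "marker_summary.json").write_text(
            json.dumps(markers.summary, indent=1, sort_keys=True)
        )
        predictions = marker_predictions(
            {k: r.classification for k, r in results.items()}, config.min_overlap
        )

        gene_sets = None
        gene_table = pd.DataFrame(columns=["gene", "fold_change"])
        if config.expression and config.sample_sheet:
            stage = "de"
            em = load_expression(config.expression, config.sample_sheet)
            de_base = differential_expression(em, "baseline", shrink=config.de_shrink)
            de_treat = differential_expression(em, "treated", shrink=config.de_shrink)
            de_base.to_csv(out_dir / "de_baseline.tsv", sep="\t", float_format="%.6g")
            de_treat.to_csv(out_dir / "de_treated.tsv", sep="\t", float_format="%.6g")
            gene_sets = select_resistance_genes(
                de_base, de_treat, q_max=config.q_max, fc_min=config.fc_min
            )
            counts["genes_tested"] = len(de_base)
            counts["genes_independent_up"] = len(gene_sets.up)
            counts["genes_independent_down"] = len(gene_sets.down)
            (out_dir / "resistance_genes.json").write_text(
                json.dumps(
                    {"up": sorted(gene_sets.up), "down": sorted(gene_sets.down)},
                    indent=1,
                )
            )
            # signed fold change averaged over the two contrasts (log2 scale)
            mean_l2 = (de_base["log2fc"] + de_treat["log2fc"]) / 2.0
            fold = mean_l2.apply(lambda v: 2.0 ** v if v >= 0 else -(2.0 ** -v))
            gene_table = pd.DataFrame(
                {
                    "gene": sorted(gene_sets.all),
                    "fold_change": [fold[g] for g in sorted(gene_sets.all)],
                }
            )

        stage = "integrate"
        edges = read_edge_list(config.edges) if config.edges else None
        kinases = (
            set(Path(config.kinases).read_text().split()) if config.kinases else None
        )
        graph = build_network(markers.table, gene_table, edges=edges, kinases=kinases)
        counts["network_nodes"] = graph.number_of_nodes()
        counts["network_edges"] = graph.number_of_edges()
        export_graph(graph, out_dir / "network.graphml", "graphml")
        export_graph(graph, out_dir / "network.cyjs", "cytoscape-json")

        if config.gene_sets_gmt:
            stage = "enrich"
            collections = read_gmt(config.gene_sets_gmt)
            universe = set()
            for tp in tables:
                universe |= {r.gene_symbol for r in tables[tp]}
            if config.expression:
                universe |= set(em.values.index)
            selected = {results[k].gene_symbol for k in predictions}
            if gene_sets is not None:
                selected |= gene_sets.all
            selected &= universe
            enrichment = hypergeometric_enrichment(selected, universe, collections)
            enrichment.to_csv(
                out_dir / "enrichment.csv", index=False, float_format="%.6g"
            )
            counts["enriched_terms_q05"] = int((enrichment["q"] <= 0.05).sum())
    except Exception as exc:
        (out_dir / "manifest.json").write_text(
            json.dumps({**manifest, "status": "incomplete", "failed_stage": stage})
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["status"] = "complete"
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
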