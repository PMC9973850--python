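"""Run configuration and pipeline orchestration.

Binds the stages together: compile rank genome sets, search for homologues,
reduce hits to presence, compute PDTs, classify, and optionally run marker
enrichment and island benchmarking. One protein search is performed against
the family-level T1 superset and its hits are partitioned per rank before
filtering, so each backend is invoked once per run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .classifier import (ClassificationThresholds, classifications_to_frame,
                         classify_genome)
from .enrichment import annotate_markers, enrich_alien_set, read_marker_table
from .homology import (BlastBackend, FilterPolicy, MockAlignmentBackend,
                       SearchBackend, TableBackend, filter_hits,
                       presence_matrix, read_genes, search)
from .metrics import (assign_genes_to_islands, confusion, detections_to_frame,
                      island_detection, read_island_table)
from .taxonomy import RANKS, RankedGenomeSets, compile_genome_sets, load_taxonomy_index

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Serializable run configuration; defaults reproduce the published
    decision-rule parameters (30/80/70/40 PDT cutoffs, 70 % coverage,
    60/50/25 identity by rank, T2 fallback below 5 genomes)."""

    taxonomy: str = ""
    genes: str = ""
    query: str = ""
    backend: str = "mock"            # mock | blast | table
    hits_table: str = ""             # for the table backend
    out: str = "phyletic_report.tsv"
    markers: Optional[str] = None
    islands: Optional[str] = None
    gene_coords: Optional[str] = None
    min_t2_size: int = 5
    seed: int = 0
    report_rounding: bool = True
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    filter: FilterPolicy = field(default_factory=FilterPolicy)
    blast_evalue: float = 1e-5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = ClassificationThresholds(**raw.pop("thresholds", {}))
        flt_raw = raw.pop("filter", {})
        flt = FilterPolicy(
            min_query_coverage=flt_raw.get("min_query_coverage", 70.0),
            identity_cutoff_by_rank=flt_raw.get(
                "identity_cutoff_by_rank",
                {"species": 60.0, "genus": 50.0, "family": 25.0}),
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown keys {sorted(unknown)}")
        return cls(thresholds=thr, filter=flt, **raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["thresholds"] = dataclasses.asdict(self.thresholds)
        payload["filter"] = {
            "min_query_coverage": self.filter.min_query_coverage,
            "identity_cutoff_by_rank": dict(self.filter.identity_cutoff_by_rank),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    def make_backend(self) -> SearchBackend:
        if self.backend == "mock":
            return MockAlignmentBackend()
        if self.backend == "blast":
            return BlastBackend(evalue=self.blast_evalue)
        if self.backend == "table":
            if not self.hits_table:
                raise PipelineError("config", "table backend needs hits_table")
            return TableBackend(self.hits_table)
        raise PipelineError("config", f"unknown backend {self.backend!r}")


def rank_presence_matrices(genes, sets: RankedGenomeSets, backend: SearchBackend,
                           policy: FilterPolicy = FilterPolicy(),
                           ) -> dict:
    """Search once against the family T1 superset; build per-rank matrices."""
    superset = sets.family_t1
    raw_hits = search(genes, superset, backend)
    matrices = {}
    for rank in RANKS:
        rank_set = sets.species_t1 if rank == "species" else sets.t1(rank)
        accs = {g.accession for g in rank_set}
        rank_hits = [h for h in raw_hits if h.subject_genome in accs]
        passing = filter_hits(rank_hits, rank, policy)
        matrices[rank] = presence_matrix(passing, genes, rank_set, rank_context=rank)
    return matrices


def profile_and_classify(genes, sets: RankedGenomeSets, backend: SearchBackend,
                         policy: FilterPolicy = FilterPolicy(),
                         thresholds: ClassificationThresholds = ClassificationThresholds()):
    """Search + profile + classify in one call; returns GeneClassifications."""
    matrices = rank_presence_matrices(genes, sets, backend, policy)
    return classify_genome(genes, sets, matrices, thresholds)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the per-stage artifacts.

    Keys of the result: ``classifications`` (DataFrame, also written to
    ``config.out``), ``summary`` (label counts), optional ``enrichment``
    (EnrichmentResult) and ``benchmark`` (confusion + island tables).
    """
    try:
        index = load_taxonomy_index(config.taxonomy)
        sets = compile_genome_sets(config.query, index, config.min_t2_size)
    except Exception as exc:
        raise PipelineError("taxonomy", str(exc)) from exc

    try:
        genes = read_genes(config.genes, source_genome=config.query)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    try:
        backend = config.make_backend()
        matrices = rank_presence_matrices(genes, sets, backend, config.filter)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("homology", str(exc)) from exc

    try:
        results = classify_genome(genes, sets, matrices, config.thresholds)
        frame = classifications_to_frame(results)
    except Exception as exc:
        raise PipelineError("classifier", str(exc)) from exc

    frame.to_csv(config.out, sep="\t", index=False)
    summary = frame["label"].value_counts().to_dict()
    outputs = {"classifications": frame, "summary": summary, "sets": sets}
    logger.info("pipeline: %d genes classified; summary %s", len(frame), summary)

    if config.markers:
        try:
            table = read_marker_table(config.markers)
            annotations = annotate_markers(genes, table)
            outputs["enrichment"] = enrich_alien_set(results, annotations)
        except Exception as exc:
            raise PipelineError("enrichment", str(exc)) from exc

    if config.islands and config.gene_coords:
        try:
            islands = read_island_table(config.islands)
            coords = pd.read_csv(config.gene_coords, sep="\t",
                                 dtype={"gene_id": str, "replicon": str})
            islands = assign_genes_to_islands(coords, islands)
            island_gene_ids = {g for isl in islands for g in isl.member_genes}
            alien_ids = {r.gene_id for r in results if r.is_alien}
            cm = confusion(alien_ids, island_gene_ids, [g.gene_id for g in genes])
            detections, counts, histogram = island_detection(islands, alien_ids)
            outputs["benchmark"] = {
                "confusion": cm,
                "islands": detections_to_frame(detections),
                "detected_counts": counts,
                "histogram": histogram,
            }
        except Exception as exc:
            raise PipelineError("benchmark", str(exc)) from exc

    return outputs
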