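"""Mobile-element marker annotation and hypergeometric enrichment.

Genes matching mobile-element-associated families (transposase, integrase,
prophage, recombinase, plasmid) corroborate a horizontal-acquisition call.
A genome's predicted alien gene set is tested for marker enrichment with an
upper-tail hypergeometric test: drawing n alien genes from a population of
N genes containing K markers, the p-value is P[X >= k] for the k markers
observed among the alien calls (inclusive of k).

Marker evidence comes either from a plain TSV (gene_id, family, e_value) or
from an HMMER ``hmmscan --domtblout`` file; a gene is a marker when its best
hit has E <= 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

DEFAULT_E_CUTOFF = 0.01


class EnrichmentError(ValueError):
    pass


@dataclass
class MarkerAnnotation:
    """Marker status of one gene: best E-value and matched families."""

    gene_id: str
    is_marker: bool
    best_e_value: Optional[float] = None
    matched_families: list = field(default_factory=list)
    note: str = ""


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts and p-value of the marker-in-alien-set hypergeometric test."""

    population_size: int     # N: all genes of the genome
    population_markers: int  # K: markers in the population
    draw_size: int           # n: predicted alien genes
    drawn_markers: int       # k: markers among the alien genes
    p_value: float

    def __post_init__(self):
        N, K, n, k = (self.population_size, self.population_markers,
                      self.draw_size, self.drawn_markers)
        if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
            raise EnrichmentError(
                f"inconsistent counts N={N}, K={K}, n={n}, k={k}"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise EnrichmentError(f"p-value {self.p_value} outside [0, 1]")


def read_marker_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a marker TSV with columns gene_id, family, e_value."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "family": str})
    required = {"gene_id", "family", "e_value"}
    if not required.issubset(df.columns):
        raise EnrichmentError(
            f"marker table {path} lacks columns {sorted(required - set(df.columns))}"
        )
    return df


def read_domtblout(path: Union[str, Path]) -> pd.DataFrame:
    """Parse HMMER ``hmmscan --domtblout`` into (gene_id, family, e_value).

    Uses the full-sequence E-value (best of all domains per query/target
    pair), matching how a practitioner thresholds marker hits.
    """
    from Bio import SearchIO

    rows = []
    for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
        for hit in qresult.hits:
            rows.append({"gene_id": qresult.id, "family": hit.id,
                         "e_value": float(hit.evalue)})
    return pd.DataFrame(rows, columns=["gene_id", "family", "e_value"])


def annotate_markers(genes: Sequence, marker_table: pd.DataFrame,
                     e_cutoff: float = DEFAULT_E_CUTOFF) -> list[MarkerAnnotation]:
    """Annotate each gene's marker status from a gene→(family, E) table.

    A gene absent from the table is a non-marker with an "unscanned" note;
    a gene with hits only above the cutoff is a scanned non-marker.
    """
    gene_ids = [g.gene_id if hasattr(g, "gene_id") else str(g) for g in genes]
    by_gene = dict(tuple(marker_table.groupby("gene_id", sort=False)))
    annotations = []
    for gid in gene_ids:
        sub = by_gene.get(gid)
        if sub is None or sub.empty:
            annotations.append(MarkerAnnotation(gid, False, None, [], "unscanned"))
            continue
        best = float(sub["e_value"].min())
        passing = sub[sub["e_value"] <= e_cutoff]
        annotations.append(MarkerAnnotation(
            gid,
            is_marker=best <= e_cutoff,
            best_e_value=best,
            matched_families=sorted(passing["family"].unique().tolist()),
        ))
    n_mark = sum(a.is_marker for a in annotations)
    logger.info("annotated %d/%d genes as markers (E <= %g)",
                n_mark, len(annotations), e_cutoff)
    return annotations


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Upper-tail hypergeometric test, inclusive of the observed count.

    p = P[X >= k] with X ~ Hypergeometric(N, K, n). k = 0 gives p = 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise EnrichmentError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(1.0, max(0.0, p))
    return EnrichmentResult(N, K, n, k, p)


def enrich_alien_set(classifications: Iterable,
                     annotations: Sequence[MarkerAnnotation]) -> EnrichmentResult:
    """Test the predicted alien gene set of one genome for marker enrichment.

    The population is every classified gene (ambiguous included); the draw
    is the alien calls only — ambiguous genes are never drawn.
    """
    marker_ids = {a.gene_id for a in annotations if a.is_marker}
    all_ids, alien_ids = [], set()
    for c in classifications:
        all_ids.append(c.gene_id)
        if c.is_alien:
            alien_ids.add(c.gene_id)
    N = len(all_ids)
    K = sum(1 for g in all_ids if g in marker_ids)
    n = len(alien_ids)
    k = sum(1 for g in alien_ids if g in marker_ids)
    return hypergeometric_enrichment(N, K, n, k)
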