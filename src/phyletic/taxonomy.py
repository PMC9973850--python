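"""Taxonomy index and rank-level genome-set compilation.

A query genome is profiled against genome sets drawn from its own species,
genus and family. For each rank two sets exist: the inclusive set of every
genome in the rank ("T1") and the set obtained by removing the query's group
at the next-lower rank ("T2"). The T2 sets expose transfers that happened in
the common ancestor of the excluded group; when a T2 set is too small for a
robust phyletic estimate it falls back to its T1 set.

The taxonomy source is a plain TSV (one row per assembled genome) rather
than an NCBI taxdump; see :data:`TAXONOMY_COLUMNS` for the dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of the taxonomy TSV, in canonical order. The three
#: ``*_name`` columns are optional human-readable labels.
TAXONOMY_COLUMNS = ["accession", "species_id", "genus_id", "family_id"]
TAXONOMY_NAME_COLUMNS = ["species_name", "genus_name", "family_name"]

RANKS = ("species", "genus", "family")


class TaxonomyError(ValueError):
    """Malformed taxonomy input (duplicate accession, missing rank, ...)."""


@dataclass(frozen=True)
class Lineage:
    """Three-rank lineage of a genome (species -> genus -> family)."""

    species_id: str
    genus_id: str
    family_id: str
    names: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self):
        for rank in RANKS:
            if not getattr(self, f"{rank}_id"):
                raise TaxonomyError(f"empty {rank}_id in lineage")

    def rank_id(self, rank: str) -> str:
        if rank not in RANKS:
            raise TaxonomyError(f"unknown rank {rank!r}")
        return getattr(self, f"{rank}_id")


@dataclass(frozen=True)
class GenomeRecord:
    """One assembled genome: unique accession, lineage, proteome locator.

    ``proteome_ref`` points at the genome's protein FASTA (or at a
    precomputed hit table for table-backend runs); it is resolved lazily at
    search time, so an index can be built from taxonomy alone.
    """

    accession: str
    lineage: Lineage
    proteome_ref: Optional[str] = None


class TaxonomyIndex:
    """In-memory genome index queryable by accession or by rank identifier."""

    def __init__(self, records: Iterable[GenomeRecord]):
        self._by_accession: dict[str, GenomeRecord] = {}
        species_parent: dict[str, tuple[str, str]] = {}
        for rec in records:
            if rec.accession in self._by_accession:
                raise TaxonomyError(f"duplicate accession {rec.accession!r}")
            parent = (rec.lineage.genus_id, rec.lineage.family_id)
            seen = species_parent.setdefault(rec.lineage.species_id, parent)
            if seen != parent:
                raise TaxonomyError(
                    f"species {rec.lineage.species_id!r} maps to conflicting "
                    f"genus/family pairs {seen} and {parent}"
                )
            self._by_accession[rec.accession] = rec

    def __len__(self) -> int:
        return len(self._by_accession)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __iter__(self):
        return iter(self._by_accession.values())

    def get(self, accession: str) -> GenomeRecord:
        try:
            return self._by_accession[accession]
        except KeyError:
            raise TaxonomyError(f"accession {accession!r} not in index") from None

    def members(self, rank: str, rank_id: str) -> set[GenomeRecord]:
        """All genomes whose lineage carries ``rank_id`` at ``rank``."""
        if rank not in RANKS:
            raise TaxonomyError(f"unknown rank {rank!r}")
        return {r for r in self if r.lineage.rank_id(rank) == rank_id}


@dataclass
class RankedGenomeSets:
    """The per-query genome sets used for phyletic profiling.

    The query genome itself is excluded from every set (a self-hit would make
    every gene trivially "present"). ``fallback_flags[rank]`` records that the
    rank's T2 set was smaller than ``min_t2_size`` and was replaced by T1.
    """

    query: GenomeRecord
    species_t1: set[GenomeRecord] = field(default_factory=set)
    genus_t1: set[GenomeRecord] = field(default_factory=set)
    genus_t2: set[GenomeRecord] = field(default_factory=set)
    family_t1: set[GenomeRecord] = field(default_factory=set)
    family_t2: set[GenomeRecord] = field(default_factory=set)
    fallback_flags: dict = field(default_factory=lambda: {"genus": False, "family": False})
    species_empty: bool = False

    def t1(self, rank: str) -> set[GenomeRecord]:
        return getattr(self, f"{rank}_t1") if rank != "species" else self.species_t1

    def accessions(self, which: str) -> set[str]:
        return {g.accession for g in getattr(self, which)}


def load_taxonomy_index(table_source: Union[str, Path, pd.DataFrame]) -> TaxonomyIndex:
    """Load a genome index from a taxonomy TSV (or an equivalent DataFrame).

    The table must carry one row per genome with ``accession`` and the three
    rank identifiers; optional name columns are attached to the lineage.

    Raises
    ------
    TaxonomyError
        On a duplicate accession (named) or a missing/blank rank field
        (reported with its 1-based data row number).
    """
    if isinstance(table_source, pd.DataFrame):
        df = table_source.copy()
    else:
        df = pd.read_csv(table_source, sep="\t", dtype=str)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise TaxonomyError(f"taxonomy table lacks required columns: {missing}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        for col in TAXONOMY_COLUMNS:
            val = row.get(col)
            if val is None or pd.isna(val) or str(val).strip() == "":
                raise TaxonomyError(f"row {i}: missing {col}")
        names = {
            rank: str(row[f"{rank}_name"])
            for rank in RANKS
            if f"{rank}_name" in row and pd.notna(row.get(f"{rank}_name"))
        }
        lineage = Lineage(
            species_id=str(row["species_id"]),
            genus_id=str(row["genus_id"]),
            family_id=str(row["family_id"]),
            names=names or None,
        )
        ref = row.get("proteome_ref")
        records.append(
            GenomeRecord(
                accession=str(row["accession"]),
                lineage=lineage,
                proteome_ref=None if ref is None or pd.isna(ref) else str(ref),
            )
        )
    index = TaxonomyIndex(records)
    logger.info("loaded taxonomy index with %d genomes", len(index))
    return index


def compile_genome_sets(
    query: Union[GenomeRecord, str],
    index: TaxonomyIndex,
    min_t2_size: int = 5,
) -> RankedGenomeSets:
    """Compile the five rank-level genome sets for ``query``.

    T1 at a rank is every genome sharing the query's identifier at that rank
    (query excluded); T2 removes, in addition, the query's group at the rank
    just below (its species from the genus set, its genus from the family
    set). A T2 set with fewer than ``min_t2_size`` members is replaced by its
    T1 set and the rank's fallback flag raised.

    Raises
    ------
    TaxonomyError
        If the query is absent from the index, or the index is empty of
        comparators altogether.
    """
    if isinstance(query, str):
        query = index.get(query)
    elif query.accession not in index:
        raise TaxonomyError(f"query {query.accession!r} not in index")

    lin = query.lineage
    species_t1 = index.members("species", lin.species_id) - {query}
    genus_t1 = index.members("genus", lin.genus_id) - {query}
    family_t1 = index.members("family", lin.family_id) - {query}
    if not family_t1:
        raise TaxonomyError(
            f"no comparators: index holds no genome besides {query.accession!r} "
            f"in family {lin.family_id!r}"
        )
    genus_t2 = genus_t1 - species_t1
    family_t2 = family_t1 - genus_t1

    sets = RankedGenomeSets(
        query=query,
        species_t1=species_t1,
        genus_t1=genus_t1,
        genus_t2=genus_t2,
        family_t1=family_t1,
        family_t2=family_t2,
    )
    for rank, t2, t1 in (("genus", genus_t2, genus_t1), ("family", family_t2, family_t1)):
        if len(t2) < min_t2_size:
            setattr(sets, f"{rank}_t2", set(t1))
            sets.fallback_flags[rank] = True
            logger.info(
                "rank %s: T2 set (%d genomes) below min_t2_size=%d; using T1 (%d genomes)",
                rank, len(t2), min_t2_size, len(t1),
            )
    if not species_t1:
        sets.species_empty = True
        logger.warning(
            "query %s is the sole sequenced member of species %s; "
            "species-level inference degenerates", query.accession, lin.species_id,
        )
    return sets
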