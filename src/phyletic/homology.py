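"""Protein homology search, hit filtering and presence/absence profiling.

A gene is "present" in a comparator genome when at least one protein search
hit against that genome survives the rank-specific filters: query coverage
of at least 70 % at every rank, and percent identity of at least 60 % within
the species, 50 % within the genus and 25 % within the family (the identity
bar relaxes with rank to absorb divergence over longer evolutionary times).

Three interchangeable backends produce hits:

* :class:`MockAlignmentBackend` — deterministic exact global alignment of
  every query against every subject protein (no external binary);
* :class:`TableBackend` — replays a precomputed BLAST-tabular hit file;
* :class:`BlastBackend` — thin adapter over ``makeblastdb``/``blastp``.

Hit tables use the 12-column BLAST ``outfmt 6`` order with two appended
columns ``qlen`` and ``qcovs``.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .taxonomy import RANKS, GenomeRecord

logger = logging.getLogger(__name__)

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

#: Column order of hit tables (BLAST outfmt 6 + qlen + qcovs).
HIT_TABLE_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "qcovs",
]


class HomologyError(ValueError):
    """Invalid homology input or backend failure."""


@dataclass(frozen=True)
class QueryGene:
    """A protein-coding query gene (amino-acid sequence)."""

    gene_id: str
    sequence: str
    source_genome: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise HomologyError(f"gene {self.gene_id!r}: empty sequence")
        bad = set(self.sequence.upper()) - AMINO_ALPHABET
        if bad:
            raise HomologyError(
                f"gene {self.gene_id!r}: non-amino-acid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class HomologyHit:
    """One query-gene vs subject-protein hit with its alignment statistics."""

    gene_id: str
    subject_genome: str
    subject_protein: str
    percent_identity: float
    query_coverage: float
    e_value: float
    bit_score: float

    def __post_init__(self):
        if not 0.0 <= self.percent_identity <= 100.0:
            raise HomologyError(f"percent_identity {self.percent_identity} out of [0, 100]")
        if not 0.0 <= self.query_coverage <= 100.0:
            raise HomologyError(f"query_coverage {self.query_coverage} out of [0, 100]")
        if self.e_value < 0:
            raise HomologyError(f"negative e-value {self.e_value}")


@dataclass(frozen=True)
class FilterPolicy:
    """Coverage and rank-dependent identity thresholds for presence calling.

    Both filters are inclusive: a hit at exactly the cutoff is retained.
    """

    min_query_coverage: float = 70.0
    identity_cutoff_by_rank: Mapping[str, float] = field(
        default_factory=lambda: {"species": 60.0, "genus": 50.0, "family": 25.0}
    )

    def __post_init__(self):
        cuts = [self.identity_cutoff_by_rank[r] for r in RANKS]
        if not (cuts[0] > cuts[1] > cuts[2]):
            raise HomologyError(
                "identity cutoffs must strictly decrease from species to family, "
                f"got {cuts}"
            )
        for c in cuts + [self.min_query_coverage]:
            if not 0.0 < c <= 100.0:
                raise HomologyError(f"cutoff {c} outside (0, 100]")


@dataclass
class PresenceMatrix:
    """Boolean gene x genome presence, with the rank whose filters built it."""

    data: pd.DataFrame  # index: gene_id, columns: genome accession, dtype bool
    rank_context: str

    def pdt_counts(self) -> pd.Series:
        """Number of genomes each gene is present in."""
        return self.data.sum(axis=1)

    def subset(self, accessions: Iterable[str]) -> "PresenceMatrix":
        """Restrict the matrix to a genome subset (for T2 profiling)."""
        cols = [a for a in self.data.columns if a in set(accessions)]
        return PresenceMatrix(self.data[cols], self.rank_context)


# ---------------------------------------------------------------------------
# FASTA / hit-table I/O


def read_genes(fasta: Union[str, Path], source_genome: str = "") -> list[QueryGene]:
    """Read query genes from a protein FASTA; ids must be unique."""
    genes, seen = [], set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in seen:
            raise HomologyError(f"duplicate gene id {rec.id!r} in {fasta}")
        seen.add(rec.id)
        genes.append(QueryGene(rec.id, str(rec.seq), source_genome))
    return genes


def subject_genome_of(sseqid: str) -> str:
    """Genome accession encoded in a subject id (``ACCESSION|protein``)."""
    return sseqid.split("|", 1)[0]


def read_hit_table(path: Union[str, Path]) -> list[HomologyHit]:
    """Parse a 14-column hit TSV into hits, preserving input order."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(HIT_TABLE_COLUMNS):
                raise HomologyError(
                    f"{path}: line {lineno}: expected {len(HIT_TABLE_COLUMNS)} "
                    f"columns, found {len(parts)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        gene_id=parts[0],
                        subject_genome=subject_genome_of(parts[1]),
                        subject_protein=parts[1],
                        percent_identity=float(parts[2]),
                        query_coverage=float(parts[13]),
                        e_value=float(parts[10]),
                        bit_score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise HomologyError(f"{path}: line {lineno}: {exc}") from None
    return hits


def write_hit_table(hits: Sequence[HomologyHit], genes: Sequence[QueryGene],
                    path: Union[str, Path]) -> None:
    """Write hits in the 14-column dialect (alignment coords synthesised)."""
    qlen = {g.gene_id: len(g.sequence) for g in genes}
    with open(path, "w") as fh:
        for h in hits:
            L = qlen.get(h.gene_id, 0)
            alen = max(1, round(L * h.query_coverage / 100.0))
            fh.write("\t".join(map(str, [
                h.gene_id, h.subject_protein, f"{h.percent_identity:.3f}",
                alen, 0, 0, 1, alen, 1, alen,
                f"{h.e_value:.3g}", f"{h.bit_score:.1f}", L,
                f"{h.query_coverage:.3f}",
            ])) + "\n")


# ---------------------------------------------------------------------------
# Search backends


class SearchBackend:
    """Interface: produce raw hits of query genes against genome proteomes."""

    def search(self, genes: Sequence[QueryGene],
               genomes: Iterable[GenomeRecord]) -> list[HomologyHit]:
        raise NotImplementedError


def _load_proteome(record: GenomeRecord) -> dict[str, str]:
    if record.proteome_ref is None:
        raise HomologyError(f"genome {record.accession!r} has no proteome_ref")
    path = Path(record.proteome_ref)
    if not path.exists():
        raise HomologyError(f"proteome FASTA not found: {path}")
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


class MockAlignmentBackend(SearchBackend):
    """Deterministic in-process search by exact global protein alignment.

    Every query is globally aligned (BLOSUM62, affine gaps) against every
    subject protein. Percent identity is identical columns over alignment
    columns; query coverage is the fraction of query residues aligned to a
    subject residue. Hits below ``min_report_identity`` are not reported
    (the backend's reporting floor, analogous to a real search tool not
    returning hopeless alignments). E-values are a deterministic monotone
    transform of the score — presence calling never depends on them.

    Proteomes are read from each record's ``proteome_ref`` unless supplied
    in-memory via ``proteomes`` ({accession: {protein_id: sequence}}).
    """

    def __init__(self, proteomes: Optional[Mapping[str, Mapping[str, str]]] = None,
                 min_report_identity: float = 15.0):
        self.proteomes = proteomes
        self.min_report_identity = min_report_identity
        self._aligner = PairwiseAligner()
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.open_gap_score = -11.0
        self._aligner.extend_gap_score = -1.0
        self._aligner.mode = "global"

    def _proteome(self, record: GenomeRecord) -> Mapping[str, str]:
        if self.proteomes is not None and record.accession in self.proteomes:
            return self.proteomes[record.accession]
        return _load_proteome(record)

    def align_stats(self, query: str, subject: str) -> tuple[float, float, float]:
        """(percent_identity, query_coverage, score) of the best global alignment."""
        # substitution matrices lack '*'; strip terminal stops, map rare chars
        q = query.rstrip("*").replace("*", "X")
        s = subject.rstrip("*").replace("*", "X")
        aln = self._aligner.align(q, s)[0]
        matches = aligned_q = 0
        for (qs, qe), (ss, se) in zip(*aln.aligned):
            aligned_q += qe - qs
            matches += sum(1 for a, b in zip(q[qs:qe], s[ss:se]) if a == b)
        identity = 100.0 * matches / aln.length if aln.length else 0.0
        coverage = 100.0 * aligned_q / len(q) if q else 0.0
        return identity, coverage, float(aln.score)

    def search(self, genes, genomes):
        hits = []
        for record in sorted(genomes, key=lambda r: r.accession):
            proteome = self._proteome(record)
            for gene in genes:
                for prot_id, prot_seq in proteome.items():
                    if not prot_seq:
                        continue
                    identity, coverage, score = self.align_stats(gene.sequence, prot_seq)
                    if identity < self.min_report_identity:
                        continue
                    e_value = 10.0 ** (-max(score, 0.0) / 10.0)
                    hits.append(HomologyHit(
                        gene_id=gene.gene_id,
                        subject_genome=record.accession,
                        subject_protein=f"{record.accession}|{prot_id}"
                        if "|" not in prot_id else prot_id,
                        percent_identity=identity,
                        query_coverage=coverage,
                        e_value=e_value,
                        bit_score=score,
                    ))
        return hits


class TableBackend(SearchBackend):
    """Replay hits from a precomputed hit table, restricted to the request."""

    def __init__(self, table: Union[str, Path, Sequence[HomologyHit]]):
        if isinstance(table, (str, Path)):
            self._hits = read_hit_table(table)
        else:
            self._hits = list(table)

    def search(self, genes, genomes):
        gene_ids = {g.gene_id for g in genes}
        accessions = {g.accession for g in genomes}
        return [h for h in self._hits
                if h.gene_id in gene_ids and h.subject_genome in accessions]


class BlastBackend(SearchBackend):
    """Adapter over NCBI BLAST+ ``makeblastdb`` + ``blastp``.

    Builds one database per genome set (subject ids prefixed with the genome
    accession) and parses tabular output with appended qlen/qcovs columns.
    """

    def __init__(self, evalue: float = 1e-5, threads: int = 1):
        self.evalue = evalue
        self.threads = threads
        for exe in ("makeblastdb", "blastp"):
            if shutil.which(exe) is None:
                raise HomologyError(
                    f"{exe} not found on PATH; install NCBI BLAST+ or use the "
                    "mock/table backend"
                )

    def search(self, genes, genomes):
        with tempfile.TemporaryDirectory(prefix="phyletic_blast_") as tmp:
            tmp = Path(tmp)
            db_fasta = tmp / "subjects.faa"
            with open(db_fasta, "w") as fh:
                for record in sorted(genomes, key=lambda r: r.accession):
                    for pid, seq in _load_proteome(record).items():
                        sid = pid if "|" in pid else f"{record.accession}|{pid}"
                        fh.write(f">{sid}\n{seq}\n")
            query_fasta = tmp / "query.faa"
            with open(query_fasta, "w") as fh:
                for g in genes:
                    fh.write(f">{g.gene_id}\n{g.sequence}\n")
            subprocess.run(
                ["makeblastdb", "-in", str(db_fasta), "-dbtype", "prot",
                 "-out", str(tmp / "db")],
                check=True, capture_output=True,
            )
            out = tmp / "hits.tsv"
            subprocess.run(
                ["blastp", "-query", str(query_fasta), "-db", str(tmp / "db"),
                 "-evalue", str(self.evalue), "-num_threads", str(self.threads),
                 "-outfmt", "6 " + " ".join(HIT_TABLE_COLUMNS), "-out", str(out)],
                check=True, capture_output=True,
            )
            return read_hit_table(out)


# ---------------------------------------------------------------------------
# Operations


def search(genes: Sequence[QueryGene], genomes: Iterable[GenomeRecord],
           backend: SearchBackend) -> list[HomologyHit]:
    """Run the backend and return all raw (unfiltered) hits."""
    hits = backend.search(genes, list(genomes))
    logger.info("search: %d genes vs %d genomes -> %d raw hits",
                len(genes), len(list(genomes)), len(hits))
    return hits


def filter_hits(hits: Sequence[HomologyHit], rank: str,
                policy: FilterPolicy = FilterPolicy()) -> list[HomologyHit]:
    """Keep hits meeting the coverage floor and the rank's identity cutoff."""
    if rank not in RANKS:
        raise HomologyError(f"unknown rank {rank!r}; expected one of {RANKS}")
    identity_cut = policy.identity_cutoff_by_rank[rank]
    return [
        h for h in hits
        if h.query_coverage >= policy.min_query_coverage
        and h.percent_identity >= identity_cut
    ]


def presence_matrix(passing_hits: Sequence[HomologyHit],
                    genes: Sequence[QueryGene],
                    genome_set: Iterable[GenomeRecord],
                    rank_context: str = "") -> PresenceMatrix:
    """Reduce rank-filtered hits to a boolean gene x genome matrix.

    Genomes with no hit appear as all-false columns; a hit referencing a
    genome outside the set signals a set/search mismatch and raises.
    """
    accessions = sorted(g.accession for g in genome_set)
    gene_ids = [g.gene_id for g in genes]
    data = pd.DataFrame(False, index=gene_ids, columns=accessions, dtype=bool)
    for h in passing_hits:
        if h.subject_genome not in data.columns:
            raise HomologyError(
                f"hit of {h.gene_id!r} references genome {h.subject_genome!r} "
                "outside the profiled set"
            )
        if h.gene_id in data.index:
            data.loc[h.gene_id, h.subject_genome] = True
    return PresenceMatrix(data, rank_context)
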