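"""Phyletic-distribution (PDT) computation and the hierarchical decision tree.

The PDT of a gene in a genome set is the percentage of genomes in the set
that harbour a homologue. Classification walks the taxonomy from species to
family:

* a gene present in fewer than 30 % of the query's species-mates is called
  **alien (recent transfer)** outright;
* a gene well distributed in the species (> 80 %) may still be an ancient
  acquisition by the species' or genus' common ancestor, so its PDT is
  re-examined in the genus and family sets *with the lower group excluded*
  (the T2 sets) — sporadic presence there (< 30 %) yields an ancestral alien
  call, broad presence in the family (> 40 %) yields native, the middle band
  is ambiguous;
* genes in the intermediate species band (30–80 %) are tested against the
  inclusive genus and family sets (T1): < 30 % alien, > 70 % (genus) or
  > 40 % (family) native, otherwise ambiguous.

All comparisons are strict, with unrounded PDTs; a PDT exactly at a cutoff
falls through to the next rule. The native bar relaxes from genus (70 %) to
family (40 %) to absorb gene loss and detection failure at larger
evolutionary distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .homology import PresenceMatrix
from .taxonomy import RankedGenomeSets

logger = logging.getLogger(__name__)

LABELS = ("alien_recent", "alien_ancestral_species", "alien_ancestral_genus",
          "native", "ambiguous")
ALIEN_LABELS = ("alien_recent", "alien_ancestral_species", "alien_ancestral_genus")


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class ClassificationThresholds:
    """PDT cutoffs of the decision tree (percentages).

    alien_pdt: below this a gene is sporadic enough to be called alien.
    species_well_distributed: above this the gene saturates its species and
        only ancestral acquisition remains plausible.
    genus_native / family_native: native bars in the inclusive genus/family
        sets; the family bar is lower by design.
    """

    alien_pdt: float = 30.0
    species_well_distributed: float = 80.0
    genus_native: float = 70.0
    family_native: float = 40.0

    def __post_init__(self):
        if not self.alien_pdt < self.species_well_distributed:
            raise ClassifierError("alien_pdt must be below species_well_distributed")
        if not self.alien_pdt <= self.family_native <= self.genus_native:
            raise ClassifierError(
                "expected alien_pdt <= family_native <= genus_native, got "
                f"{self.alien_pdt}, {self.family_native}, {self.genus_native}"
            )


@dataclass
class PdtProfile:
    """Per-gene PDT across the five genome sets (None = undefined/empty set)."""

    gene_id: str = ""
    pdt_species: Optional[float] = None
    pdt_genus_t1: Optional[float] = None
    pdt_genus_t2: Optional[float] = None
    pdt_family_t1: Optional[float] = None
    pdt_family_t2: Optional[float] = None
    set_sizes: dict = field(default_factory=dict)
    fallback_flags: dict = field(default_factory=dict)


@dataclass
class GeneClassification:
    """Decision-tree verdict for one gene with its PDT evidence trail.

    ``decided_at`` names the rank and set type where the deciding rule fired
    (e.g. ``species``, ``genus/T2``, ``family/T1``); ``species_skipped``
    marks genes classified without a species-level test because the query is
    its species' only sequenced member.
    """

    gene_id: str
    label: str
    decided_at: str
    profile: PdtProfile
    species_skipped: bool = False

    @property
    def is_alien(self) -> bool:
        return self.label in ALIEN_LABELS


def compute_pdt(presence_row: Iterable[bool], set_size: int) -> Optional[float]:
    """Percentage of genomes in the set harbouring the gene (unrounded).

    An empty set has no defined PDT: returns None rather than 0 or 100.
    """
    if set_size < 0:
        raise ClassifierError(f"negative set size {set_size}")
    if set_size == 0:
        return None
    present = int(np.count_nonzero(np.asarray(list(presence_row), dtype=bool)))
    if present > set_size:
        raise ClassifierError(f"{present} presences exceed set size {set_size}")
    return 100.0 * present / set_size


def classify_gene(profile: PdtProfile,
                  thresholds: ClassificationThresholds = ClassificationThresholds(),
                  ) -> GeneClassification:
    """Apply the species→genus→family decision tree to one PDT profile.

    With an undefined species PDT (query alone in its species) the tree
    starts at the intermediate-band rules on the genus T1 set, and the
    result is flagged ``species_skipped``. An undefined genus or family PDT
    skips that rank's tests and falls through to the next.
    """
    t = thresholds
    s = profile.pdt_species

    def verdict(label, decided_at, skipped=False):
        return GeneClassification(profile.gene_id, label, decided_at, profile,
                                  species_skipped=skipped)

    skipped = s is None
    if not skipped:
        if s < t.alien_pdt:
            return verdict("alien_recent", "species")
        if s > t.species_well_distributed:
            # ancestral-acquisition rules on the exclusion (T2) sets
            g2, f2 = profile.pdt_genus_t2, profile.pdt_family_t2
            if g2 is not None and g2 < t.alien_pdt:
                return verdict("alien_ancestral_species", "genus/T2")
            if f2 is not None:
                if f2 < t.alien_pdt:
                    return verdict("alien_ancestral_genus", "family/T2")
                if f2 > t.family_native:
                    return verdict("native", "family/T2")
            return verdict("ambiguous", "family/T2")

    # intermediate species band (or species test unavailable): inclusive sets
    g1, f1 = profile.pdt_genus_t1, profile.pdt_family_t1
    if g1 is not None:
        if g1 < t.alien_pdt:
            return verdict("alien_recent", "genus/T1", skipped)
        if g1 > t.genus_native:
            return verdict("native", "genus/T1", skipped)
    if f1 is not None:
        if f1 < t.alien_pdt:
            return verdict("alien_recent", "family/T1", skipped)
        if f1 > t.family_native:
            return verdict("native", "family/T1", skipped)
    if g1 is None and f1 is None:
        raise ClassifierError(
            f"gene {profile.gene_id!r}: no defined PDT at any rank; "
            "cannot classify against an empty universe"
        )
    return verdict("ambiguous", "family/T1", skipped)


def build_profiles(gene_ids: Sequence[str], sets: RankedGenomeSets,
                   matrices: Mapping[str, PresenceMatrix]) -> list[PdtProfile]:
    """Assemble PDT profiles from per-rank T1 presence matrices.

    ``matrices`` maps rank → PresenceMatrix over that rank's T1 set
    (computed with the rank-matched filters); T2 PDTs are obtained by
    restricting the columns to the T2 accessions, except when the fallback
    fired, in which case the T2 slot deliberately repeats the T1 value.
    """
    slots = {
        "pdt_species": ("species", sets.accessions("species_t1")),
        "pdt_genus_t1": ("genus", sets.accessions("genus_t1")),
        "pdt_genus_t2": ("genus", sets.accessions("genus_t2")),
        "pdt_family_t1": ("family", sets.accessions("family_t1")),
        "pdt_family_t2": ("family", sets.accessions("family_t2")),
    }
    set_sizes = {name: len(acc) for name, (_, acc) in slots.items()}
    profiles = []
    for gid in gene_ids:
        prof = PdtProfile(gene_id=gid, set_sizes=set_sizes,
                          fallback_flags=dict(sets.fallback_flags))
        for slot, (rank, accessions) in slots.items():
            matrix = matrices.get(rank)
            if matrix is None:
                raise ClassifierError(f"no presence matrix for rank {rank!r}")
            if gid not in matrix.data.index:
                raise ClassifierError(
                    f"gene {gid!r} missing from the {rank} presence matrix"
                )
            row = matrix.subset(accessions).data.loc[gid]
            setattr(prof, slot, compute_pdt(row.to_numpy(), len(accessions)))
        profiles.append(prof)
    return profiles


def classify_genome(genes: Sequence, sets: RankedGenomeSets,
                    matrices: Mapping[str, PresenceMatrix],
                    thresholds: ClassificationThresholds = ClassificationThresholds(),
                    ) -> list[GeneClassification]:
    """Classify every gene of a query genome; order preserved."""
    gene_ids = [g.gene_id if hasattr(g, "gene_id") else str(g) for g in genes]
    profiles = build_profiles(gene_ids, sets, matrices)
    results = [classify_gene(p, thresholds) for p in profiles]
    counts = pd.Series([r.label for r in results]).value_counts().to_dict()
    logger.info("classified %d genes: %s", len(results), counts)
    return results


def classifications_to_frame(results: Sequence[GeneClassification]) -> pd.DataFrame:
    """Tabular report: one row per gene with label, locus of decision, PDTs."""
    rows = []
    for r in results:
        p = r.profile
        rows.append({
            "gene_id": r.gene_id,
            "label": r.label,
            "decided_at": r.decided_at,
            "pdt_species": p.pdt_species,
            "pdt_genus_t1": p.pdt_genus_t1,
            "pdt_genus_t2": p.pdt_genus_t2,
            "pdt_family_t1": p.pdt_family_t1,
            "pdt_family_t2": p.pdt_family_t2,
            "n_species": p.set_sizes.get("pdt_species"),
            "n_genus_t1": p.set_sizes.get("pdt_genus_t1"),
            "n_genus_t2": p.set_sizes.get("pdt_genus_t2"),
            "n_family_t1": p.set_sizes.get("pdt_family_t1"),
            "n_family_t2": p.set_sizes.get("pdt_family_t2"),
            "genus_fallback": p.fallback_flags.get("genus", False),
            "family_fallback": p.fallback_flags.get("family", False),
            "species_skipped": r.species_skipped,
        })
    return pd.DataFrame(rows)
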