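"""Self-contained synthetic test universes with known gene ancestry.

Generates a query genome plus species/genus/family comparator genomes whose
gene sharing follows configurable per-rank probabilities, then plants
horizontal acquisitions from out-of-family donors at controlled protein
divergence (0–30 % in 5-point steps, emulating transfer followed by
sequence drift). Every gene carries a truth label, so the full
taxonomy → homology → classification pipeline can be scored without any
external data.

Divergence is applied at the protein level as uniform random substitutions
(each mutated site takes one of the 19 alternative residues) at positions
sampled without replacement — the simplest model that realises an exact
target identity; it carries no substitution-matrix biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .taxonomy import load_taxonomy_index, compile_genome_sets

AA20 = "ACDEFGHIKLMNPQRSTVWY"

MARKER_FAMILIES = ["transposase", "integrase", "prophage_coat", "recombinase",
                   "plasmid_mob"]

MAX_DIVERGENCE = 30.0


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class UniverseConfig:
    """Shape and sharing structure of a synthetic universe.

    ``p_species``/``p_genus``/``p_family`` are the per-genome probabilities
    that a comparator at that relation carries a homologue of a query native
    gene; they set the expected PDTs the classifier sees. Homolog copies
    drift by ``homolog_divergence`` percent so comparator proteomes are not
    byte-copies, while staying far inside the species identity cutoff.
    """

    n_species_mates: int = 6
    n_genus_other: int = 6
    n_family_other: int = 8
    genes_per_genome: int = 30
    gene_length: int = 80
    p_species: float = 0.9
    p_genus: float = 0.75
    p_family: float = 0.5
    n_private_genes: int = 3
    homolog_divergence: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_species, self.p_genus, self.p_family):
            if not 0.0 <= p <= 1.0:
                raise SyntheticError(f"sharing probability {p} outside [0, 1]")
        for n in (self.n_species_mates, self.n_genus_other, self.n_family_other,
                  self.genes_per_genome, self.n_private_genes):
            if n < 0:
                raise SyntheticError("counts must be non-negative")


@dataclass(frozen=True)
class HgtEvent:
    """One planted transfer: donor genes into the recipient at a divergence."""

    donor_label: str
    gene_ids: tuple
    target_divergence: float
    recipient_accession: str

    def __post_init__(self):
        if not 0.0 <= self.target_divergence <= MAX_DIVERGENCE:
            raise SyntheticError(
                f"divergence {self.target_divergence} outside the emulated "
                f"range [0, {MAX_DIVERGENCE}]"
            )


@dataclass
class Universe:
    """A generated universe: taxonomy, proteomes, truth, coordinates."""

    config: UniverseConfig
    taxonomy: pd.DataFrame
    proteomes: dict           # accession -> {protein_id: sequence}
    query_accession: str
    query_genes: dict         # gene_id -> sequence (native + planted)
    truth: pd.DataFrame       # gene_id, truth_label, divergence, donor
    gene_coords: pd.DataFrame # gene_id, replicon, start, end
    islands: pd.DataFrame     # replicon, start, end, name
    markers: pd.DataFrame     # gene_id, family, e_value

    @property
    def planted_gene_ids(self) -> list:
        return self.truth.loc[self.truth.truth_label == "alien", "gene_id"].tolist()


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_sequence(seq: str, divergence_pct: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(L * d/100) positions, sampled w/o replacement."""
    n_sub = round(len(seq) * divergence_pct / 100.0)
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [a for a in AA20 if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _gene_layout(gene_ids: Sequence[str], replicon: str = "chr",
                 gene_span: int = 900, spacing: int = 1000) -> pd.DataFrame:
    rows = [
        {"gene_id": gid, "replicon": replicon,
         "start": i * spacing + 1, "end": i * spacing + gene_span}
        for i, gid in enumerate(gene_ids)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "replicon", "start", "end"])


def generate_universe(config: UniverseConfig) -> Universe:
    """Build the taxonomy, proteomes and truth labels of a native universe.

    Deterministic under ``config.seed``: identical configs yield identical
    universes (byte-identical once written).
    """
    rng = np.random.default_rng(config.seed)
    query = "QRY000"

    rows = [{"accession": query, "species_id": "sp_q", "genus_id": "ge_q",
             "family_id": "fa_q", "species_name": "Simulon queri",
             "genus_name": "Simulon", "family_name": "Simulaceae"}]
    relations = {}
    for i in range(config.n_species_mates):
        acc = f"SPM{i:03d}"
        rows.append({"accession": acc, "species_id": "sp_q", "genus_id": "ge_q",
                     "family_id": "fa_q", "species_name": "Simulon queri",
                     "genus_name": "Simulon", "family_name": "Simulaceae"})
        relations[acc] = "species"
    for i in range(config.n_genus_other):
        acc = f"GEN{i:03d}"
        rows.append({"accession": acc, "species_id": f"sp_g{i}", "genus_id": "ge_q",
                     "family_id": "fa_q", "species_name": f"Simulon alius{i}",
                     "genus_name": "Simulon", "family_name": "Simulaceae"})
        relations[acc] = "genus"
    for i in range(config.n_family_other):
        acc = f"FAM{i:03d}"
        rows.append({"accession": acc, "species_id": f"sp_f{i}", "genus_id": f"ge_f{i}",
                     "family_id": "fa_q", "species_name": f"Parasimulon sp{i}",
                     "genus_name": f"Parasimulon{i}", "family_name": "Simulaceae"})
        relations[acc] = "family"
    taxonomy = pd.DataFrame(rows)

    share_p = {"species": config.p_species, "genus": config.p_genus,
               "family": config.p_family}
    gene_ids = [f"gene{i:04d}" for i in range(config.genes_per_genome)]
    query_genes = {gid: random_protein(rng, config.gene_length) for gid in gene_ids}

    proteomes = {query: dict(query_genes)}
    for acc, relation in relations.items():
        proteome = {}
        p = share_p[relation]
        for gid, seq in query_genes.items():
            if rng.random() < p:
                proteome[f"{gid}_h"] = mutate_sequence(
                    seq, config.homolog_divergence, rng)
        for j in range(config.n_private_genes):
            proteome[f"priv{j}"] = random_protein(rng, config.gene_length)
        proteomes[acc] = proteome

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "truth_label": "native",
        "divergence": 0.0,
        "donor": "",
    })
    coords = _gene_layout(gene_ids)
    islands = pd.DataFrame(columns=["replicon", "start", "end", "name"])
    markers = pd.DataFrame(columns=["gene_id", "family", "e_value"])
    return Universe(config, taxonomy, proteomes, query, dict(query_genes),
                    truth, coords, islands, markers)


def plant_hgt(recipient_proteome: Mapping[str, str],
              donor_genes: Mapping[str, str],
              event: HgtEvent,
              rng: np.random.Generator) -> tuple[dict, pd.DataFrame]:
    """Transfer donor genes into a recipient proteome at the event divergence.

    Each donor sequence is mutated to exactly the target divergence (0 %
    keeps it identical) and appended under its gene id. Planting a gene id
    already resident in the recipient raises.
    """
    new_proteome = dict(recipient_proteome)
    rows = []
    for gid in event.gene_ids:
        if gid in new_proteome:
            raise SyntheticError(
                f"gene {gid!r} already present in recipient "
                f"{event.recipient_accession!r}"
            )
        if gid not in donor_genes:
            raise SyntheticError(f"donor gene {gid!r} unknown")
        new_proteome[gid] = mutate_sequence(donor_genes[gid],
                                            event.target_divergence, rng)
        rows.append({"gene_id": gid, "truth_label": "alien",
                     "divergence": event.target_divergence,
                     "donor": event.donor_label})
    return new_proteome, pd.DataFrame(rows)


def plant_transfer_series(universe: Universe,
                          divergences: Sequence[float] = (0, 5, 10, 15, 20, 25, 30),
                          genes_per_divergence: int = 3,
                          donor_label: str = "out_of_family_donor",
                          marker_fraction: float = 0.6,
                          seed: Optional[int] = None) -> tuple[Universe, list]:
    """Plant foreign genes into the query at each divergence step.

    Donor genes are fresh random proteins (guaranteed absent from every rank
    pool, emulating an out-of-family donor). The planted block is laid out
    as a contiguous synthetic island downstream of the native genes, and a
    fraction of planted genes receives mobile-element marker hits below the
    E-value cutoff. Returns a new Universe plus the event list.
    """
    cfg = universe.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    proteome = dict(universe.proteomes[universe.query_accession])
    query_genes = dict(universe.query_genes)
    truth = universe.truth.copy()
    events, planted_ids = [], []

    idx = 0
    for div in divergences:
        gids = []
        for _ in range(genes_per_divergence):
            gid = f"hgt{idx:04d}"
            idx += 1
            gids.append(gid)
        donors = {gid: random_protein(rng, cfg.gene_length) for gid in gids}
        event = HgtEvent(donor_label, tuple(gids), float(div),
                         universe.query_accession)
        proteome, new_truth = plant_hgt(proteome, donors, event, rng)
        for gid in gids:
            query_genes[gid] = proteome[gid]
        truth = pd.concat([truth, new_truth], ignore_index=True)
        events.append(event)
        planted_ids.extend(gids)

    all_ids = truth["gene_id"].tolist()
    coords = _gene_layout(all_ids)
    planted_coords = coords[coords.gene_id.isin(planted_ids)]
    islands = pd.DataFrame([{
        "replicon": "chr",
        "start": int(planted_coords.start.min()),
        "end": int(planted_coords.end.max()),
        "name": "synthetic_island_1",
    }]) if planted_ids else universe.islands

    marker_rows = []
    for gid in planted_ids:
        if rng.random() < marker_fraction:
            fam = MARKER_FAMILIES[rng.integers(len(MARKER_FAMILIES))]
            marker_rows.append({"gene_id": gid, "family": fam,
                                "e_value": float(10.0 ** -rng.integers(3, 10))})
    # weak, above-threshold hits on a couple of native genes
    for gid in truth.loc[truth.truth_label == "native", "gene_id"].head(2):
        marker_rows.append({"gene_id": gid, "family": MARKER_FAMILIES[0],
                            "e_value": 0.05})
    markers = pd.DataFrame(marker_rows, columns=["gene_id", "family", "e_value"])

    proteomes = dict(universe.proteomes)
    proteomes[universe.query_accession] = proteome
    planted = Universe(cfg, universe.taxonomy, proteomes,
                       universe.query_accession, query_genes, truth, coords,
                       islands, markers)
    return planted, events


def end_to_end_recovery(universe: Universe, thresholds=None,
                        min_t2_size: int = 5):
    """Run the full pipeline on a universe; score planted-gene recovery.

    Returns (ConfusionMatrix over planted-vs-native truth, classifications).
    """
    from .classifier import ClassificationThresholds
    from .homology import MockAlignmentBackend
    from .metrics import confusion
    from .pipeline import profile_and_classify

    thresholds = thresholds or ClassificationThresholds()
    index = load_taxonomy_index(universe.taxonomy)
    sets = compile_genome_sets(universe.query_accession, index, min_t2_size)
    backend = MockAlignmentBackend(proteomes=universe.proteomes)
    from .homology import QueryGene
    genes = [QueryGene(gid, seq, universe.query_accession)
             for gid, seq in universe.query_genes.items()]
    results = profile_and_classify(genes, sets, backend, thresholds=thresholds)
    predicted_alien = {r.gene_id for r in results if r.is_alien}
    truth_alien = set(universe.planted_gene_ids)
    cm = confusion(predicted_alien, truth_alien,
                   [g.gene_id for g in genes])
    return cm, results


# ---------------------------------------------------------------------------
# Writers (all outputs deterministic: sorted keys, fixed float formats)


def write_universe(universe: Universe, outdir) -> dict:
    """Emit the universe in the dialects the other modules consume.

    Writes taxonomy.tsv, per-genome FASTA under proteomes/, the query gene
    FASTA, truth.tsv, gene_coords.tsv, islands.tsv and markers.tsv; returns
    the path map. Taxonomy rows gain a proteome_ref column so the written
    universe is runnable by path alone.
    """
    outdir = Path(outdir)
    (outdir / "proteomes").mkdir(parents=True, exist_ok=True)
    paths = {}

    tax = universe.taxonomy.copy()
    refs = []
    for acc in tax["accession"]:
        fasta = outdir / "proteomes" / f"{acc}.faa"
        with open(fasta, "w") as fh:
            for pid in sorted(universe.proteomes[acc]):
                fh.write(f">{pid}\n{universe.proteomes[acc][pid]}\n")
        refs.append(str(fasta))
    tax["proteome_ref"] = refs
    paths["taxonomy"] = outdir / "taxonomy.tsv"
    tax.to_csv(paths["taxonomy"], sep="\t", index=False)

    paths["query_genes"] = outdir / "query_genes.faa"
    with open(paths["query_genes"], "w") as fh:
        for gid in universe.truth["gene_id"]:
            fh.write(f">{gid}\n{universe.query_genes[gid]}\n")

    for name, df in (("truth", universe.truth),
                     ("gene_coords", universe.gene_coords),
                     ("islands", universe.islands),
                     ("markers", universe.markers)):
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)
    return paths
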