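# Methods

## Model and assumptions

`phyletic` infers horizontal acquisition from the presence/absence
distribution of a gene's homologues across taxonomically defined genome
sets. The underlying assumptions are:

* **Parsimony between gain and loss.** A gene present in the query but
  absent from most close relatives is better explained by gain than by
  repeated independent loss. The alien bar is deliberately stringent
  (absence from more than 70 % of a rank's genomes is needed before a gene
  can be called alien there), so that plausible
  loss scenarios land in *ambiguous* rather than *alien*.
* **Rank structure as a clock proxy.** Sporadic distribution within the
  species set indicates a recent transfer; saturation of the species set
  combined with sporadic distribution in the genus-minus-species (T2) set
  indicates acquisition by the species group's common ancestor, and
  analogously one rank up. The T2 exclusion is what makes ancestral events
  visible: without it the query's own group would mask them.
* **Detectability decays with rank.** The identity cutoff for counting a
  homologue relaxes from 60 % (species) to 50 % (genus) to 25 % (family),
  and the native PDT bar relaxes from 70 % (genus) to 40 % (family), both
  absorbing sequence divergence and genuine gene turnover over longer
  evolutionary distances.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alien_pdt` | 30 % | below this PDT a gene is sporadic → alien |
| `species_well_distributed` | 80 % | above this the species set is saturated |
| `genus_native` | 70 % | native bar in the inclusive genus set |
| `family_native` | 40 % | native bar in the family sets |
| `min_query_coverage` | 70 % | alignment must span this much of the query |
| identity cutoffs | 60/50/25 % | per rank (species/genus/family) |
| `min_t2_size` | 5 genomes | below this a T2 set falls back to T1 |
| marker `e_cutoff` | 0.01 | HMMER E-value bound for marker genes |

All PDT comparisons are **strict** ("less than", "more than") on unrounded
percentages; a PDT exactly at a cutoff falls through to the next rule. Both
homology filters are **inclusive** (≥). These conventions are exercised
explicitly by boundary tests.

## Design choices where the design was open

* **Query self-exclusion.** The query genome is removed from every set;
  otherwise every gene would be trivially present via its self-hit and the
  species-level signal would be destroyed.
* **Branch-2 native test on the family T2 set.** The ancestral-acquisition
  branch tests alien status on T2 sets; its native test uses the same T2
  set for internal consistency. (The inclusive alternative is a one-line
  configuration change.)
* **Degenerate sets.** If the query is its species' only sequenced member,
  the species test is skipped and classification starts at the
  intermediate-band (genus T1) rules, flagged `species_skipped` in the
  report. The same fall-through applies if a higher rank's set is empty; a
  gene with no defined PDT at any rank is an error, not a silent label.
* **E-values do not gate presence.** The BLAST adapter applies its default
  reporting ceiling (1e-5, configurable) and the mock backend a deterministic
  transform of the alignment score, but presence is decided solely by the
  coverage and identity filters.
* **One search per run.** The backend is invoked once against the family
  T1 superset and hits are partitioned per rank before filtering. For the
  deterministic backends this is exactly equivalent to per-set searches; for
  real BLAST it fixes the database (and hence E-values) across ranks, which
  is harmless because E-values never gate presence.
* **Coverage definition.** Fraction of query residues aligned to a subject
  residue in the best single alignment (no HSP tiling), as a percentage of
  query length.
* **Gene↔island assignment** is by midpoint containment, each gene joining
  at most the first containing island in coordinate order. Island truth
  tables are 1-based inclusive; a flag converts BED-style input.
* **F(0, 0) = 0** by convention; report mode rounds metrics to integer
  percent, internal computation never rounds.
* **Hypergeometric tail.** Enrichment is the upper tail inclusive of the
  observed count, P[X ≥ k]; ambiguous genes belong to the population but
  never to the alien draw.

## The synthetic universe

The simulator emulates the study conditions end to end: a query genome, 6
species-mates, 6 further same-genus genomes and 8 further same-family
genomes; 30 native query genes of 80 aa; per-genome homologue carriage with
probability 0.9 / 0.75 / 0.5 at species / genus / family relation (chosen as
a desk-scale analogue of a well-sampled species whose native genes read
clearly native under the default thresholds); homolog copies drift by 2 %
so comparator proteomes are not byte-copies; 3 private genes per comparator.
Transfers are planted from out-of-family donors (fresh random proteins,
guaranteed absent from every rank pool) at 0, 5, …, 30 % protein divergence,
laid out as a contiguous synthetic island, with ~60 % of planted genes given
sub-threshold mobile-element marker hits.

Divergence is realised as exactly `round(L·d/100)` substitutions at
positions sampled without replacement, each to one of the 19 alternative
residues drawn uniformly. This is intentionally non-biological (no
substitution matrix, no nucleotide/codon model): it is the simplest
mechanism that hits an exact target identity, which is the only property
the classifier's filters see. Consequently, passing tests demonstrate the
correctness of the set compilation, filtering and decision logic under
controlled phyletic patterns — they do not demonstrate performance on real
proteomes, where alignment ambiguity, paralogy, partial genes and biased
taxon sampling add noise the simulator does not model.

Test and acceptance runs use this desk-scale universe (21 genomes, ~50
genes, 3 transfers per divergence step); the sizes are the package's own
defaults and complete the full pipeline in seconds.

## Numerical and degenerate-input conventions

* PDT of an empty set is *undefined* (`None`), never 0 or 100.
* Duplicate genome accessions, inconsistent species→genus/family parentage,
  hits referencing genomes outside the profiled set, and predicted genes
  outside the evaluation universe are hard errors.
* Islands with no member genes are excluded from island-level scoring with
  a warning; range bins are lower-inclusive half-open with a closed top bin
  (0–25, 25–50, 50–75, 75–100).
* The mock aligner uses BLOSUM62 with affine gaps (−11/−1), global mode;
  identity is identical columns over alignment columns. Everything it emits
  is deterministic, so fixed-seed runs are byte-reproducible.

## Limitations

* Only three ranks (species/genus/family) are modelled; transfers older
  than the family's ancestor are invisible by construction.
* Donor inference, transfer dating and explicit gene-loss modelling are out
  of scope.
* The marker database itself is user input (any HMMER domain-table output
  or a plain TSV); the package ships only a toy marker fixture generator.
* Live retrieval of genomes/taxonomy from NCBI is not implemented; the
  taxonomy TSV dialect is the ingestion boundary.
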