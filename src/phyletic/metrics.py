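"""Benchmarking against genomic-island truth: confusion, F-measure, islands.

Evaluation datasets list genomic islands (GIs) — contiguous clusters of
horizontally acquired genes — as coordinate intervals per replicon. Gene
predictions are scored against island membership: recall is the percentage
of island genes called alien, precision the percentage of alien calls that
are island genes, and the F-measure their harmonic mean. Genes the
classifier leaves ambiguous count as native for evaluation.

Island-level detection asks, per island, what fraction of its genes were
called alien; an island is detected at cutoff X when that fraction is X %
or more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (50.0, 75.0, 95.0)
RANGE_BINS = ("0-25", "25-50", "50-75", "75-100")


class MetricsError(ValueError):
    pass


@dataclass
class Island:
    """A genomic island: 1-based inclusive interval on a named replicon."""

    replicon: str
    start: int
    end: int
    name: str
    member_genes: list = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise MetricsError(
                f"island {self.name!r}: start {self.start} > end {self.end}"
            )


@dataclass
class ConfusionMatrix:
    """Gene-level confusion counts with recall/precision/F (percentages)."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else None

    @property
    def f_measure(self) -> Optional[float]:
        r, p = self.recall, self.precision
        if r is None or p is None:
            return None
        return f_measure(r, p)

    def rounded(self) -> dict:
        """Report-mode view with metrics rounded to integer percent."""
        def r(x):
            return None if x is None else round(x)
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "recall": r(self.recall), "precision": r(self.precision),
                "f_measure": r(self.f_measure)}


@dataclass
class IslandDetection:
    """Per-island alien fraction, detection flags per cutoff, range bin."""

    name: str
    n_genes: int
    n_alien: int
    fraction_alien: float
    detected_at: dict
    range_bin: str


def f_measure(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision (percent), F(0,0)=0 by convention."""
    for v, nm in ((recall, "recall"), (precision, "precision")):
        if not 0.0 <= v <= 100.0:
            raise MetricsError(f"{nm} {v} outside [0, 100]")
    if recall == 0.0 and precision == 0.0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def read_island_table(path: Union[str, Path], bed: bool = False) -> list[Island]:
    """Read an island truth TSV (replicon, start, end, name).

    Coordinates are 1-based inclusive; pass ``bed=True`` for 0-based
    half-open input, which is converted on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"replicon": str, "name": str})
    required = {"replicon", "start", "end", "name"}
    if not required.issubset(df.columns):
        raise MetricsError(
            f"island table {path} lacks columns {sorted(required - set(df.columns))}"
        )
    islands = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if bed:
            start, end = start + 1, end
        islands.append(Island(str(row.replicon), start, end, str(row.name)))
    return islands


def assign_genes_to_islands(gene_coords: pd.DataFrame,
                            islands: Sequence[Island]) -> list[Island]:
    """Assign genes to islands by midpoint containment.

    ``gene_coords`` needs columns gene_id, replicon, start, end (1-based
    inclusive). A gene joins the first island (islands ordered by replicon,
    start, end) whose interval contains the gene's midpoint; each gene joins
    at most one island, and genes on island-free replicons stay unassigned
    (non-island). Raises when islands and genes exist but share no replicon
    at all, listing the unmatched island replicons.
    """
    required = {"gene_id", "replicon", "start", "end"}
    if not required.issubset(gene_coords.columns):
        raise MetricsError(
            f"gene coordinates lack columns {sorted(required - set(gene_coords.columns))}"
        )
    islands = sorted(islands, key=lambda i: (i.replicon, i.start, i.end))
    for isl in islands:
        isl.member_genes = []
    if len(islands) and len(gene_coords):
        island_reps = {i.replicon for i in islands}
        gene_reps = set(gene_coords["replicon"].astype(str))
        if not island_reps & gene_reps:
            raise MetricsError(
                "no replicon shared between islands and gene coordinates; "
                f"unmatched island replicons: {sorted(island_reps)}"
            )
    by_rep: dict[str, list[Island]] = {}
    for isl in islands:
        by_rep.setdefault(isl.replicon, []).append(isl)
    for row in gene_coords.itertuples(index=False):
        mid = (int(row.start) + int(row.end)) / 2.0
        for isl in by_rep.get(str(row.replicon), []):
            if isl.start <= mid <= isl.end:
                isl.member_genes.append(str(row.gene_id))
                break
    return islands


def confusion(predicted_alien: Iterable[str], truth_island_genes: Iterable[str],
              all_genes: Iterable[str]) -> ConfusionMatrix:
    """Gene-level confusion of alien predictions vs island-membership truth.

    Callers map ambiguous labels to native *before* building
    ``predicted_alien`` (the evaluation convention). Predicted genes outside
    the gene universe raise.
    """
    universe = set(all_genes)
    predicted = set(predicted_alien)
    truth = set(truth_island_genes) & universe
    stray = predicted - universe
    if stray:
        raise MetricsError(f"predicted genes outside the universe: {sorted(stray)[:5]}")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _range_bin(fraction: float) -> str:
    # lower-inclusive half-open bins; top bin closed at 100
    if fraction < 25.0:
        return "0-25"
    if fraction < 50.0:
        return "25-50"
    if fraction < 75.0:
        return "50-75"
    return "75-100"


def island_detection(islands: Sequence[Island],
                     alien_gene_ids: Iterable[str],
                     cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
                     ) -> tuple[list[IslandDetection], dict, dict]:
    """Score island recovery at percentage cutoffs.

    Returns per-island detections, detected counts per cutoff (fraction of
    alien-called member genes >= cutoff, inclusive), and the histogram of
    islands over the 0-25/25-50/50-75/75-100 ranges. Islands without member
    genes are excluded with a warning.
    """
    alien = set(alien_gene_ids)
    detections = []
    for isl in islands:
        if not isl.member_genes:
            logger.warning("island %s has no member genes; excluded", isl.name)
            continue
        n = len(isl.member_genes)
        k = sum(1 for g in isl.member_genes if g in alien)
        frac = 100.0 * k / n
        detections.append(IslandDetection(
            name=isl.name, n_genes=n, n_alien=k, fraction_alien=frac,
            detected_at={c: frac >= c for c in cutoffs},
            range_bin=_range_bin(frac),
        ))
    detected_counts = {c: sum(d.detected_at[c] for d in detections) for c in cutoffs}
    histogram = {b: sum(1 for d in detections if d.range_bin == b) for b in RANGE_BINS}
    return detections, detected_counts, histogram


def detections_to_frame(detections: Sequence[IslandDetection]) -> pd.DataFrame:
    rows = []
    for d in detections:
        row = {"island": d.name, "n_genes": d.n_genes, "n_alien": d.n_alien,
               "fraction_alien": d.fraction_alien, "range_bin": d.range_bin}
        for c, flag in d.detected_at.items():
            row[f"detected_at_{c:g}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
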