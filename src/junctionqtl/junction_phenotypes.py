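"""Junction-level splicing phenotypes from classified RNA-seq reads.

A read is *spliced* at a junction when one of its between-block gaps matches
the intron exactly and the flanking blocks anchor in the donor and acceptor
exons; it is *unspliced* when a single block runs across the donor-side
exon|intron boundary.  From these tallies the module derives the phenotypes
used for splicing-QTL mapping:

* splicing-efficiency ratio  — spliced : unspliced reads per junction, a
  proxy for the rate constant of intron removal;
* intron-read percentage     — % of gene reads with any overlap of an intron;
* PSI                        — % of donor-informative spliced reads using the
  reference 5' donor rather than an annotated alternative donor;
* normalised expression      — median-of-ratios size factors + log2(x+1),
  with optional batch mean-centering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from junctionqtl.io_core import AlignedRead, GeneModel, Junction

logger = logging.getLogger(__name__)

SPLICED, UNSPLICED, OTHER = "spliced", "unspliced", "other"

#: default minimal overlap of the flanking exon(s), in bases
DEFAULT_MIN_ANCHOR = 1
#: default pseudocount for the efficiency ratio (0 gives the strict ratio)
DEFAULT_PSEUDOCOUNT = 0.5


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_read(
    read: AlignedRead,
    junction: Junction,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    both_boundaries: bool = False,
) -> str:
    """Classify one read at one junction as spliced / unspliced / other.

    Spliced: a between-block gap equals the intron exactly and the flanking
    blocks overlap the donor- and acceptor-side exons by >= ``min_anchor``
    bases.  Unspliced: a single block covers the donor-side exon|intron
    boundary with >= ``min_anchor`` bases on each side (``both_boundaries``
    additionally accepts acceptor-side crossings).  Everything else that
    touches the junction neighbourhood is "other".
    """
    s, e = junction.intron
    for i, gap in enumerate(read.gaps):
        if gap == (s, e):
            left, right = read.blocks[i], read.blocks[i + 1]
            if (left[1] - left[0]) >= min_anchor and (right[1] - right[0]) >= min_anchor:
                return SPLICED
    boundaries = [junction.donor_boundary]
    if both_boundaries:
        boundaries.append(junction.acceptor_boundary)
    for b in boundaries:
        for bs, be in read.blocks:
            if bs <= b - min_anchor and be >= b + min_anchor:
                return UNSPLICED
    return OTHER


def overlaps_junction_neighbourhood(read: AlignedRead, junction: Junction) -> bool:
    """True when any block touches the intron or its immediately flanking
    exonic base on either side (the region where classification applies)."""
    s, e = junction.intron
    return any(_overlap(b, (s - 1, e + 1)) > 0 for b in read.blocks)


@dataclass
class JunctionCountTable:
    """Per (sample, junction) tallies of spliced / unspliced / other reads.

    When the gene model carries an alternative donor, per-sample tallies of
    reference- and alternative-donor spliced reads are kept as well (PSI
    numerator/denominator).
    """

    junction_indices: list[int]
    counts: dict[str, dict[int, list[int]]] = field(default_factory=dict)
    donor_usage: dict[str, list[int]] = field(default_factory=dict)  # [n_ref, n_alt]

    def _row(self, sample: str, junction: int) -> list[int]:
        per_sample = self.counts.setdefault(sample, {j: [0, 0, 0] for j in self.junction_indices})
        return per_sample[junction]

    def add(self, sample: str, junction: int, cls: str) -> None:
        self._row(sample, junction)[[SPLICED, UNSPLICED, OTHER].index(cls)] += 1

    def add_donor(self, sample: str, reference: bool) -> None:
        row = self.donor_usage.setdefault(sample, [0, 0])
        row[0 if reference else 1] += 1

    def get(self, sample: str, junction: int) -> tuple[int, int, int]:
        return tuple(self.counts.get(sample, {}).get(junction, [0, 0, 0]))

    @property
    def samples(self) -> list[str]:
        return sorted(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for j in self.junction_indices:
                n_sp, n_un, n_ot = self.get(s, j)
                rows.append((s, j, n_sp, n_un, n_ot))
        return pd.DataFrame(rows, columns=["sample", "junction", "n_spliced", "n_unspliced", "n_other"])


def count_junctions(
    reads: Iterable[AlignedRead],
    model: GeneModel,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    both_boundaries: bool = False,
) -> JunctionCountTable:
    """Tally spliced/unspliced/other reads at every junction of the model.

    A read contributes at most once per junction but may contribute to
    several junctions (e.g. a read with two exact splice gaps is spliced at
    both).  Reads on other chromosomes are ignored.  When the model has an
    alternative donor event, reads spliced at the reference or alternative
    form of that junction are also tallied for PSI.
    """
    junctions = model.junctions()
    table = JunctionCountTable(junction_indices=[j.index for j in junctions])
    alt_j = model.alt_donor_junction() if model.alt_donor is not None else None
    ref_j = model.reference_donor_junction() if model.alt_donor is not None else None
    n_reads = 0
    for read in reads:
        if read.chrom != model.chrom:
            continue
        n_reads += 1
        for junction in junctions:
            if not overlaps_junction_neighbourhood(read, junction):
                continue
            table.add(read.sample_id, junction.index, classify_read(read, junction, min_anchor, both_boundaries))
        if alt_j is not None:
            if classify_read(read, ref_j, min_anchor) == SPLICED:
                table.add_donor(read.sample_id, reference=True)
            elif classify_read(read, alt_j, min_anchor) == SPLICED:
                table.add_donor(read.sample_id, reference=False)
    if n_reads == 0:
        logger.warning("count_junctions: empty read stream for gene %s", model.gene_id)
    else:
        logger.debug("count_junctions: classified %d reads at %d junctions", n_reads, len(junctions))
    return table


def efficiency_ratio(
    n_spliced: int | float,
    n_unspliced: int | float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Splicing-efficiency ratio (spliced + c) / (unspliced + c).

    With ``pseudocount`` 0 and no unspliced reads the strict ratio is
    undefined and NaN is returned.
    """
    if n_spliced < 0 or n_unspliced < 0:
        raise ValueError("read counts must be non-negative")
    denom = n_unspliced + pseudocount
    if denom == 0:
        return math.nan
    return (n_spliced + pseudocount) / denom


def intron_read_pct(
    reads: Iterable[AlignedRead], model: GeneModel, intron_index: int
) -> float:
    """Percentage of gene-overlapping reads with >= 1 base in the intron.

    ``intron_index`` is the 1-based junction number in transcription order.
    NaN when no read overlaps the gene span.
    """
    intron = model.junction(intron_index).intron
    gene_span = model.span
    n_gene = n_intron = 0
    for read in reads:
        if read.chrom != model.chrom:
            continue
        if any(_overlap(b, gene_span) for b in read.blocks):
            n_gene += 1
            if any(_overlap(b, intron) for b in read.blocks):
                n_intron += 1
    if n_gene == 0:
        return math.nan
    return 100.0 * n_intron / n_gene


def compute_psi(n_ref_spliced: int | float, n_alt_spliced: int | float) -> float:
    """Percent spliced-in of the reference donor form.

    100 x n_ref / (n_ref + n_alt); NaN when no informative spliced read.
    """
    if n_ref_spliced < 0 or n_alt_spliced < 0:
        raise ValueError("read counts must be non-negative")
    total = n_ref_spliced + n_alt_spliced
    if total == 0:
        return math.nan
    return 100.0 * n_ref_spliced / total


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (samples x genes count matrix).

    Genes with a zero count in any sample are excluded from the per-gene
    geometric means (and hence from the medians); if every gene is excluded
    all size factors are 1.
    """
    counts = np.asarray(counts, dtype=float)
    keep = (counts > 0).all(axis=0)
    if not keep.any():
        return np.ones(counts.shape[0])
    logc = np.log(counts[:, keep])
    log_geomean = logc.mean(axis=0)
    return np.exp(np.median(logc - log_geomean, axis=1))


def normalize_expression(
    counts: np.ndarray,
    batch: Iterable | None = None,
) -> np.ndarray:
    """Variance-stabilised expression: log2(count / size_factor + 1).

    Size factors come from the median-of-ratios method; a single sample gets
    size factor 1, and a single-gene matrix keeps unit size factors as well
    (depth cannot be separated from expression with one gene).  When
    ``batch`` labels are supplied, each batch is mean-centred to the grand
    mean per gene (a simple location adjustment for batch effects).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        sf = np.ones(counts.shape[0])
    else:
        sf = median_of_ratios_size_factors(counts)
    values = np.log2(counts / sf[:, None] + 1.0)
    if batch is not None:
        batch = np.asarray(list(batch))
        grand = values.mean(axis=0)
        for b in np.unique(batch):
            mask = batch == b
            values[mask] += grand - values[mask].mean(axis=0)
    return values


def build_phenotype_table(
    reads_by_sample: dict[str, list[AlignedRead]],
    model: GeneModel,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    batch: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full per-sample phenotype table for one gene.

    Columns: ``psi`` (if an alternative donor is annotated), ``eff_<j>`` and
    ``intronpct_<j>`` per junction, and ``expr_norm`` (normalised read count
    over the gene span).
    """
    table = count_junctions(
        (r for reads in reads_by_sample.values() for r in reads), model, min_anchor
    )
    samples = sorted(reads_by_sample)
    rows = {}
    gene_counts = []
    for s in samples:
        row: dict[str, float] = {}
        if model.alt_donor is not None:
            n_ref, n_alt = table.donor_usage.get(s, (0, 0))
            row["psi"] = compute_psi(n_ref, n_alt)
        for j in table.junction_indices:
            n_sp, n_un, _ = table.get(s, j)
            row[f"eff_{j}"] = efficiency_ratio(n_sp, n_un, pseudocount)
            row[f"intronpct_{j}"] = intron_read_pct(reads_by_sample[s], model, j)
        gene_counts.append(
            sum(
                1
                for r in reads_by_sample[s]
                if r.chrom == model.chrom and any(_overlap(b, model.span) for b in r.blocks)
            )
        )
        rows[s] = row
    expr = normalize_expression(
        np.array(gene_counts, dtype=float)[:, None],
        batch=[batch[s] for s in samples] if batch else None,
    )[:, 0]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    df["expr_norm"] = expr
    return df
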