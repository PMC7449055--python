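"""Readers/writers for the standard genomics formats and shared coordinate rules.

All external formats keep their native conventions (GTF/VCF/FASTA 1-based
inclusive, BED 0-based half-open).  Internally every interval is 0-based
half-open; conversion happens exactly once, at the file boundary.  Junction
donor/acceptor roles follow the gene-model strand: on the minus strand,
transcription order is reversed genomic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils
import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

# Alignment gaps at least this long are treated as splices (skipped introns);
# shorter gaps are deletions and do not split aligned blocks.  Matches the
# conventional aligner minimum intron size.
MIN_INTRON_GAP = 20


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_1based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


@dataclass(frozen=True)
class Junction:
    """One intron of a gene model, in transcription order.

    ``index`` is the 1-based intron number in transcription order (intron 1
    follows exon 1).  ``donor_exon_end`` / ``acceptor_exon_start`` are the
    internal (0-based half-open) boundary coordinates of the flanking exons:
    on the plus strand the donor boundary is the intron start, on the minus
    strand it is the intron end.
    """

    index: int
    intron: tuple[int, int]  # 0-based half-open
    strand: str

    def __post_init__(self):
        if self.intron[1] - self.intron[0] < 1:
            raise ValueError(f"intron interval must have length >= 1: {self.intron}")

    @property
    def donor_boundary(self) -> int:
        """Internal coordinate of the exon|intron boundary on the donor (5') side."""
        return self.intron[0] if self.strand == "+" else self.intron[1]

    @property
    def acceptor_boundary(self) -> int:
        return self.intron[1] if self.strand == "+" else self.intron[0]

    @property
    def intron_1based(self) -> tuple[int, int]:
        return to_1based(*self.intron)


@dataclass(frozen=True)
class AltDonorEvent:
    """An alternative 5' splice-donor event inside one exon.

    ``alt_exon`` and ``ref_exon`` are internal half-open intervals: the
    alternative donor truncates the exon so that the ``ref_exon`` span is
    spliced out ("intronified") in the alternative isoform.  When the removed
    span is a multiple of three the event deletes ``removed_codons`` codons
    in frame; otherwise it is a frameshift.
    """

    exon_index: int  # 1-based exon number (transcription order) carrying the event
    alt_exon: tuple[int, int]
    ref_exon: tuple[int, int]

    @property
    def removed_span(self) -> int:
        """Bases of the reference span absent from the alternative exon."""
        ref_len = self.ref_exon[1] - self.ref_exon[0]
        overlap = max(
            0,
            min(self.ref_exon[1], self.alt_exon[1]) - max(self.ref_exon[0], self.alt_exon[0]),
        )
        return ref_len - overlap

    @property
    def removed_codons(self) -> int | None:
        return self.removed_span // 3 if self.removed_span % 3 == 0 else None

    @property
    def frameshift(self) -> bool:
        return self.removed_span % 3 != 0


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one gene (exon union across transcripts).

    ``exons`` are 0-based half-open genomic intervals sorted by start and
    non-overlapping; ``introns`` are exactly the gaps between consecutive
    exons.  Use :meth:`from_1based` when constructing from GTF-style
    coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    alt_donor: AltDonorEvent | None = field(default=None)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -: {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model requires at least one exon")
        exons = tuple(sorted((tuple(e) for e in self.exons)))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons: {(s1, e1)} and {(s2, e2)}")
        object.__setattr__(self, "exons", exons)

    @classmethod
    def from_1based(
        cls, gene_id: str, chrom: str, strand: str, exons_1based, **kw
    ) -> "GeneModel":
        return cls(gene_id, chrom, strand, tuple(to_internal(s, e) for s, e in exons_1based), **kw)

    @property
    def exons_1based(self) -> tuple[tuple[int, int], ...]:
        return tuple(to_1based(s, e) for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order, 0-based half-open."""
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    @property
    def introns_1based(self) -> tuple[tuple[int, int], ...]:
        return tuple(to_1based(s, e) for s, e in self.introns)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def n_junctions(self) -> int:
        return len(self.exons) - 1

    def junctions(self) -> tuple[Junction, ...]:
        """Introns as junctions numbered in transcription order.

        On the minus strand intron 1 is the right-most genomic gap.
        """
        introns = self.introns
        order = range(len(introns)) if self.strand == "+" else range(len(introns) - 1, -1, -1)
        return tuple(
            Junction(index=i + 1, intron=introns[g], strand=self.strand)
            for i, g in enumerate(order)
        )

    def junction(self, index: int) -> Junction:
        for j in self.junctions():
            if j.index == index:
                return j
        raise KeyError(f"gene {self.gene_id} has no junction {index}")

    def alt_donor_junction(self) -> Junction:
        """The junction formed by the alternative donor (same acceptor as the
        reference junction downstream of the carrying exon)."""
        if self.alt_donor is None:
            raise ValueError("gene model has no alternative donor event")
        ref_j = self.reference_donor_junction()
        if self.strand == "+":
            intron = (self.alt_donor.alt_exon[1], ref_j.intron[1])
        else:
            intron = (ref_j.intron[0], self.alt_donor.alt_exon[0])
        return Junction(index=ref_j.index, intron=intron, strand=self.strand)

    def reference_donor_junction(self) -> Junction:
        """The reference-form junction downstream of the exon carrying the
        alternative donor event (transcription order)."""
        if self.alt_donor is None:
            raise ValueError("gene model has no alternative donor event")
        return self.junction(self.alt_donor.exon_index)


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read reduced to its reference blocks.

    ``blocks`` are sorted, non-overlapping 0-based half-open intervals; gaps
    between consecutive blocks are skipped reference, i.e. splices.
    """

    sample_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("read requires at least one block")
        blocks = tuple(tuple(b) for b in self.blocks)
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise ValueError(f"blocks out of order or overlapping: {blocks}")
        object.__setattr__(self, "blocks", blocks)

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]))

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class VariantSpec:
    """A same-length substitution variant (SNP or MNP such as AA>GC)."""

    chrom: str
    pos: int  # 1-based start
    ref: str
    alt: str

    def __post_init__(self):
        if len(self.ref) != len(self.alt) or len(self.ref) < 1:
            raise ValueError(
                f"only same-length substitutions supported: {self.ref}>{self.alt}"
            )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span, 0-based half-open."""
        return self.pos - 1, self.pos - 1 + len(self.ref)


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with marker metadata.

    ``dosage[i, j]`` is the count of alternative alleles (0/1/2) of sample i
    at marker j; missing genotypes are NaN.
    """

    sample_ids: list[str]
    markers: list[tuple[str, str, int, str, str]]  # (id, chrom, pos_1based, ref, alt)
    dosage: "np.ndarray"

    def __post_init__(self):
        import numpy as np

        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )

    @property
    def marker_ids(self) -> list[str]:
        return [m[0] for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in genotype matrix") from None

    def dosages_of(self, marker_id: str):
        return self.dosage[:, self.marker_index(marker_id)]


class GeneNotFoundError(KeyError):
    pass


def _gene_model_from_gtf(path: str, gene_id: str) -> GeneModel:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons = []
    strand = None
    chrom = None
    for feat in db.features_of_type("exon"):
        ids = feat.attributes.get("gene_id", []) + feat.attributes.get("Parent", [])
        if gene_id not in ids and feat.attributes.get("gene_id", [None])[0] != gene_id:
            continue
        exons.append(to_internal(feat.start, feat.end))
        strand, chrom = feat.strand, feat.seqid
    if not exons:
        raise GeneNotFoundError(f"gene {gene_id!r} not found in {path}")
    merged = merge_intervals(exons)
    if len(merged) != len(exons):
        logger.warning(
            "gene %s: %d exon records merged into %d union exons "
            "(overlapping transcripts)", gene_id, len(exons), len(merged)
        )
    return GeneModel(gene_id, chrom, strand if strand in "+-" else "+", tuple(merged))


def _gene_model_from_bed12(path: str, gene_id: str) -> GeneModel:
    # BED12 is a fixed 12-column line format; no installed library exposes the
    # block fields directly, so the columns are split here (0-based half-open).
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"not a BED12 line ({len(f)} columns): {line!r}")
            if f[3] != gene_id:
                continue
            chrom, chrom_start, strand = f[0], int(f[1]), f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ValueError(f"blockCount mismatch in BED12 record {f[3]}")
            exons = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            return GeneModel(gene_id, chrom, strand if strand in "+-" else "+", tuple(exons))
    raise GeneNotFoundError(f"gene {gene_id!r} not found in {path}")


def read_gene_model(path: str, gene_id: str) -> GeneModel:
    """Read one gene's exon/intron structure from a GTF/GFF3 or BED12 file.

    Exons from multiple transcripts are merged into their union (with a
    logged warning); introns are derived as the gaps between union exons.
    """
    p = str(path)
    if p.endswith((".bed", ".bed12")):
        return _gene_model_from_bed12(p, gene_id)
    return _gene_model_from_gtf(p, gene_id)


def write_gene_model_gtf(model: GeneModel, path: str) -> None:
    """Write a gene model as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(model.exons_1based, 1):
            attrs = f'gene_id "{model.gene_id}"; transcript_id "{model.gene_id}.t1"; exon_number "{i}";'
            fh.write(
                f"{model.chrom}\tjunctionqtl\texon\t{s}\t{e}\t.\t{model.strand}\t.\t{attrs}\n"
            )


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals (touching intervals are merged)."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def add_alternative_donor(
    model: GeneModel,
    alt_exon_1based: tuple[int, int],
    ref_exon_1based: tuple[int, int],
) -> GeneModel:
    """Annotate an alternative 5' donor inside one exon of the model.

    ``alt_exon`` is the truncated form of the exon; ``ref_exon`` is the span
    present only in the reference isoform (spliced out of the alternative
    isoform).  In transcription order the alternative donor lies upstream of
    the reference span; both must fall inside a single existing exon.
    """
    alt = to_internal(*alt_exon_1based)
    ref = to_internal(*ref_exon_1based)
    host = None
    for idx, (s, e) in enumerate(model.exons):
        if alt[0] >= s and alt[1] <= e and ref[0] >= s and ref[1] <= e:
            host = idx
            break
    if host is None:
        raise ValueError(
            f"alternative/reference intervals {alt_exon_1based}/{ref_exon_1based} "
            f"are not contained in a single exon of {model.gene_id}"
        )
    # transcription-order check: alt donor upstream of the removed span
    if model.strand == "+":
        upstream_ok = alt[1] <= ref[0]
    else:
        upstream_ok = alt[0] >= ref[1]
    if not upstream_ok and alt != ref:
        raise ValueError("alternative exon must end upstream of the reference span")
    # exon numbering in transcription order
    exon_number = host + 1 if model.strand == "+" else len(model.exons) - host
    event = AltDonorEvent(exon_index=exon_number, alt_exon=alt, ref_exon=ref)
    if event.frameshift:
        logger.warning(
            "alternative donor removes %d bp (not a codon multiple): frameshift",
            event.removed_span,
        )
    return replace(model, alt_donor=event)


def _segment_to_read(seg: pysam.AlignedSegment, min_intron: int) -> AlignedRead:
    blocks: list[list[int]] = []
    for s, e in seg.get_blocks():
        if blocks and s - blocks[-1][1] < min_intron:
            blocks[-1][1] = e  # short deletion: do not split
        else:
            blocks.append([s, e])
    return AlignedRead(
        sample_id=seg.get_tag("RG") if seg.has_tag("RG") else (seg.query_name or ""),
        chrom=seg.reference_name,
        blocks=tuple(tuple(b) for b in blocks),
    )


def read_alignments(
    path: str,
    region: tuple[str, int, int] | None = None,
    sample_id: str | None = None,
    min_intron: int = MIN_INTRON_GAP,
    exclude_flags: int = 0x4 | 0x100 | 0x400,  # unmapped, secondary, duplicate
):
    """Stream :class:`AlignedRead` records from a SAM/BAM file.

    ``region`` is (chrom, start, end) in 1-based inclusive coordinates and
    requires an index for BAM input.  Reference gaps >= ``min_intron`` split
    blocks (splices); shorter gaps (deletions) do not.  Records matching
    ``exclude_flags`` (default: unmapped, secondary, duplicate) are skipped.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        if region is not None:
            chrom, s1, e1 = region
            s0, e0 = to_internal(s1, e1)
            it = af.fetch(chrom, s0, e0) if af.has_index() else (
                r for r in af
                if not r.is_unmapped and r.reference_name == chrom
                and r.reference_start < e0 and r.reference_end > s0
            )
        else:
            it = af
        n_skipped = 0
        for seg in it:
            if seg.flag & exclude_flags:
                n_skipped += 1
                continue
            read = _segment_to_read(seg, min_intron)
            if sample_id is not None:
                read = replace(read, sample_id=sample_id)
            yield read
        if n_skipped:
            logger.debug("%s: skipped %d reads by flag filter 0x%x", path, n_skipped, exclude_flags)


def read_genotypes(
    path: str,
    region: tuple[str, int, int] | None = None,
    skip_multiallelic: bool = True,
) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (count of alternative alleles).

    Missing or malformed GT fields become NaN (counted and logged);
    multiallelic records are skipped with a warning by default.
    """
    import numpy as np

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        markers, rows = [], []
        n_missing = n_multi = 0
        if region is not None:
            chrom, s1, e1 = region
            try:
                it = vf.fetch(chrom, s1 - 1, e1)
            except ValueError:
                it = (r for r in vf if r.chrom == chrom and s1 <= r.pos <= e1)
        else:
            it = vf
        for rec in it:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                continue
            row = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    n_missing += 1
                    continue
                row[i] = sum(1 for a in gt if a == 1)
            markers.append((rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos, rec.ref, alts[0]))
            rows.append(row)
    if n_multi:
        level = logger.warning if skip_multiallelic else logger.error
        level("%s: skipped %d multiallelic records", path, n_multi)
    if n_missing:
        logger.info("%s: %d missing genotype calls set to NaN", path, n_missing)
    dosage = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(sample_ids=samples, markers=markers, dosage=dosage)


def read_fasta_region(path: str, chrom: str, start: int, end: int) -> str:
    """Uppercase sequence of ``chrom:start-end`` (1-based inclusive)."""
    if end < start:
        raise ValueError(f"end < start: {chrom}:{start}-{end}")
    fa = Fasta(str(path), sequence_always_upper=True)
    if chrom not in fa:
        raise KeyError(f"contig {chrom!r} not in {path}")
    clen = len(fa[chrom])
    if start < 1 or end > clen:
        raise ValueError(
            f"{chrom}:{start}-{end} outside contig bounds (length {clen})"
        )
    return str(fa[chrom][start - 1 : end])
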