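"""Exonic splice enhancer (ESE) hexamer scanning and allele-specific deltas.

An ESE panel is a set of 6-mers (e.g. the published RESCUE-ESE vertebrate
panel); scanning slides a 6-base window over a sequence and reports every
window found in the panel.  For a substitution variant, the module compares
the hits overlapping the variant between the two alleles and reports motifs
destroyed or created by the substitution — e.g. a dinucleotide change that
removes the enhancer hexamers only encoded by one allele.

Scanning is strand-naive: it operates on the sequence as given.  To scan the
other strand, pass the reverse complement explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from junctionqtl.io_core import VariantSpec

_VALID = set("ACGT")


@dataclass(frozen=True)
class ESEHit:
    """One panel hexamer found in a scanned sequence.

    ``start`` is the 0-based offset in the scanned sequence;
    ``genomic_start`` the 1-based genomic position when the sequence origin
    is known; ``overlaps_variant`` is set by :func:`variant_motif_delta`.
    """

    motif: str
    start: int
    genomic_start: int | None = None
    overlaps_variant: bool = False


def load_panel(path) -> frozenset[str]:
    """Read a hexamer panel: one 6-mer per line, '#' starts a comment."""
    panel = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            motif = line.split("#", 1)[0].strip().upper()
            if not motif:
                continue
            if len(motif) != 6 or not set(motif) <= _VALID:
                raise ValueError(f"{path}:{lineno}: not a valid hexamer: {motif!r}")
            panel.add(motif)
    return frozenset(panel)


def default_panel() -> frozenset[str]:
    """The packaged fixture panel (a subset of published human ESE hexamers)."""
    with resources.as_file(
        resources.files("junctionqtl.data") / "ese_fixture_panel.txt"
    ) as p:
        return load_panel(p)


def scan_ese(
    sequence: str,
    panel: frozenset[str] | set[str],
    genomic_offset: int | None = None,
) -> list[ESEHit]:
    """All panel hexamers in ``sequence``, sorted by offset.

    Windows containing N (or any non-ACGT base) never match.  When
    ``genomic_offset`` (1-based position of the first base) is given, hits
    carry genomic coordinates.
    """
    seq = sequence.upper()
    hits = []
    for i in range(len(seq) - 5):
        window = seq[i : i + 6]
        if window in panel and set(window) <= _VALID:
            hits.append(
                ESEHit(
                    motif=window,
                    start=i,
                    genomic_start=None if genomic_offset is None else genomic_offset + i,
                )
            )
    return hits


def apply_variant(sequence: str, offset: int, ref: str, alt: str) -> str:
    """Replace the ``ref`` allele at 0-based ``offset`` with ``alt``.

    Only same-length substitutions are supported; the observed sequence must
    match ``ref`` at the offset.
    """
    if len(ref) != len(alt):
        raise ValueError(f"indels not supported: {ref}>{alt}")
    observed = sequence[offset : offset + len(ref)].upper()
    if observed != ref.upper():
        raise ValueError(
            f"reference allele mismatch at offset {offset}: "
            f"expected {ref!r}, observed {observed!r}"
        )
    return sequence[:offset] + alt.upper() + sequence[offset + len(ref) :]


def _overlapping(hits: list[ESEHit], span: tuple[int, int]) -> list[ESEHit]:
    """Hits whose 6-base window intersects the half-open offset span."""
    out = []
    for h in hits:
        if h.start < span[1] and h.start + 6 > span[0]:
            out.append(
                ESEHit(h.motif, h.start, h.genomic_start, overlaps_variant=True)
            )
    return out


def variant_motif_delta(
    sequence_ref_allele: str,
    variant: VariantSpec | tuple[int, str, str],
    panel: frozenset[str] | set[str],
    genomic_offset: int | None = None,
) -> tuple[list[ESEHit], list[ESEHit], dict[str, int]]:
    """Panel motifs destroyed / created by a substitution variant.

    ``variant`` is either a :class:`VariantSpec` (requires
    ``genomic_offset``, the 1-based position of the first sequence base) or
    a tuple ``(offset, ref, alt)`` with a 0-based sequence offset.  Only
    hits whose window intersects the variant span are compared.  Returns
    ``(hits_lost, hits_gained, counts)`` where counts maps each allele to
    its number of variant-overlapping hits.
    """
    if isinstance(variant, VariantSpec):
        if genomic_offset is None:
            raise ValueError("genomic_offset required with a VariantSpec")
        offset = variant.pos - genomic_offset
        ref, alt = variant.ref, variant.alt
    else:
        offset, ref, alt = variant
    span = (offset, offset + len(ref))
    seq_alt = apply_variant(sequence_ref_allele, offset, ref, alt)
    hits_ref = _overlapping(scan_ese(sequence_ref_allele, panel, genomic_offset), span)
    hits_alt = _overlapping(scan_ese(seq_alt, panel, genomic_offset), span)
    key = lambda h: (h.start, h.motif)
    ref_keys = {key(h) for h in hits_ref}
    alt_keys = {key(h) for h in hits_alt}
    lost = [h for h in hits_ref if key(h) not in alt_keys]
    gained = [h for h in hits_alt if key(h) not in ref_keys]
    counts = {"ref": len(hits_ref), "alt": len(hits_alt)}
    return lost, gained, counts
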