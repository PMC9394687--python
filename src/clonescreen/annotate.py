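"""Codon-resolution coding consequences of variants on transcripts.

Maps each variant onto one canonical transcript per gene, translating
reference and alternate codons with the standard genetic code
(strand-aware), so that non-coding mutations can be excluded from the
somatic sets and codon-level recurrence (the same codon of a gene hit
in independent clones) can be computed.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from enum import Enum
from functools import cached_property
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import ReferenceMismatchError, ValidationError
from .variant_io import VariantKey

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One amino-acid letter ('*' for stop) for a 3-base codon."""
    return str(Seq(codon).translate())


class Consequence(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    NONCODING = "noncoding"


#: consequence classes that place a variant inside the coding sequence
CODING_CLASSES = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.SYNONYMOUS,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.INFRAME_INDEL,
    }
)

#: intronic bases on each side of a CDS exon counted as splice region
SPLICE_FLANK = 2


@dataclass(frozen=True)
class Transcript:
    """One canonical transcript: ordered CDS intervals on one chromosome.

    ``cds_intervals`` are 0-based half-open genomic intervals sorted by
    position regardless of strand; transcription order is derived from
    ``strand``. Total CDS length must be a multiple of 3.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        if not self.cds_intervals:
            raise ValidationError(f"transcript {self.transcript_id}: no CDS intervals")
        prev_end = None
        for start, end in self.cds_intervals:
            if end <= start:
                raise ValidationError(
                    f"transcript {self.transcript_id}: empty or inverted CDS "
                    f"interval [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS intervals overlap or unsorted"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"transcript {self.transcript_id}: CDS length {self.cds_length} "
                "not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    @cached_property
    def _starts(self) -> list[int]:
        return [s for s, _ in self.cds_intervals]

    @cached_property
    def _cum_lengths(self) -> list[int]:
        """Cumulative CDS length before each interval (genomic order)."""
        out, total = [], 0
        for start, end in self.cds_intervals:
            out.append(total)
            total += end - start
        return out

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        """Spliced CDS in transcription order (reverse-complemented for -)."""
        chrom_seq = reference[self.chrom]
        plus = "".join(chrom_seq[s:e] for s, e in self.cds_intervals)
        return reverse_complement(plus) if self.strand == "-" else plus

    def genomic_position(self, offset: int) -> int:
        """Genomic 0-based position of CDS ``offset`` (transcription order)."""
        if not 0 <= offset < self.cds_length:
            raise IndexError(f"CDS offset {offset} out of range")
        plus_offset = offset if self.strand == "+" else self.cds_length - 1 - offset
        i = bisect.bisect_right(self._cum_lengths, plus_offset) - 1
        start, _ = self.cds_intervals[i]
        return start + (plus_offset - self._cum_lengths[i])


def cds_offset(transcript: Transcript, pos: int) -> int | None:
    """0-based CDS offset (transcription direction) of genomic 0-based ``pos``.

    Returns ``None`` for positions outside the CDS (introns, flanks).
    """
    i = bisect.bisect_right(transcript._starts, pos) - 1
    if i < 0:
        return None
    start, end = transcript.cds_intervals[i]
    if pos >= end:
        return None
    plus_offset = transcript._cum_lengths[i] + (pos - start)
    if transcript.strand == "+":
        return plus_offset
    return transcript.cds_length - 1 - plus_offset


def _in_splice_region(transcript: Transcript, pos: int) -> bool:
    """True if ``pos`` lies within SPLICE_FLANK intronic bases of a CDS edge.

    Flanks at the transcript's outer boundaries count too; with a
    single-exon model there is no donor/acceptor distinction to make.
    """
    for start, end in transcript.cds_intervals:
        if start - SPLICE_FLANK <= pos < start or end <= pos < end + SPLICE_FLANK:
            return True
    return False


def classify(
    variant: VariantKey,
    transcript: Transcript,
    reference: Mapping[str, str],
) -> "CodingConsequence":
    """Coding consequence of a normalized variant on one transcript.

    SNVs are assigned a 1-based codon index (offset // 3 + 1) and
    ref/alt amino acids from strand-aware codon translation. Indels are
    frameshift when the length change is not a multiple of 3, inframe
    otherwise, attributed to the first affected codon; indels spanning
    a CDS/intron boundary are frameshift with a warning. SNVs within
    2 intronic bases of a CDS edge are splice; everything else outside
    the CDS is noncoding.
    """
    chrom_seq = reference.get(transcript.chrom)
    if chrom_seq is None:
        raise ReferenceMismatchError(f"chromosome {transcript.chrom} not in reference")
    pos0 = variant.pos - 1
    ref_in_genome = chrom_seq[pos0 : pos0 + len(variant.ref)]
    if ref_in_genome != variant.ref:
        raise ReferenceMismatchError(
            f"reference has {ref_in_genome!r} at {variant.chrom}:{variant.pos}, "
            f"variant REF is {variant.ref!r}"
        )

    if variant.is_snv:
        return _classify_snv(variant, transcript, chrom_seq, pos0)
    return _classify_indel(variant, transcript, pos0)


def _classify_snv(
    variant: VariantKey, transcript: Transcript, chrom_seq: str, pos0: int
) -> "CodingConsequence":
    offset = cds_offset(transcript, pos0)
    if offset is None:
        cls = (
            Consequence.SPLICE
            if _in_splice_region(transcript, pos0)
            else Consequence.NONCODING
        )
        return CodingConsequence(
            gene=transcript.gene, transcript_id=transcript.transcript_id,
            codon_index=None, ref_aa=None, alt_aa=None, consequence_class=cls,
        )
    codon_index = offset // 3 + 1
    within = offset % 3
    codon_start = offset - within
    ref_codon = "".join(
        chrom_seq[transcript.genomic_position(codon_start + k)] for k in range(3)
    )
    alt_base = variant.alt
    if transcript.strand == "-":
        ref_codon = "".join(b.translate(_COMPLEMENT) for b in ref_codon)
        alt_base = alt_base.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        cls = Consequence.SYNONYMOUS
    elif alt_aa == "*":
        cls = Consequence.NONSENSE
    else:
        cls = Consequence.MISSENSE
    return CodingConsequence(
        gene=transcript.gene, transcript_id=transcript.transcript_id,
        codon_index=codon_index, ref_aa=ref_aa, alt_aa=alt_aa, consequence_class=cls,
    )


def _classify_indel(
    variant: VariantKey, transcript: Transcript, pos0: int
) -> "CodingConsequence":
    delta = len(variant.alt) - len(variant.ref)
    if delta < 0:
        # deleted bases sit after the anchor base
        affected = range(pos0 + 1, pos0 + len(variant.ref))
    else:
        # insertion lands between the anchor and the next base
        affected = range(pos0, pos0 + 2)
    offsets = [cds_offset(transcript, p) for p in affected]
    coding = [o for o in offsets if o is not None]
    if not coding:
        in_splice = any(_in_splice_region(transcript, p) for p in affected)
        cls = Consequence.SPLICE if in_splice else Consequence.NONCODING
        return CodingConsequence(
            gene=transcript.gene, transcript_id=transcript.transcript_id,
            codon_index=None, ref_aa=None, alt_aa=None, consequence_class=cls,
        )
    spans_boundary = any(o is None for o in offsets)
    if spans_boundary:
        log.warning(
            "indel %s spans a CDS/intron boundary of %s; classified frameshift",
            variant, transcript.transcript_id,
        )
        cls = Consequence.FRAMESHIFT
    else:
        cls = Consequence.FRAMESHIFT if delta % 3 != 0 else Consequence.INFRAME_INDEL
    codon_index = min(coding) // 3 + 1
    return CodingConsequence(
        gene=transcript.gene, transcript_id=transcript.transcript_id,
        codon_index=codon_index, ref_aa=None, alt_aa=None, consequence_class=cls,
    )


@dataclass(frozen=True)
class CodingConsequence:
    """Transcript-level consequence of one variant.

    ``codon_index`` is 1-based; ``None`` for splice/noncoding. Amino
    acids are one-letter codes with '*' for stop; they are ``None`` for
    indels, where per-residue assignment is not meaningful.
    """

    gene: str | None
    transcript_id: str | None
    codon_index: int | None
    ref_aa: str | None
    alt_aa: str | None
    consequence_class: Consequence

    def __post_init__(self) -> None:
        if self.consequence_class is Consequence.NONCODING and self.codon_index is not None:
            raise ValidationError("noncoding consequence cannot carry a codon index")
        if self.codon_index is not None and self.codon_index < 1:
            raise ValidationError(f"codon index must be >= 1, got {self.codon_index}")

    @property
    def aa_change(self) -> str | None:
        """Protein notation like 'G142S', or None when not applicable."""
        if self.codon_index is None or self.ref_aa is None or self.alt_aa is None:
            return None
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


INTERGENIC = CodingConsequence(
    gene=None, transcript_id=None, codon_index=None,
    ref_aa=None, alt_aa=None, consequence_class=Consequence.NONCODING,
)


class TranscriptIndex:
    """Chromosome-bucketed lookup from position to overlapping transcript.

    Transcript spans are extended by the splice flank so splice-region
    positions still resolve. With one canonical transcript per gene and
    non-overlapping genes, at most one transcript matches.
    """

    def __init__(self, transcripts: Iterable[Transcript]) -> None:
        by_chrom: dict[str, list[Transcript]] = {}
        for tx in transcripts:
            by_chrom.setdefault(tx.chrom, []).append(tx)
        self._by_chrom: dict[str, tuple[list[int], list[Transcript]]] = {}
        for chrom, txs in by_chrom.items():
            txs.sort(key=lambda t: t.span)
            starts = [t.span[0] - SPLICE_FLANK for t in txs]
            self._by_chrom[chrom] = (starts, txs)

    def lookup(self, chrom: str, pos: int) -> Transcript | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, txs = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i < 0:
            return None
        tx = txs[i]
        if pos < tx.span[1] + SPLICE_FLANK:
            return tx
        return None


def annotate_panel(
    records: Sequence,
    transcripts: Iterable[Transcript],
    reference: Mapping[str, str],
) -> dict[VariantKey, CodingConsequence]:
    """Consequence for every record's key; intergenic keys map to noncoding."""
    index = TranscriptIndex(transcripts)
    out: dict[VariantKey, CodingConsequence] = {}
    for rec in records:
        key = rec.key
        if key in out:
            continue
        tx = index.lookup(key.chrom, key.pos - 1)
        out[key] = INTERGENIC if tx is None else classify(key, tx, reference)
    return out
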