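"""Variant, panel and reference I/O.

Reads GATK-HaplotypeCaller-style VCFs into the pipeline's data model,
splits multi-allelic sites into biallelic records, normalizes indel
representation, and computes per-sample variant allele frequencies
(VAF) from allele depths.

Coordinate conventions: VCF and the gene-model TSV are 1-based
inclusive on disk; everything internal is 0-based half-open, and the
conversion happens only in the readers/writers in this module. The
one deliberate exception is :class:`VariantKey.pos`, which keeps the
VCF's 1-based position so that keys printed in reports match what a
user sees in the VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

from .errors import ConfigurationError, ValidationError, VcfParseError

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass(frozen=True, slots=True, order=True)
class VariantKey:
    """Exact identity of one biallelic variant.

    ``pos`` is 1-based (VCF convention). Two variants are the same
    mutation iff all four fields are equal; somatic-set intersection
    (clone relatedness) relies on this.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _BASES.issuperset(allele):
                raise ValidationError(
                    f"{name} allele {allele!r} at {self.chrom}:{self.pos} "
                    "must be non-empty uppercase A/C/G/T"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) > 1 and len(self.alt) > 1:
            raise ValidationError(
                f"only SNVs and simple indels are supported, got "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True, slots=True)
class SiteAnnotations:
    """Site-level calling annotations used by the hard filters.

    ``None`` means the annotation was absent from the VCF record;
    it is distinct from 0 and handled by the filter configuration.
    """

    qd: float | None = None  # variant confidence / depth
    fs: float | None = None  # Phred-scaled strand-bias (Fisher) score
    mq: float | None = None  # RMS mapping quality

    def __post_init__(self) -> None:
        if self.fs is not None and self.fs < 0:
            raise ValidationError(f"FS must be >= 0, got {self.fs}")
        if self.mq is not None and self.mq < 0:
            raise ValidationError(f"MQ must be >= 0, got {self.mq}")


@dataclass(frozen=True, slots=True)
class SampleCall:
    """One sample's evidence at one variant."""

    ref_depth: int = 0
    alt_depth: int = 0
    dp: int | None = None
    gq: int | None = None
    called: bool = False

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValidationError("allele depths must be >= 0")
        if self.dp is not None and self.ref_depth + self.alt_depth > self.dp:
            raise ValidationError(
                f"AD sum {self.ref_depth + self.alt_depth} exceeds DP {self.dp}"
            )


UNCALLED = SampleCall()


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One biallelic variant with its site annotations and per-sample calls."""

    key: VariantKey
    site: SiteAnnotations
    calls: Mapping[str, SampleCall]

    def call(self, sample: str) -> SampleCall:
        return self.calls.get(sample, UNCALLED)


@dataclass(frozen=True)
class CloneScreenPanel:
    """A resistance-screen panel: parental line, resistant clones, counter-screen.

    The counter-screen samples are clones resistant to an unrelated
    compound; mutations they carry are selection-independent background
    and are subtracted during somatic filtering.
    """

    parental: str
    clones: tuple[str, ...]
    counter_screen: tuple[str, ...]
    records: tuple[VariantRecord, ...]

    def __post_init__(self) -> None:
        names = [self.parental, *self.clones, *self.counter_screen]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"sample names not unique across roles: {names}")
        if not self.clones:
            raise ConfigurationError("panel must contain at least one clone")

    @property
    def samples(self) -> tuple[str, ...]:
        return (self.parental, *self.clones, *self.counter_screen)


def compute_vaf(call: SampleCall | None) -> float | None:
    """Variant allele frequency from allele depths.

    VAF = alt / (ref + alt). Returns ``None`` (indeterminate) for an
    absent or uncalled sample or a zero denominator; the denominator is
    the allele-informative depth, not DP, so the result is always in
    [0, 1] when defined.
    """
    if call is None or not call.called:
        return None
    denom = call.ref_depth + call.alt_depth
    if denom == 0:
        return None
    return call.alt_depth / denom


def normalize_variant(
    pos: int, ref: str, alt: str, seq: str | None = None
) -> tuple[int, str, str]:
    """Minimal, left-aligned representation of (1-based ``pos``, ref, alt).

    Trims shared suffix/prefix bases so that equivalent spellings of the
    same indel compare equal across samples; with the chromosome sequence
    available the indel is additionally shifted left through repeats.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim shared suffix, then shared prefix (keeping one anchor base)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if seq is not None and len(ref) != len(alt):
        # left-shift: while the alleles end with the same base, roll the
        # window one base left (standard left-alignment for indels)
        while pos > 1 and ref[-1] == alt[-1]:
            prev = seq[pos - 2].upper()
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    return pos, ref, alt


def _int_or_none(value) -> int | None:
    if value is None:
        return None
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def read_vcf(
    path: str | Path,
    sample_role_map: Mapping[str, object],
    reference: Mapping[str, str] | None = None,
) -> CloneScreenPanel:
    """Read a VCF 4.x file into a :class:`CloneScreenPanel`.

    ``sample_role_map`` assigns header samples to roles::

        {"parental": "A673-M1", "clones": [...], "counter_screen": [...]}

    Multi-allelic sites are split into one biallelic record per ALT
    allele with allele-specific depths from AD. Samples without a
    genotype at a site get ``called=False`` placeholders. If a
    ``reference`` map is given, indels are left-aligned before keying.
    """
    path = Path(path)
    parental = sample_role_map.get("parental")
    clones = tuple(sample_role_map.get("clones", ()))
    counter = tuple(sample_role_map.get("counter_screen", ()))
    if not isinstance(parental, str):
        raise ConfigurationError("sample_role_map must name a 'parental' sample")

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    header_samples = set(vcf.header.samples)
    for name in (parental, *clones, *counter):
        if name not in header_samples:
            raise ConfigurationError(
                f"sample {name!r} in role map is not in the VCF header "
                f"(header samples: {sorted(header_samples)})"
            )

    wanted = (parental, *clones, *counter)
    records: list[VariantRecord] = []
    for rec in vcf:
        try:
            records.extend(_split_record(rec, wanted, reference))
        except (ValueError, KeyError, IndexError) as exc:
            raise VcfParseError(
                f"malformed VCF record at {rec.chrom}:{rec.pos} in {path}: {exc}"
            ) from exc
    vcf.close()
    return CloneScreenPanel(
        parental=parental, clones=clones, counter_screen=counter,
        records=tuple(records),
    )


def _split_record(
    rec: pysam.VariantRecord,
    samples: Sequence[str],
    reference: Mapping[str, str] | None,
) -> list[VariantRecord]:
    alts = rec.alts or ()
    info = rec.info
    site = SiteAnnotations(
        qd=float(info["QD"]) if "QD" in info else None,
        fs=float(info["FS"]) if "FS" in info else None,
        mq=float(info["MQ"]) if "MQ" in info else None,
    )
    out: list[VariantRecord] = []
    for alt_index, alt in enumerate(alts):
        if alt is None or not _BASES.issuperset(alt.upper()):
            log.warning("skipping non-sequence ALT %r at %s:%d", alt, rec.chrom, rec.pos)
            continue
        seq = reference.get(rec.chrom) if reference else None
        pos, ref, alt_norm = normalize_variant(rec.pos, rec.ref, alt, seq)
        key = VariantKey(chrom=rec.chrom, pos=pos, ref=ref, alt=alt_norm)
        calls: dict[str, SampleCall] = {}
        for name in samples:
            fmt = rec.samples[name]
            gt = fmt.get("GT")
            called = gt is not None and any(a is not None for a in gt)
            ad = fmt.get("AD")
            ref_depth = alt_depth = 0
            if ad is not None and ad[0] is not None:
                ref_depth = int(ad[0])
                if len(ad) > alt_index + 1 and ad[alt_index + 1] is not None:
                    alt_depth = int(ad[alt_index + 1])
            calls[name] = SampleCall(
                ref_depth=ref_depth,
                alt_depth=alt_depth,
                dp=_int_or_none(fmt.get("DP")),
                gq=_int_or_none(fmt.get("GQ")),
                called=called,
            )
        out.append(VariantRecord(key=key, site=site, calls=calls))
    return out


_VCF_HEADER_LINES = (
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher\'s exact test to detect strand bias">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
)


def write_vcf(
    panel: CloneScreenPanel,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    genotypes: Mapping[tuple[VariantKey, str], tuple[int, int]] | None = None,
) -> Path:
    """Write a panel back to a plain-text biallelic VCF.

    ``genotypes`` optionally supplies GT tuples per (key, sample); when
    absent, GT is derived from depths (0/1 if any alt read else 0/0,
    ./. for uncalled samples). Round-trips keys, depths and annotations.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    contigs: dict[str, int] = dict(contig_lengths or {})
    for rec in panel.records:
        end = rec.key.pos + len(rec.key.ref)
        if contigs.get(rec.key.chrom, 0) < end:
            contigs[rec.key.chrom] = end
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for sample in panel.samples:
        header.add_sample(sample)

    out = pysam.VariantFile(str(path), "w", header=header)
    for rec in sorted(panel.records, key=lambda r: r.key):
        vrec = out.new_record(
            contig=rec.key.chrom,
            start=rec.key.pos - 1,
            alleles=(rec.key.ref, rec.key.alt),
        )
        if rec.site.qd is not None:
            vrec.info["QD"] = rec.site.qd
        if rec.site.fs is not None:
            vrec.info["FS"] = rec.site.fs
        if rec.site.mq is not None:
            vrec.info["MQ"] = rec.site.mq
        for sample in panel.samples:
            call = rec.call(sample)
            fmt = vrec.samples[sample]
            if not call.called:
                fmt["GT"] = (None, None)
                continue
            if genotypes and (rec.key, sample) in genotypes:
                fmt["GT"] = genotypes[(rec.key, sample)]
            else:
                fmt["GT"] = (0, 1) if call.alt_depth > 0 else (0, 0)
            fmt["AD"] = (call.ref_depth, call.alt_depth)
            if call.dp is not None:
                fmt["DP"] = call.dp
            if call.gq is not None:
                fmt["GQ"] = call.gq
        out.write(vrec)
    out.close()
    return path


def read_reference(path: str | Path) -> dict[str, str]:
    """Read a FASTA reference into {name: uppercase sequence}.

    Sequence names are the first whitespace-delimited token of each
    header. An empty file yields an empty map with a warning.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        log.warning("reference FASTA %s contains no sequences", path)
    return sequences


def write_reference(reference: Mapping[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in reference:
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


GENE_MODEL_COLUMNS = ("gene", "transcript", "chrom", "strand", "cds_starts", "cds_ends")


def read_gene_models(path: str | Path):
    """Read the gene-model TSV into :class:`~clonescreen.annotate.Transcript` objects.

    Dialect: tab-separated with header columns ``gene, transcript,
    chrom, strand, cds_starts, cds_ends``; starts/ends are comma lists,
    1-based inclusive, converted here to 0-based half-open. One
    canonical transcript per gene is expected so codon numbering is
    unambiguous.
    """
    from .annotate import Transcript  # local import avoids a cycle

    path = Path(path)
    transcripts: list[Transcript] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENE_MODEL_COLUMNS:
            raise ValidationError(
                f"gene-model file {path} must have columns {GENE_MODEL_COLUMNS}, "
                f"got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(GENE_MODEL_COLUMNS):
                raise ValidationError(f"{path}:{lineno}: expected 6 columns")
            gene, tx_id, chrom, strand, starts_s, ends_s = fields
            starts = [int(x) for x in starts_s.split(",") if x]
            ends = [int(x) for x in ends_s.split(",") if x]
            if len(starts) != len(ends):
                raise ValidationError(
                    f"{path}:{lineno}: transcript {tx_id}: cds_starts and "
                    "cds_ends lengths differ"
                )
            intervals = tuple((s - 1, e) for s, e in zip(starts, ends))
            transcripts.append(
                Transcript(
                    gene=gene, transcript_id=tx_id, chrom=chrom,
                    strand=strand, cds_intervals=intervals,
                )
            )
    genes = [t.gene for t in transcripts]
    if len(set(genes)) != len(genes):
        raise ValidationError(f"gene-model file {path} has multiple transcripts per gene")
    return transcripts


def write_gene_models(transcripts: Iterable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_MODEL_COLUMNS) + "\n")
        for tx in transcripts:
            starts = ",".join(str(s + 1) for s, _ in tx.cds_intervals)
            ends = ",".join(str(e) for _, e in tx.cds_intervals)
            fh.write(
                f"{tx.gene}\t{tx.transcript_id}\t{tx.chrom}\t{tx.strand}\t{starts}\t{ends}\n"
            )
    return path
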