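"""Codon-resolution consequence calling, checked against a brute-force
splice-mutate-translate oracle.
"""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from clonescreen.annotate import (
    CodingConsequence,
    Consequence,
    Transcript,
    cds_offset,
    classify,
    reverse_complement,
)
from clonescreen.errors import ReferenceMismatchError, ValidationError
from clonescreen.somatic import FilterConfig, is_coding
from clonescreen.variant_io import VariantKey


def single_exon_transcript(start, cds, strand="+", gene="G1", chrom="chr1"):
    return Transcript(
        gene=gene, transcript_id=f"{gene}_T1", chrom=chrom, strand=strand,
        cds_intervals=((start, start + len(cds)),),
    )


def embed(cds, start, strand="+", flank_len=500, seed=7):
    """Random chromosome with the CDS (genome-strand) embedded at ``start``."""
    rng = np.random.default_rng(seed)
    total = start + len(cds) + flank_len
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, total))
    genomic = cds if strand == "+" else reverse_complement(cds)
    return seq[:start] + genomic + seq[start + len(cds):]


# CDS whose codon 142 is GGC (Gly), as in the alpha-tubulin scenario
def cds_with_codon142(seed=3):
    rng = np.random.default_rng(seed)
    sense = [c for c in
             ("".join(b) for b in itertools.product("ACGT", repeat=3))
             if str(Seq(c).translate()) != "*"]
    codons = [sense[i] for i in rng.integers(0, len(sense), 150)]
    codons[0] = "ATG"
    codons[141] = "GGC"
    codons[-1] = "TAA"
    return "".join(codons)


class TestCdsOffset:
    def test_plus_strand_arithmetic(self):
        cds = "ATG" + "GCT" * 40 + "TAA"
        tx = single_exon_transcript(1000, cds)
        assert cds_offset(tx, 1000) == 0
        assert cds_offset(tx, 1000 + 123) == 123

    def test_minus_strand_last_base_is_offset_zero(self):
        cds = "ATG" + "GCT" * 40 + "TAA"
        tx = single_exon_transcript(1000, cds, strand="-")
        assert cds_offset(tx, 1000 + len(cds) - 1) == 0
        assert cds_offset(tx, 1000) == len(cds) - 1

    def test_intronic_position_is_none(self):
        tx = Transcript(
            gene="G1", transcript_id="T1", chrom="chr1", strand="+",
            cds_intervals=((100, 220), (400, 520)),
        )
        assert cds_offset(tx, 300) is None
        assert cds_offset(tx, 99) is None
        assert cds_offset(tx, 400) == 120

    def test_two_exon_offset_spans_intron(self):
        tx = Transcript(
            gene="G1", transcript_id="T1", chrom="chr1", strand="+",
            cds_intervals=((100, 220), (400, 520)),
        )
        assert cds_offset(tx, 410) == 130


class TestClassifySnv:
    @pytest.fixture
    def setup(self):
        cds = cds_with_codon142()
        start = 2000
        tx = single_exon_transcript(start, cds)
        ref = {"chr1": embed(cds, start)}
        # genomic position of codon 142's first base (0-based): start + 141*3
        return tx, ref, start + 141 * 3

    def test_g142s_first_base(self, setup):
        tx, ref, codon_pos = setup
        cons = classify(VariantKey("chr1", codon_pos + 1, "G", "A"), tx, ref)
        assert cons.consequence_class is Consequence.MISSENSE
        assert cons.aa_change == "G142S"  # AGC = Ser

    def test_g142a_second_base(self, setup):
        tx, ref, codon_pos = setup
        cons = classify(VariantKey("chr1", codon_pos + 2, "G", "C"), tx, ref)
        assert cons.aa_change == "G142A"  # GCC = Ala

    def test_synonymous_third_base(self, setup):
        tx, ref, codon_pos = setup
        cons = classify(VariantKey("chr1", codon_pos + 3, "C", "T"), tx, ref)
        assert cons.consequence_class is Consequence.SYNONYMOUS  # GGT = Gly
        assert cons.codon_index == 142

    def test_reference_mismatch_raises(self, setup):
        tx, ref, codon_pos = setup
        with pytest.raises(ReferenceMismatchError):
            classify(VariantKey("chr1", codon_pos + 1, "T", "A"), tx, ref)


class TestClassifyIndelAndSplice:
    @pytest.fixture
    def two_exon(self):
        cds = "ATG" + "GCT" * 50 + "TAA"  # 156 nt
        first, second = cds[:90], cds[90:]
        start = 1000
        intron = 200
        chrom = embed(cds, start)  # contiguous embed, then re-split below
        seq = (
            chrom[:start] + first + "GT" + "A" * (intron - 4) + "AG" + second
            + chrom[start + len(cds):]
        )
        tx = Transcript(
            gene="G1", transcript_id="G1_T1", chrom="chr1", strand="+",
            cds_intervals=(
                (start, start + 90),
                (start + 90 + intron, start + len(cds) + intron),
            ),
        )
        return tx, {"chr1": seq}, start

    def test_one_bp_deletion_is_frameshift(self, two_exon):
        tx, ref, start = two_exon
        pos = start + 10  # inside exon 1
        r = ref["chr1"][pos : pos + 2]
        cons = classify(VariantKey("chr1", pos + 1, r, r[0]), tx, ref)
        assert cons.consequence_class is Consequence.FRAMESHIFT
        assert cons.codon_index == (10 + 1) // 3 + 1

    def test_three_bp_deletion_is_inframe(self, two_exon):
        tx, ref, start = two_exon
        pos = start + 9
        r = ref["chr1"][pos : pos + 4]
        cons = classify(VariantKey("chr1", pos + 1, r, r[0]), tx, ref)
        assert cons.consequence_class is Consequence.INFRAME_INDEL

    def test_boundary_spanning_deletion_is_frameshift_with_warning(self, two_exon, caplog):
        tx, ref, start = two_exon
        pos = start + 87  # deletion runs past the exon-1 end at start+90
        r = ref["chr1"][pos : pos + 6]
        with caplog.at_level("WARNING"):
            cons = classify(VariantKey("chr1", pos + 1, r, r[0]), tx, ref)
        assert cons.consequence_class is Consequence.FRAMESHIFT
        assert "boundary" in caplog.text

    def test_intronic_snv_near_exon_is_splice(self, two_exon):
        tx, ref, start = two_exon
        pos = start + 90  # first intronic base after exon 1
        base = ref["chr1"][pos]
        alt = "A" if base != "A" else "C"
        cons = classify(VariantKey("chr1", pos + 1, base, alt), tx, ref)
        assert cons.consequence_class is Consequence.SPLICE
        assert cons.codon_index is None

    def test_deep_intronic_snv_is_noncoding(self, two_exon):
        tx, ref, start = two_exon
        pos = start + 150  # mid-intron
        base = ref["chr1"][pos]
        alt = "C" if base != "C" else "G"
        cons = classify(VariantKey("chr1", pos + 1, base, alt), tx, ref)
        assert cons.consequence_class is Consequence.NONCODING


class TestIsCoding:
    @pytest.mark.parametrize(
        "cls,expected",
        [
            (Consequence.MISSENSE, True),
            (Consequence.SYNONYMOUS, True),
            (Consequence.NONSENSE, True),
            (Consequence.FRAMESHIFT, True),
            (Consequence.INFRAME_INDEL, True),
            (Consequence.NONCODING, False),
        ],
    )
    def test_default_classes(self, cls, expected):
        cons = CodingConsequence(
            gene="G", transcript_id="T", codon_index=None if cls in
            (Consequence.NONCODING, Consequence.SPLICE) else 5,
            ref_aa=None, alt_aa=None, consequence_class=cls,
        )
        assert is_coding(cons, FilterConfig()) is expected

    def test_splice_follows_config_flag(self):
        cons = CodingConsequence(
            gene="G", transcript_id="T", codon_index=None,
            ref_aa=None, alt_aa=None, consequence_class=Consequence.SPLICE,
        )
        assert is_coding(cons, FilterConfig()) is True
        assert is_coding(cons, FilterConfig(count_splice_as_coding=False)) is False


def oracle_snv(tx, reference, key):
    """Brute force: splice the whole CDS, mutate, translate end to end."""
    cds = tx.cds_sequence(reference)
    off = cds_offset(tx, key.pos - 1)
    base = key.alt if tx.strand == "+" else reverse_complement(key.alt)
    mutated = cds[:off] + base + cds[off + 1 :]
    prot_ref = str(Seq(cds).translate())
    prot_alt = str(Seq(mutated).translate())
    codon = off // 3 + 1
    return prot_ref[codon - 1], prot_alt[codon - 1], codon


class TestOracleEquivalence:
    def test_random_snvs_match_full_translation_oracle(self):
        """classify() agrees with splice-and-translate on both strands
        and across introns, on a random toy genome."""
        from clonescreen.simulate import TOY_GENOME, build_genome

        rng = np.random.default_rng(42)
        reference, transcripts = build_genome(TOY_GENOME, rng)
        checked = 0
        while checked < 300:
            tx = transcripts[int(rng.integers(0, len(transcripts)))]
            off = int(rng.integers(0, tx.cds_length))
            pos = tx.genomic_position(off)
            ref_base = reference[tx.chrom][pos]
            alt_base = "ACGT"[int(rng.integers(0, 4))]
            if alt_base == ref_base:
                continue
            key = VariantKey(tx.chrom, pos + 1, ref_base, alt_base)
            cons = classify(key, tx, reference)
            ref_aa, alt_aa, codon = oracle_snv(tx, reference, key)
            assert (cons.ref_aa, cons.alt_aa, cons.codon_index) == (ref_aa, alt_aa, codon)
            checked += 1

    def test_strand_symmetry(self):
        """A transcript and its reverse-complement mirror classify
        mirrored variants identically."""
        cds = cds_with_codon142()
        start = 300
        chrom_plus = embed(cds, start)
        L = len(chrom_plus)
        chrom_minus = reverse_complement(chrom_plus)
        tx_plus = single_exon_transcript(start, cds, strand="+")
        tx_minus = Transcript(
            gene="G1", transcript_id="G1_T1", chrom="chr1", strand="-",
            cds_intervals=((L - start - len(cds), L - start),),
        )
        rng = np.random.default_rng(5)
        for _ in range(50):
            off = int(rng.integers(0, len(cds)))
            pos = start + off
            ref_base = chrom_plus[pos]
            alt_base = "ACGT"[int(rng.integers(0, 4))]
            if alt_base == ref_base:
                continue
            cons_plus = classify(
                VariantKey("chr1", pos + 1, ref_base, alt_base),
                tx_plus, {"chr1": chrom_plus},
            )
            mirror_pos = L - 1 - pos
            cons_minus = classify(
                VariantKey(
                    "chr1", mirror_pos + 1,
                    reverse_complement(ref_base), reverse_complement(alt_base),
                ),
                tx_minus, {"chr1": chrom_minus},
            )
            assert cons_plus == cons_minus


class TestTranscriptInvariants:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValidationError):
            Transcript(
                gene="G", transcript_id="T", chrom="chr1", strand="+",
                cds_intervals=((100, 200), (150, 250)),
            )

    def test_bad_strand_rejected(self):
        with pytest.raises(ValidationError):
            Transcript(
                gene="G", transcript_id="T", chrom="chr1", strand="x",
                cds_intervals=((0, 3),),
            )
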