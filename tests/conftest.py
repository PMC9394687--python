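"""Shared fixtures: hand-built panels, toy transcripts, and one
session-wide simulated screen in the headline scenario (6 clones,
related pair with a 91-mutation branch, driver in 4 clones).
"""

from __future__ import annotations

from pathlib import Path

import pytest

from clonescreen.annotate import CodingConsequence, Consequence, Transcript
from clonescreen.somatic import SomaticSet, SomaticVariant
from clonescreen.variant_io import (
    CloneScreenPanel,
    SampleCall,
    SiteAnnotations,
    VariantKey,
    VariantRecord,
)


def make_call(ref_depth=60, alt_depth=0, dp=None, gq=50, called=True):
    dp = ref_depth + alt_depth if dp is None else dp
    return SampleCall(ref_depth=ref_depth, alt_depth=alt_depth, dp=dp, gq=gq, called=called)


def make_record(pos, calls, ref="A", alt="G", chrom="chr1", qd=25.0, fs=1.0, mq=58.0):
    return VariantRecord(
        key=VariantKey(chrom, pos, ref, alt),
        site=SiteAnnotations(qd=qd, fs=fs, mq=mq),
        calls=calls,
    )


def missense(gene="GENE1", codon=10, ref_aa="G", alt_aa="S"):
    return CodingConsequence(
        gene=gene, transcript_id=f"{gene}_T1", codon_index=codon,
        ref_aa=ref_aa, alt_aa=alt_aa, consequence_class=Consequence.MISSENSE,
    )


NONCODING = CodingConsequence(
    gene="GENE1", transcript_id="GENE1_T1", codon_index=None,
    ref_aa=None, alt_aa=None, consequence_class=Consequence.NONCODING,
)


def somatic_set(clone: str, entries) -> SomaticSet:
    """Build a SomaticSet from (pos, gene, codon, ref_aa, alt_aa) tuples."""
    variants = {}
    for pos, gene, codon, ref_aa, alt_aa in entries:
        key = VariantKey("chr1", pos, "A", "G")
        variants[key] = SomaticVariant(
            key=key,
            consequence=missense(gene=gene, codon=codon, ref_aa=ref_aa, alt_aa=alt_aa),
            clone_vaf=0.5, parental_vaf=0.0, counter_vafs=(0.0,),
            provenance=("test",),
        )
    return SomaticSet(clone=clone, variants=variants)


@pytest.fixture
def tiny_panel():
    """Parental + 2 clones + 1 counter sample, 3 records with known VAFs."""
    samples = ("PAR", "CL1", "CL2", "CTR")

    def calls(par, cl1, cl2, ctr):
        return dict(zip(samples, (par, cl1, cl2, ctr)))

    records = (
        # clean somatic in CL1: VAF 0.5, absent elsewhere
        make_record(100, calls(make_call(80, 0), make_call(40, 40), make_call(80, 0), make_call(80, 0))),
        # present in parental at VAF 0.5 (background)
        make_record(200, calls(make_call(40, 40), make_call(40, 40), make_call(40, 40), make_call(40, 40))),
        # in CL2 and in the counter sample at VAF 0.3
        make_record(300, calls(make_call(80, 0), make_call(80, 0), make_call(40, 40), make_call(56, 24))),
    )
    return CloneScreenPanel(
        parental="PAR", clones=("CL1", "CL2"), counter_screen=("CTR",), records=records
    )


@pytest.fixture(scope="session")
def screen_sim(tmp_path_factory):
    """One simulated screen in the headline scenario (seed 11)."""
    from clonescreen.simulate import paper_scenario, simulate_screen

    out = tmp_path_factory.mktemp("screen_sim")
    return simulate_screen(paper_scenario(11), out)


@pytest.fixture(scope="session")
def screen_bundle(screen_sim, tmp_path_factory):
    """Full pipeline output for the session's simulated screen."""
    from clonescreen.pipeline import PipelineConfig, run_screen

    out = tmp_path_factory.mktemp("screen_out")
    config = PipelineConfig(
        vcf=screen_sim.vcf_path,
        reference=screen_sim.fasta_path,
        gene_models=screen_sim.gene_models_path,
        out_dir=out,
        parental=screen_sim.panel.parental,
        clones=screen_sim.panel.clones,
        counter_screen=screen_sim.panel.counter_screen,
    )
    return run_screen(config)
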