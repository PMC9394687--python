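"""Synthetic screen generator: determinism, truth consistency, planted
structure (branch, drivers, burdens, indel signature) and viability plates.
"""

import numpy as np
import pytest
from scipy import stats

from clonescreen.annotate import classify
from clonescreen.dose_response import design_dilution_series, loglogistic
from clonescreen.errors import ConfigurationError
from clonescreen.simulate import (
    TOY_GENOME,
    DriverMutation,
    DriverSpec,
    SimulationConfig,
    build_genome,
    paper_scenario,
    simulate_screen,
    simulate_viability,
)
from clonescreen.variant_io import read_vcf


def toy_config(seed=0, **kwargs):
    defaults = dict(
        seed=seed, genome=TOY_GENOME, n_clones=3, lambda_passenger=120.0,
        counter_screen_n=1, n_background=60,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_driver_gene_has_required_codons(self):
        rng = np.random.default_rng(0)
        reference, transcripts = build_genome(TOY_GENOME, rng)
        tuba = next(t for t in transcripts if t.gene == "TUBA1B")
        cds = tuba.cds_sequence(reference)
        assert cds[(47 - 1) * 3 : 47 * 3] == "GAC"    # Asp47
        assert cds[(142 - 1) * 3 : 142 * 3] == "GGC"  # Gly142
        assert cds.startswith("ATG")

    def test_coding_fraction_near_target(self):
        rng = np.random.default_rng(0)
        reference, transcripts = build_genome(TOY_GENOME, rng)
        coding = sum(t.cds_length for t in transcripts)
        fraction = coding / len(reference["chr1"])
        assert fraction == pytest.approx(TOY_GENOME.coding_fraction, rel=0.2)

    def test_both_strands_and_multi_exon_present(self):
        rng = np.random.default_rng(0)
        _, transcripts = build_genome(TOY_GENOME, rng)
        assert any(t.strand == "-" for t in transcripts)
        assert any(len(t.cds_intervals) == 2 for t in transcripts)


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        sim1 = simulate_screen(toy_config(5), tmp_path / "a")
        sim2 = simulate_screen(toy_config(5), tmp_path / "b")
        assert sim1.vcf_path.read_bytes() == sim2.vcf_path.read_bytes()
        assert sim1.fasta_path.read_bytes() == sim2.fasta_path.read_bytes()
        assert sim1.truth_path.read_bytes() == sim2.truth_path.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        sim1 = simulate_screen(toy_config(5), tmp_path / "a")
        sim2 = simulate_screen(toy_config(6), tmp_path / "b")
        assert sim1.vcf_path.read_bytes() != sim2.vcf_path.read_bytes()


class TestTruth:
    def test_every_truth_record_in_vcf(self, tmp_path):
        sim = simulate_screen(toy_config(1), tmp_path)
        panel = read_vcf(
            sim.vcf_path,
            {
                "parental": sim.panel.parental,
                "clones": list(sim.panel.clones),
                "counter_screen": list(sim.panel.counter_screen),
            },
        )
        vcf_keys = {r.key for r in panel.records}
        for clone in sim.panel.clones:
            assert sim.truth.keys(clone) <= vcf_keys

    def test_burden_within_poisson_interval(self, tmp_path):
        lam = 120.0
        sim = simulate_screen(toy_config(2), tmp_path)
        low, high = stats.poisson.ppf([0.005, 0.995], lam)
        for clone in sim.panel.clones:
            private = [
                r for r in sim.truth.by_clone[clone] if not (r.is_branch or r.is_driver)
            ]
            assert low <= len(private) <= high

    def test_branch_shared_count_is_exact(self, tmp_path):
        config = toy_config(3, n_clones=3, related_pair=(0, 2, 91))
        sim = simulate_screen(config, tmp_path)
        a, c = sim.panel.clones[0], sim.panel.clones[2]
        shared = sim.truth.keys(a) & sim.truth.keys(c)
        assert len(shared) == 91
        assert all(
            r.is_branch for r in sim.truth.by_clone[a] if r.key in shared
        )

    def test_indels_anchored_in_homopolymers(self, tmp_path):
        sim = simulate_screen(toy_config(4, indel_fraction=0.5), tmp_path)
        ref = sim.reference["chr1"]
        indels = [
            r for clone in sim.panel.clones for r in sim.truth.by_clone[clone]
            if not r.key.is_snv
        ]
        assert indels  # the signature is actually produced
        for r in indels:
            longer = max(r.key.ref, r.key.alt, key=len)
            run_base = longer[1]
            run_start = r.key.pos  # 0-based position after the anchor
            assert ref[run_start : run_start + 4] == run_base * 4


class TestDrivers:
    def test_driver_vaf_matches_zygosity(self, tmp_path):
        """Mean observed VAF of a heterozygous driver is ~0.5 across seeds."""
        observed = []
        for seed in range(8):
            config = toy_config(
                seed,
                driver_spec=DriverSpec(
                    gene="TUBA1B",
                    mutations=(
                        DriverMutation(clone=0, codon_index=142, alt_aa="S", zygosity=0.5),
                    ),
                ),
            )
            sim = simulate_screen(config, tmp_path / str(seed))
            clone = sim.panel.clones[0]
            driver = next(r for r in sim.truth.by_clone[clone] if r.is_driver)
            rec = next(r for r in sim.panel.records if r.key == driver.key)
            call = rec.call(clone)
            observed.append(call.alt_depth / (call.ref_depth + call.alt_depth))
        assert np.mean(observed) == pytest.approx(0.5, abs=0.05)

    def test_driver_produces_requested_substitution(self, tmp_path):
        config = toy_config(
            7,
            driver_spec=DriverSpec(
                gene="TUBA1B",
                mutations=(
                    DriverMutation(clone=0, codon_index=142, alt_aa="A", zygosity=1.0),
                    DriverMutation(clone=1, codon_index=47, alt_aa="H", zygosity=0.5),
                ),
            ),
        )
        sim = simulate_screen(config, tmp_path)
        tuba = next(t for t in sim.transcripts if t.gene == "TUBA1B")
        drivers = [
            r for clone in sim.panel.clones for r in sim.truth.by_clone[clone]
            if r.is_driver
        ]
        changes = {
            classify(r.key, tuba, sim.reference).aa_change for r in drivers
        }
        assert changes == {"G142A", "D47H"}

    def test_unreachable_substitution_rejected(self, tmp_path):
        config = toy_config(
            0,
            driver_spec=DriverSpec(
                gene="TUBA1B",
                mutations=(
                    # Gly (GGC) cannot become Lys with a single base change
                    DriverMutation(clone=0, codon_index=142, alt_aa="K", zygosity=1.0),
                ),
            ),
        )
        with pytest.raises(ConfigurationError, match="cannot reach"):
            simulate_screen(config, tmp_path)

    def test_codon_beyond_transcript_rejected(self, tmp_path):
        config = toy_config(
            0,
            driver_spec=DriverSpec(
                gene="TUBA1B",
                mutations=(
                    DriverMutation(clone=0, codon_index=99999, alt_aa="A", zygosity=1.0),
                ),
            ),
        )
        with pytest.raises(ConfigurationError, match="beyond"):
            simulate_screen(config, tmp_path)


class TestObservedVafs:
    def test_mean_absolute_vaf_error_bounded_by_depth(self, screen_sim):
        """Binomial sampling keeps |observed - true| VAF below 2/sqrt(depth)
        on average across truth records."""
        records_by_key = {r.key: r for r in screen_sim.panel.records}
        errors = []
        for clone in screen_sim.panel.clones:
            for truth_rec in screen_sim.truth.by_clone[clone]:
                call = records_by_key[truth_rec.key].call(clone)
                denom = call.ref_depth + call.alt_depth
                if denom == 0:
                    continue
                errors.append(abs(call.alt_depth / denom - truth_rec.true_vaf))
        assert np.mean(errors) < 2.0 / np.sqrt(80.0)


class TestScenarioFile:
    def test_yaml_round_trip_matches_programmatic_config(self, tmp_path):
        from clonescreen.simulate import load_scenario

        path = tmp_path / "scenario.yaml"
        path.write_text(
            "seed: 11\n"
            "genome: toy\n"
            "n_clones: 4\n"
            "lambda_passenger: 150\n"
            "related_pair: [0, 2, 40]\n"
            "driver_gene: TUBA1B\n"
            "drivers:\n"
            "  - {clone: 0, codon: 142, alt_aa: A, zygosity: 1.0}\n"
            "  - {clone: 1, codon: 47, alt_aa: H, zygosity: 0.5}\n"
        )
        config = load_scenario(path)
        assert config.seed == 11
        assert config.genome is TOY_GENOME
        assert config.related_pair == (0, 2, 40)
        assert config.driver_spec.mutations[1] == DriverMutation(
            clone=1, codon_index=47, alt_aa="H", zygosity=0.5
        )

    def test_unknown_genome_rejected(self, tmp_path):
        from clonescreen.simulate import load_scenario

        path = tmp_path / "bad.yaml"
        path.write_text("genome: hg38\n")
        with pytest.raises(ConfigurationError, match="hg38"):
            load_scenario(path)


class TestViability:
    def test_noiseless_readings_on_curve(self):
        conc = design_dilution_series(50e-6, 15, min_conc=1.58e-9)
        ds = simulate_viability(1e-6, 1.0, conc, replicates=2, noise_cv=0.0, seed=0)
        for c, readings in ds.points:
            expected = loglogistic(np.log10(c), -6.0, 1.0)
            assert readings == pytest.approx([expected, expected])
        assert ds.vehicle_readings == pytest.approx([100.0] * 4)

    def test_model_limits(self):
        ds = simulate_viability(
            1e-6, 1.0, [1e-15, 1e3], replicates=1, noise_cv=0.0, seed=0
        )
        assert ds.points[0][1][0] == pytest.approx(100.0, abs=1e-6)
        assert ds.points[1][1][0] == pytest.approx(0.0, abs=1e-6)

    def test_reproducible_by_seed(self):
        conc = design_dilution_series(50e-6, 15, min_conc=1.58e-9)
        a = simulate_viability(1e-6, 1.0, conc, seed=9)
        b = simulate_viability(1e-6, 1.0, conc, seed=9)
        assert a == b
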