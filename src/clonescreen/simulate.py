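"""Synthetic screen data with known ground truth.

Generates the statistical structure the analysis assumes, without any
sequencing data: a reference genome with one canonical transcript per
gene (including an alpha-tubulin-like gene whose codons 47 and 142
encode Asp and Gly, so the D47G/H and G142A/S substitutions are
reachable by single SNVs); a parental line with heterozygous
background variants and low-frequency artifact sites; resistant clones
each carrying a Poisson number of private passenger mutations
(transition-biased SNVs plus homopolymer 1-bp indels, the mismatch-
repair-deficiency signature); an optional shared lineage branch
between two clones; and driver mutations planted at requested codons
and zygosities. Read support is sampled per site as Poisson depth and
binomial alt reads, and calling annotations (QD/FS/MQ/GQ) are drawn
from pass-region distributions with a configurable fraction of planted
hard-filter failures. All output is byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import Transcript, reverse_complement, translate_codon
from .dose_response import DoseResponseDataset, loglogistic
from .errors import ConfigurationError
from .variant_io import (
    CloneScreenPanel,
    SampleCall,
    SiteAnnotations,
    VariantKey,
    VariantRecord,
    write_gene_models,
    write_reference,
    write_vcf,
)

_SENSE_CODONS = tuple(
    sorted(
        c
        for c in ("".join(b) for b in itertools.product("ACGT", repeat=3))
        if translate_codon(c) != "*"
    )
)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

#: zygosity classes observed in engineered clones: homozygous,
#: heterozygous, or one of three alleles
ZYGOSITIES = (1.0, 0.5, 1.0 / 3.0)
_ZYGOSITY_PROBS = (0.15, 0.70, 0.15)


@dataclass(frozen=True)
class DriverMutation:
    """One planted driver substitution in one clone."""

    clone: int
    codon_index: int
    alt_aa: str
    zygosity: float

    def __post_init__(self) -> None:
        if not any(np.isclose(self.zygosity, z) for z in ZYGOSITIES):
            raise ConfigurationError(
                f"driver zygosity must be one of {ZYGOSITIES}, got {self.zygosity}"
            )


@dataclass(frozen=True)
class DriverSpec:
    gene: str
    mutations: tuple[DriverMutation, ...]


@dataclass(frozen=True)
class GenomeSpec:
    """Builtin genome shapes; ``name`` is 'toy' or 'screen'."""

    name: str
    n_genes: int
    codons_per_gene: int
    driver_gene_codons: int
    coding_fraction: float


TOY_GENOME = GenomeSpec(
    name="toy", n_genes=10, codons_per_gene=120, driver_gene_codons=150,
    coding_fraction=0.04,
)
#: scaled-down exome: enough genes that passenger recurrence stays rare,
#: as in a real exome where any one gene is a small mutational target
SCREEN_GENOME = GenomeSpec(
    name="screen", n_genes=150, codons_per_gene=400, driver_gene_codons=451,
    coding_fraction=0.04,
)

DRIVER_GENE = "TUBA1B"
#: fixed codons of the driver gene: 47 = Asp (GAC), 142 = Gly (GGC)
_FIXED_CODONS = {1: "ATG", 47: "GAC", 142: "GGC"}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    genome: GenomeSpec = SCREEN_GENOME
    n_clones: int = 6
    lambda_passenger: float = 300.0
    related_pair: tuple[int, int, int] | None = None  # (clone_i, clone_j, branch_size)
    driver_spec: DriverSpec | None = None
    depth_mean: float = 80.0
    parental_error_rate: float = 1e-5  # per-site artifact rate
    counter_screen_n: int = 2
    n_background: int = 300
    filter_fail_fraction: float = 0.02
    indel_fraction: float = 0.10
    transition_fraction: float = 2.0 / 3.0  # 2:1 transitions:transversions

    def __post_init__(self) -> None:
        if self.lambda_passenger <= 0:
            raise ConfigurationError("lambda_passenger must be > 0")
        if self.related_pair is not None:
            i, j, size = self.related_pair
            if size < 0:
                raise ConfigurationError("branch_size must be >= 0")
            if not (0 <= i < self.n_clones and 0 <= j < self.n_clones and i != j):
                raise ConfigurationError("related_pair clones out of range")
        if self.driver_spec is not None:
            for m in self.driver_spec.mutations:
                if not 0 <= m.clone < self.n_clones:
                    raise ConfigurationError(
                        f"driver clone {m.clone} outside 0..{self.n_clones - 1}"
                    )


def paper_scenario(seed: int) -> SimulationConfig:
    """The screen's headline scenario: 6 clones, one related pair
    sharing a 91-mutation branch, and the driver gene hit in 4 of 6
    clones at codons 142 (Ala/Ser) and 47 (Gly/His) with the observed
    zygosities (G142A homozygous, G142S heterozygous, D47H one-third).
    """
    return SimulationConfig(
        seed=seed,
        genome=SCREEN_GENOME,
        n_clones=6,
        lambda_passenger=300.0,
        related_pair=(0, 2, 91),
        driver_spec=DriverSpec(
            gene=DRIVER_GENE,
            mutations=(
                DriverMutation(clone=0, codon_index=142, alt_aa="A", zygosity=1.0),
                DriverMutation(clone=1, codon_index=142, alt_aa="S", zygosity=0.5),
                DriverMutation(clone=3, codon_index=47, alt_aa="G", zygosity=0.5),
                DriverMutation(clone=5, codon_index=47, alt_aa="H", zygosity=1 / 3),
            ),
        ),
    )


def load_scenario(path: str | Path) -> SimulationConfig:
    """Read a simulation scenario from a YAML key/value file.

    Recognized keys mirror :class:`SimulationConfig`; ``genome`` is
    'toy' or 'screen', ``related_pair`` a 3-item list
    [clone_i, clone_j, branch_size], and ``drivers`` a list of
    {clone, codon, alt_aa, zygosity} mappings under a ``driver_gene``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"scenario file {path} must be a mapping")
    genomes = {"toy": TOY_GENOME, "screen": SCREEN_GENOME}
    kwargs: dict = {"seed": int(raw.get("seed", 0))}
    if "genome" in raw:
        name = raw["genome"]
        if name not in genomes:
            raise ConfigurationError(f"unknown genome {name!r} (use toy or screen)")
        kwargs["genome"] = genomes[name]
    for field_name in (
        "n_clones", "lambda_passenger", "depth_mean", "parental_error_rate",
        "counter_screen_n", "n_background", "filter_fail_fraction",
        "indel_fraction", "transition_fraction",
    ):
        if field_name in raw:
            kwargs[field_name] = raw[field_name]
    if "related_pair" in raw and raw["related_pair"] is not None:
        i, j, size = raw["related_pair"]
        kwargs["related_pair"] = (int(i), int(j), int(size))
    if raw.get("drivers"):
        gene = raw.get("driver_gene", DRIVER_GENE)
        kwargs["driver_spec"] = DriverSpec(
            gene=gene,
            mutations=tuple(
                DriverMutation(
                    clone=int(d["clone"]), codon_index=int(d["codon"]),
                    alt_aa=str(d["alt_aa"]), zygosity=float(d["zygosity"]),
                )
                for d in raw["drivers"]
            ),
        )
    try:
        return SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad scenario key in {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# genome construction


def _random_cds(rng: np.random.Generator, n_codons: int, fixed: Mapping[int, str] | None = None) -> str:
    codons = [
        _SENSE_CODONS[i]
        for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
    ]
    codons.append("TAA")
    codons[0] = "ATG"
    for index, codon in (fixed or {}).items():
        codons[index - 1] = codon
    return "".join(codons)


def build_genome(
    spec: GenomeSpec, rng: np.random.Generator
) -> tuple[dict[str, str], list[Transcript]]:
    """Random reference with evenly spaced genes on one chromosome.

    Gene 0 is the driver gene with its fixed codons; every third gene
    is on the minus strand and every fourth is split into two CDS
    exons, so annotation is exercised on both strands and across
    introns.
    """
    lengths = [spec.driver_gene_codons * 3] + [spec.codons_per_gene * 3] * (
        spec.n_genes - 1
    )
    genome_len = int(sum(lengths) / spec.coding_fraction)
    spacing = genome_len // spec.n_genes
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = bases[rng.integers(0, 4, size=genome_len)].copy()

    transcripts: list[Transcript] = []
    for i, cds_len in enumerate(lengths):
        gene = DRIVER_GENE if i == 0 else f"GENE{i:03d}"
        strand = "-" if (i > 0 and i % 3 == 2) else "+"
        cds = _random_cds(
            rng, cds_len // 3, _FIXED_CODONS if i == 0 else None
        )
        start = i * spacing + spacing // 4
        if i > 0 and i % 4 == 1:
            # two exons with a 200 bp intron; split at a codon boundary
            first = (cds_len // 2) - ((cds_len // 2) % 3)
            intervals = ((start, start + first), (start + first + 200, start + cds_len + 200))
        else:
            intervals = ((start, start + cds_len),)
        genomic = cds if strand == "+" else reverse_complement(cds)
        offset = 0
        for s, e in intervals:
            chunk = genomic[offset : offset + (e - s)]
            seq[s:e] = np.frombuffer(chunk.encode(), dtype="S1")
            offset += e - s
        transcripts.append(
            Transcript(
                gene=gene, transcript_id=f"{gene}_T1", chrom="chr1",
                strand=strand, cds_intervals=intervals,
            )
        )
    reference = {"chr1": seq.tobytes().decode()}
    return reference, transcripts


def _homopolymer_anchors(seq: str, min_len: int = 4) -> list[tuple[int, str]]:
    """(anchor 0-based position, run base) for maximal runs >= min_len.

    The anchor is the base before the run, as required for left-aligned
    VCF indel representation; runs starting at position 0 are skipped.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1")
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    out = []
    for s, e in zip(starts, ends):
        if e - s >= min_len and s > 0:
            out.append((int(s) - 1, arr[s].decode()))
    return out


# ---------------------------------------------------------------------------
# mutation planting


@dataclass
class _SimVariant:
    key: VariantKey
    true_vaf: dict[str, float]       # carriers only
    zygosity: float
    coding: bool
    gene: str | None
    codon_index: int | None
    is_driver: bool = False
    is_branch: bool = False
    is_background: bool = False
    is_artifact: bool = False
    fail_mode: str | None = None     # planted hard-filter failure


@dataclass(frozen=True)
class TruthRecord:
    key: VariantKey
    true_vaf: float
    zygosity: float
    coding: bool
    gene: str | None
    codon_index: int | None
    is_driver: bool
    is_branch: bool
    hard_filter_fail: bool


@dataclass(frozen=True)
class TruthSet:
    """Planted acquired mutations per clone, for sensitivity/recovery checks."""

    by_clone: dict[str, tuple[TruthRecord, ...]]

    def keys(self, clone: str) -> frozenset[VariantKey]:
        return frozenset(r.key for r in self.by_clone[clone])


@dataclass(frozen=True)
class ScreenSimulation:
    panel: CloneScreenPanel
    truth: TruthSet
    reference: dict[str, str]
    transcripts: tuple[Transcript, ...]
    vcf_path: Path
    fasta_path: Path
    gene_models_path: Path
    truth_path: Path


def _snv_alt(rng: np.random.Generator, ref: str, transition_fraction: float) -> str:
    if rng.random() < transition_fraction:
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][int(rng.integers(0, 2))]


def _driver_snv(
    transcript: Transcript, reference: Mapping[str, str], mutation: DriverMutation
) -> tuple[VariantKey, int]:
    """Reverse-engineer the SNV realizing a codon substitution.

    Returns the variant key and the codon's first genomic position set.
    Raises if the requested amino acid is not reachable by one SNV.
    """
    if mutation.codon_index > transcript.n_codons:
        raise ConfigurationError(
            f"codon {mutation.codon_index} beyond {transcript.gene} "
            f"({transcript.n_codons} codons)"
        )
    cds = transcript.cds_sequence(reference)
    start = (mutation.codon_index - 1) * 3
    ref_codon = cds[start : start + 3]
    for within in range(3):
        for base in "ACGT":
            if base == ref_codon[within]:
                continue
            alt_codon = ref_codon[:within] + base + ref_codon[within + 1 :]
            if translate_codon(alt_codon) == mutation.alt_aa:
                offset = start + within
                gpos = transcript.genomic_position(offset)
                chrom_seq = reference[transcript.chrom]
                ref_base = chrom_seq[gpos]
                alt_base = base if transcript.strand == "+" else reverse_complement(base)
                return (
                    VariantKey(transcript.chrom, gpos + 1, ref_base, alt_base),
                    gpos,
                )
    raise ConfigurationError(
        f"{transcript.gene} codon {mutation.codon_index} ({ref_codon}, "
        f"{translate_codon(ref_codon)}) cannot reach {mutation.alt_aa} by one SNV"
    )


def _coding_position_array(transcripts: Sequence[Transcript]) -> np.ndarray:
    parts = [
        np.arange(s, e) for tx in transcripts for s, e in tx.cds_intervals
    ]
    return np.concatenate(parts)


class _Planter:
    """Places mutations at fresh genomic positions."""

    def __init__(
        self,
        config: SimulationConfig,
        reference: Mapping[str, str],
        transcripts: Sequence[Transcript],
        rng: np.random.Generator,
    ) -> None:
        self.config = config
        self.rng = rng
        self.seq = reference["chr1"]
        self.anchors = _homopolymer_anchors(self.seq)
        self.coding_positions = _coding_position_array(transcripts)
        self.used: set[int] = set()
        self._tx_by_pos = sorted(
            (tx.span[0], tx.span[1], tx) for tx in transcripts
        )
        self.transcripts = transcripts

    def reserve(self, positions: Sequence[int]) -> None:
        self.used.update(positions)

    def _locate(self, pos: int) -> tuple[bool, str | None, int | None]:
        from .annotate import cds_offset

        for start, end, tx in self._tx_by_pos:
            if start <= pos < end:
                off = cds_offset(tx, pos)
                if off is None:
                    return False, tx.gene, None
                return True, tx.gene, off // 3 + 1
        return False, None, None

    def passenger(self, coding_only: bool = False) -> tuple[VariantKey, bool, str | None, int | None]:
        rng = self.rng
        if not coding_only and rng.random() < self.config.indel_fraction and self.anchors:
            for _ in range(100):
                anchor, base = self.anchors[int(rng.integers(0, len(self.anchors)))]
                if anchor in self.used or self.seq[anchor] not in "ACGT":
                    continue
                self.used.add(anchor)
                ref_base = self.seq[anchor]
                if rng.random() < 0.5:
                    key = VariantKey("chr1", anchor + 1, ref_base + base, ref_base)
                else:
                    key = VariantKey("chr1", anchor + 1, ref_base, ref_base + base)
                coding, gene, codon = self._locate(anchor + 1)
                return key, coding, gene, codon
        for _ in range(10000):
            if coding_only:
                pos = int(
                    self.coding_positions[int(rng.integers(0, len(self.coding_positions)))]
                )
            else:
                pos = int(rng.integers(0, len(self.seq)))
            if pos in self.used:
                continue
            ref = self.seq[pos]
            if ref not in "ACGT":
                continue
            self.used.add(pos)
            alt = _snv_alt(rng, ref, self.config.transition_fraction)
            coding, gene, codon = self._locate(pos)
            return VariantKey("chr1", pos + 1, ref, alt), coding, gene, codon
        raise RuntimeError("could not place mutation; genome too saturated")


def simulate_screen(config: SimulationConfig, out_dir: str | Path) -> ScreenSimulation:
    """Generate the panel (VCF + FASTA + gene models on disk) and its truth set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    reference, transcripts = build_genome(config.genome, rng)
    tx_by_gene = {tx.gene: tx for tx in transcripts}

    parental = "A673-M1"
    clones = tuple(f"TK216-{chr(65 + i)}" for i in range(config.n_clones))
    counters = tuple(f"MLN-{i + 1}" for i in range(config.counter_screen_n))
    samples = (parental, *clones, *counters)

    registry: dict[VariantKey, _SimVariant] = {}
    planter = _Planter(config, reference, transcripts, rng)

    # drivers first so passengers cannot stack on driver codons
    if config.driver_spec is not None:
        tx = tx_by_gene.get(config.driver_spec.gene)
        if tx is None:
            raise ConfigurationError(
                f"driver gene {config.driver_spec.gene!r} not in genome"
            )
        for m in config.driver_spec.mutations:
            key, gpos = _driver_snv(tx, reference, m)
            planter.reserve(range(gpos - 2, gpos + 3))
            sv = registry.get(key)
            if sv is None:
                sv = _SimVariant(
                    key=key, true_vaf={}, zygosity=m.zygosity, coding=True,
                    gene=config.driver_spec.gene, codon_index=m.codon_index,
                    is_driver=True,
                )
                registry[key] = sv
            sv.true_vaf[clones[m.clone]] = m.zygosity

    # shared lineage branch between the related pair (coding mutations,
    # mirroring the shared *somatic* count the analysis measures)
    if config.related_pair is not None:
        i, j, branch_size = config.related_pair
        for _ in range(branch_size):
            key, coding, gene, codon = planter.passenger(coding_only=True)
            zyg = ZYGOSITIES[int(rng.choice(len(ZYGOSITIES), p=_ZYGOSITY_PROBS))]
            registry[key] = _SimVariant(
                key=key, true_vaf={clones[i]: zyg, clones[j]: zyg},
                zygosity=zyg, coding=coding, gene=gene, codon_index=codon,
                is_branch=True,
            )

    # private passengers per clone and counter-screen sample
    for sample in (*clones, *counters):
        n = int(rng.poisson(config.lambda_passenger))
        for _ in range(n):
            key, coding, gene, codon = planter.passenger()
            zyg = ZYGOSITIES[int(rng.choice(len(ZYGOSITIES), p=_ZYGOSITY_PROBS))]
            registry[key] = _SimVariant(
                key=key, true_vaf={sample: zyg}, zygosity=zyg,
                coding=coding, gene=gene, codon_index=codon,
            )

    # heterozygous parental background, present in every descendant sample
    for _ in range(config.n_background):
        key, coding, gene, codon = planter.passenger()
        registry[key] = _SimVariant(
            key=key, true_vaf={s: 0.5 for s in samples}, zygosity=0.5,
            coding=coding, gene=gene, codon_index=codon, is_background=True,
        )

    # parental low-frequency artifact sites
    n_artifacts = int(rng.poisson(config.parental_error_rate * len(reference["chr1"])))
    for _ in range(n_artifacts):
        key, coding, gene, codon = planter.passenger()
        vaf = float(rng.uniform(0.002, 0.009))
        registry[key] = _SimVariant(
            key=key, true_vaf={parental: vaf}, zygosity=0.0,
            coding=coding, gene=gene, codon_index=codon, is_artifact=True,
        )

    records = _sample_reads(registry, samples, config, rng)

    panel = CloneScreenPanel(
        parental=parental, clones=clones, counter_screen=counters,
        records=tuple(records),
    )
    truth = _build_truth(registry, clones)

    fasta_path = write_reference(reference, out_dir / "reference.fa")
    gene_models_path = write_gene_models(transcripts, out_dir / "gene_models.tsv")
    vcf_path = write_vcf(
        panel, out_dir / "panel.vcf",
        contig_lengths={"chr1": len(reference["chr1"])},
    )
    truth_path = _write_truth_json(truth, config, out_dir / "truth.json")
    return ScreenSimulation(
        panel=panel, truth=truth, reference=reference,
        transcripts=tuple(transcripts), vcf_path=vcf_path,
        fasta_path=fasta_path, gene_models_path=gene_models_path,
        truth_path=truth_path,
    )


_FAIL_MODES = ("qd", "fs", "mq", "dp", "gq")


def _sample_reads(
    registry: dict[VariantKey, _SimVariant],
    samples: tuple[str, ...],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    records = []
    for key in sorted(registry):
        sv = registry[key]
        # pass-region annotation draws
        qd = round(float(rng.uniform(15, 35)), 2)
        fs = round(float(min(rng.exponential(3.0), 59.0)), 3)
        mq = round(float(rng.uniform(55, 60)), 2)
        fail_sample = None
        if not sv.is_driver and rng.random() < config.filter_fail_fraction:
            mode = _FAIL_MODES[int(rng.integers(0, len(_FAIL_MODES)))]
            sv.fail_mode = mode
            if mode == "qd":
                qd = round(float(rng.uniform(0.0, 1.9)), 2)
            elif mode == "fs":
                fs = round(float(rng.uniform(60.5, 150.0)), 3)
            elif mode == "mq":
                mq = round(float(rng.uniform(10.0, 39.5)), 2)
            else:
                carriers = sorted(sv.true_vaf) or list(samples)
                fail_sample = carriers[int(rng.integers(0, len(carriers)))]
        calls: dict[str, SampleCall] = {}
        for sample in samples:
            dp = int(rng.poisson(config.depth_mean))
            if sv.fail_mode == "dp" and sample == fail_sample:
                dp = int(rng.integers(0, 3))
            vaf = sv.true_vaf.get(sample, 0.0)
            alt = int(rng.binomial(dp, vaf)) if dp > 0 else 0
            gq = int(rng.integers(30, 100))
            if sv.fail_mode == "gq" and sample == fail_sample:
                gq = int(rng.integers(0, 7))
            calls[sample] = SampleCall(
                ref_depth=dp - alt, alt_depth=alt, dp=dp, gq=gq, called=True,
            )
        records.append(
            VariantRecord(
                key=key, site=SiteAnnotations(qd=qd, fs=fs, mq=mq), calls=calls,
            )
        )
    return records


def _build_truth(
    registry: dict[VariantKey, _SimVariant], clones: tuple[str, ...]
) -> TruthSet:
    by_clone: dict[str, list[TruthRecord]] = {c: [] for c in clones}
    for key in sorted(registry):
        sv = registry[key]
        if sv.is_background or sv.is_artifact:
            continue
        for clone in clones:
            if clone in sv.true_vaf:
                by_clone[clone].append(
                    TruthRecord(
                        key=key, true_vaf=sv.true_vaf[clone], zygosity=sv.zygosity,
                        coding=sv.coding, gene=sv.gene, codon_index=sv.codon_index,
                        is_driver=sv.is_driver, is_branch=sv.is_branch,
                        hard_filter_fail=sv.fail_mode is not None,
                    )
                )
    return TruthSet(by_clone={c: tuple(v) for c, v in by_clone.items()})


def _write_truth_json(truth: TruthSet, config: SimulationConfig, path: Path) -> Path:
    payload = {
        "seed": config.seed,
        "genome": config.genome.name,
        "lambda_passenger": config.lambda_passenger,
        "clones": {
            clone: [
                {
                    "chrom": r.key.chrom, "pos": r.key.pos,
                    "ref": r.key.ref, "alt": r.key.alt,
                    "true_vaf": round(r.true_vaf, 6), "zygosity": round(r.zygosity, 6),
                    "coding": r.coding, "gene": r.gene, "codon_index": r.codon_index,
                    "is_driver": r.is_driver, "is_branch": r.is_branch,
                    "hard_filter_fail": r.hard_filter_fail,
                }
                for r in records
            ]
            for clone, records in truth.by_clone.items()
        },
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# viability plates


def simulate_viability(
    ic50: float,
    hill: float,
    concentrations: Sequence[float],
    replicates: int = 2,
    noise_cv: float = 0.02,
    seed: int = 0,
    compound: str = "compound",
    sample: str = "sample",
    n_vehicle: int = 4,
) -> DoseResponseDataset:
    """Viability plate readings from the log-logistic model.

    Readings are model(conc) x (1 + Normal(0, noise_cv)), truncated at
    zero, with vehicle wells at the 100 level; ``noise_cv = 0`` puts
    every reading exactly on the curve.
    """
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for conc in concentrations:
        mean = loglogistic(np.log10(conc), np.log10(ic50), hill)
        readings = mean * (1.0 + rng.normal(0.0, noise_cv, size=replicates))
        points.append((float(conc), tuple(float(max(r, 0.0)) for r in readings)))
    vehicle = 100.0 * (1.0 + rng.normal(0.0, noise_cv, size=n_vehicle))
    return DoseResponseDataset(
        compound=compound, sample=sample, points=tuple(points),
        vehicle_readings=tuple(float(max(v, 0.0)) for v in vehicle),
    )
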