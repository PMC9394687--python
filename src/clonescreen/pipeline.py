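"""End-to-end orchestration of the screen and dose-response analyses.

`run_screen` takes a panel VCF, reference and gene models and emits
per-clone somatic TSVs, the relatedness matrix, and the recurrence
report; `run_dose` fits every (compound, sample) curve in a viability
table and reports fold-resistance versus a designated parental sample.
Both are deterministic given their inputs, and every threshold that
affected the output is written to the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import annotate_panel
from .dose_response import fit_normalized, fits_table, normalize_to_vehicle, read_viability_table
from .errors import ConfigurationError
from .recurrence import (
    DEFAULT_SHARE_THRESHOLD,
    RecurrenceReport,
    gene_recurrence,
    relatedness,
    write_codon_table,
    write_gene_table,
    write_relatedness_tsv,
    write_report_json,
)
from .somatic import FilterConfig, SomaticSet, acquired_somatic_set, write_somatic_tsv
from .variant_io import read_gene_models, read_reference, read_vcf

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and options for a full screen run."""

    vcf: Path
    reference: Path
    gene_models: Path
    out_dir: Path
    parental: str
    clones: tuple[str, ...]
    counter_screen: tuple[str, ...] = ()
    filters: FilterConfig = field(default_factory=FilterConfig)
    share_threshold: int = DEFAULT_SHARE_THRESHOLD
    min_clones: int = 2

    def __post_init__(self) -> None:
        for path in (self.vcf, self.reference, self.gene_models):
            if not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")


@dataclass(frozen=True)
class ScreenReportBundle:
    somatic_sets: dict[str, SomaticSet]
    report: RecurrenceReport
    candidates: tuple[str, ...]
    paths: dict[str, Path]


def _log_thresholds(config: PipelineConfig, log_path: Path) -> None:
    payload = {
        "version": __version__,
        "filters": dataclasses.asdict(config.filters),
        "share_threshold": config.share_threshold,
        "min_clones": config.min_clones,
        "inputs": {
            "vcf": str(config.vcf),
            "reference": str(config.reference),
            "gene_models": str(config.gene_models),
        },
        "samples": {
            "parental": config.parental,
            "clones": list(config.clones),
            "counter_screen": list(config.counter_screen),
        },
    }
    log_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    for key, value in sorted(dataclasses.asdict(config.filters).items()):
        log.info("filter threshold %s = %s", key, value)
    log.info("share_threshold = %d, min_clones = %d", config.share_threshold, config.min_clones)


def run_screen(config: PipelineConfig) -> ScreenReportBundle:
    """Somatic filtering, relatedness and recurrence for one panel VCF."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _log_thresholds(config, out_dir / "run_log.json")

    reference = read_reference(config.reference)
    transcripts = read_gene_models(config.gene_models)
    panel = read_vcf(
        config.vcf,
        {
            "parental": config.parental,
            "clones": list(config.clones),
            "counter_screen": list(config.counter_screen),
        },
        reference=reference,
    )
    consequences = annotate_panel(panel.records, transcripts, reference)

    paths: dict[str, Path] = {"run_log": out_dir / "run_log.json"}
    somatic_sets: dict[str, SomaticSet] = {}
    for clone in panel.clones:
        somatic = acquired_somatic_set(panel, clone, consequences, config.filters)
        somatic_sets[clone] = somatic
        paths[f"somatic_{clone}"] = write_somatic_tsv(
            somatic, out_dir / f"somatic_{clone}.tsv"
        )
        log.info("clone %s: %d acquired somatic mutations", clone, len(somatic))

    sets = [somatic_sets[c] for c in panel.clones]
    if len(sets) >= 2:
        related = relatedness(sets, config.share_threshold)
    else:
        # single clone: trivial partition, no pairwise sharing to compute
        import numpy as np

        from .recurrence import RelatednessMatrix

        related = RelatednessMatrix(
            samples=(sets[0].clone,),
            shared_counts=np.array([[len(sets[0])]]),
            related_groups=(frozenset({sets[0].clone}),),
            share_threshold=config.share_threshold,
        )
    report = gene_recurrence(sets, related)
    candidates = tuple(
        g for g in report.ranking
        if report.gene_counts[g].collapsed_count >= config.min_clones
    )

    paths["relatedness"] = write_relatedness_tsv(related, out_dir / "relatedness.tsv")
    paths["gene_table"] = write_gene_table(report, out_dir / "recurrence_genes.tsv")
    paths["codon_table"] = write_codon_table(report, out_dir / "recurrence_codons.tsv")
    paths["report_json"] = write_report_json(report, out_dir / "recurrence_report.json")
    return ScreenReportBundle(
        somatic_sets=somatic_sets, report=report, candidates=candidates, paths=paths,
    )


def run_dose(
    viability: str | Path,
    parental_sample: str,
    out_dir: str | Path,
    free_top_bottom: bool = False,
):
    """Fit every curve in a viability table; fold-resistance vs the parental."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    datasets = read_viability_table(viability)
    samples = {ds.sample for ds in datasets}
    if parental_sample not in samples:
        raise ConfigurationError(
            f"parental sample {parental_sample!r} not in viability table "
            f"(samples: {sorted(samples)})"
        )
    fits = []
    for ds in datasets:
        fit = fit_normalized(normalize_to_vehicle(ds), free_top_bottom=free_top_bottom)
        if not fit.converged:
            log.warning("curve %s / %s did not converge", ds.compound, ds.sample)
        fits.append(fit)
    table = fits_table(fits, parental_sample=parental_sample)
    table.to_csv(out_dir / "dose_response_fits.tsv", sep="\t", index=False)
    return table
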