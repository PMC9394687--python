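"""Hard filters and acquired-somatic VAF criteria.

A variant is an acquired somatic mutation of a resistant clone when it
survives the site/genotype hard filters (QD, FS, MQ, DP, GQ), is well
supported in the clone (VAF > 0.2), is absent from the parental line
(VAF < 0.01) and from every counter-screen clone (VAF < 0.05), and
falls in coding sequence. All printed inequalities are strict removal
conditions (GATK hard-filter semantics): boundary values pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .annotate import CODING_CLASSES, CodingConsequence, Consequence
from .errors import ConfigurationError
from .variant_io import CloneScreenPanel, SampleCall, VariantKey, VariantRecord, compute_vaf

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for hard filtering and the acquired-somatic definition.

    Hard-filter defaults are the standard short-variant cutoffs
    (QD < 2, FS > 60, MQ < 40, DP < 3, GQ < 7 remove a call); VAF
    thresholds define "acquired": present in the clone above 0.2,
    absent below 0.01 in the parental line and below 0.05 in each
    counter-screen sample. ``parental_min_depth`` guards against
    calling a site parental-absent with no parental coverage.
    """

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    dp_min: int = 3
    gq_min: int = 7
    vaf_clone_min: float = 0.2
    vaf_parental_max: float = 0.01
    vaf_counter_max: float = 0.05
    parental_min_depth: int = 10
    count_splice_as_coding: bool = True
    missing_annotation_fails: bool = True

    def __post_init__(self) -> None:
        for name in ("vaf_clone_min", "vaf_parental_max", "vaf_counter_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not self.vaf_parental_max <= self.vaf_counter_max <= self.vaf_clone_min:
            # unusual but legitimate (e.g. disabling criteria by setting
            # them to their extremes); warn rather than refuse
            log.warning(
                "VAF thresholds not ordered parental <= counter <= clone: %s, %s, %s",
                self.vaf_parental_max, self.vaf_counter_max, self.vaf_clone_min,
            )


def is_coding(consequence: CodingConsequence, config: FilterConfig) -> bool:
    """Whether a consequence counts as coding for the somatic definition."""
    if consequence.consequence_class in CODING_CLASSES:
        return True
    if consequence.consequence_class is Consequence.SPLICE:
        return config.count_splice_as_coding
    return False


def _passes(value, threshold, fail_when, missing_fails: bool) -> bool:
    if value is None:
        return not missing_fails
    return not fail_when(value, threshold)


def apply_hard_filters(
    panel: CloneScreenPanel, clone: str, config: FilterConfig
) -> tuple[VariantRecord, ...]:
    """Records surviving the site and clone-genotype hard filters.

    Removal is strict: qd < qd_min, fs > fs_max, mq < mq_min, clone
    dp < dp_min, clone gq < gq_min. Missing values fail or pass
    according to ``missing_annotation_fails``.
    """
    if clone not in panel.samples:
        raise ConfigurationError(f"sample {clone!r} is not in the panel")
    mf = config.missing_annotation_fails
    kept = []
    for rec in panel.records:
        call = rec.call(clone)
        ok = (
            _passes(rec.site.qd, config.qd_min, lambda v, t: v < t, mf)
            and _passes(rec.site.fs, config.fs_max, lambda v, t: v > t, mf)
            and _passes(rec.site.mq, config.mq_min, lambda v, t: v < t, mf)
            and _passes(call.dp if call.called else None, config.dp_min, lambda v, t: v < t, mf)
            and _passes(call.gq if call.called else None, config.gq_min, lambda v, t: v < t, mf)
        )
        if ok:
            kept.append(rec)
    return tuple(kept)


@dataclass(frozen=True)
class SomaticVariant:
    """One acquired somatic mutation with its audit trail."""

    key: VariantKey
    consequence: CodingConsequence
    clone_vaf: float
    parental_vaf: float
    counter_vafs: tuple[float, ...]
    provenance: tuple[str, ...]

    @property
    def max_counter_vaf(self) -> float:
        return max(self.counter_vafs, default=0.0)


@dataclass(frozen=True)
class SomaticSet:
    """A clone's acquired somatic mutations (set semantics on VariantKey)."""

    clone: str
    variants: Mapping[VariantKey, SomaticVariant]

    @property
    def keys(self) -> frozenset[VariantKey]:
        return frozenset(self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.variants


def _effective_parental_vaf(
    call: SampleCall, config: FilterConfig
) -> tuple[float | None, str]:
    """Parental VAF with the callability guard.

    Returns (vaf, note); vaf None means the site is uncallable in the
    parental line and the variant must be excluded.
    """
    depth = call.dp if call.dp is not None else call.ref_depth + call.alt_depth
    if not call.called or depth < config.parental_min_depth:
        return None, f"parental_uncallable(depth={depth if call.called else 0})"
    vaf = compute_vaf(call)
    if vaf is None:
        # covered but no allele-informative reads: treat as reference
        return 0.0, "parental_vaf=0(indeterminate,covered)"
    return vaf, f"parental_vaf={vaf:.4g}"


def acquired_somatic_set(
    panel: CloneScreenPanel,
    clone: str,
    consequences: Mapping[VariantKey, CodingConsequence],
    config: FilterConfig,
    prefiltered: Sequence[VariantRecord] | None = None,
) -> SomaticSet:
    """The clone's acquired somatic mutation set under ``config``.

    Applies the hard filters (unless ``prefiltered`` records are
    supplied) and then the VAF and coding criteria. Counter-screen
    criteria apply per counter sample; an uncovered counter sample
    contributes VAF 0.
    """
    if clone == panel.parental:
        raise ConfigurationError("clone must differ from the parental sample")
    if clone not in panel.clones and clone not in panel.counter_screen:
        raise ConfigurationError(f"sample {clone!r} is not a clone in the panel")
    records = (
        tuple(prefiltered)
        if prefiltered is not None
        else apply_hard_filters(panel, clone, config)
    )
    out: dict[VariantKey, SomaticVariant] = {}
    for rec in records:
        provenance: list[str] = ["hard_filters=pass"]
        clone_vaf = compute_vaf(rec.call(clone))
        if clone_vaf is None or clone_vaf <= config.vaf_clone_min:
            continue
        provenance.append(f"clone_vaf={clone_vaf:.4g}>{config.vaf_clone_min}")

        parental_vaf, note = _effective_parental_vaf(rec.call(panel.parental), config)
        provenance.append(note)
        if parental_vaf is None:
            log.debug("excluding %s for %s: %s", rec.key, clone, note)
            continue
        if parental_vaf >= config.vaf_parental_max:
            continue

        counter_vafs = []
        counter_ok = True
        for name in panel.counter_screen:
            vaf = compute_vaf(rec.call(name))
            vaf = 0.0 if vaf is None else vaf
            counter_vafs.append(vaf)
            if vaf >= config.vaf_counter_max:
                counter_ok = False
        if not counter_ok:
            continue
        provenance.append(f"counter_vafs<{config.vaf_counter_max}")

        consequence = consequences.get(rec.key)
        if consequence is None or not is_coding(consequence, config):
            continue
        provenance.append(f"coding={consequence.consequence_class.value}")

        out[rec.key] = SomaticVariant(
            key=rec.key,
            consequence=consequence,
            clone_vaf=clone_vaf,
            parental_vaf=parental_vaf,
            counter_vafs=tuple(counter_vafs),
            provenance=tuple(provenance),
        )
    return SomaticSet(clone=clone, variants=out)


SOMATIC_TSV_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene", "codon", "aa_change", "consequence",
    "clone_vaf", "parental_vaf", "max_counter_vaf", "filters_evaluated",
)


def write_somatic_tsv(somatic: SomaticSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(SOMATIC_TSV_COLUMNS) + "\n")
        for key in sorted(somatic.variants):
            v = somatic.variants[key]
            c = v.consequence
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        key.chrom, key.pos, key.ref, key.alt,
                        c.gene or ".", c.codon_index or ".", c.aa_change or ".",
                        c.consequence_class.value,
                        f"{v.clone_vaf:.4f}", f"{v.parental_vaf:.4f}",
                        f"{v.max_counter_vaf:.4f}", ";".join(v.provenance),
                    )
                )
                + "\n"
            )
    return path
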