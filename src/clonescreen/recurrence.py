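"""Recurrently mutated genes, codon recurrence, and clone relatedness.

Clones sharing many somatic mutations descend from a common ancestor
that predates selection, so they are not independent evidence for a
candidate gene: relatedness is computed from pairwise shared-mutation
counts and each related group contributes a single "vote" to the
collapsed recurrence count. Codon-level recurrence (the same codon hit
in unrelated clones, possibly with different substitutions) is the
strongest signal of positive selection and breaks ranking ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .annotate import Consequence
from .errors import ConfigurationError, InputError
from .somatic import SomaticSet
from .variant_io import VariantKey

#: default minimum shared somatic mutations for two clones to be related;
#: sits between the observed related-pair count (91) and the maximum
#: between unrelated clones (11)
DEFAULT_SHARE_THRESHOLD = 20


def shared_count(a: SomaticSet, b: SomaticSet) -> int:
    """Number of somatic mutations shared by exact VariantKey equality."""
    return len(a.keys & b.keys)


@dataclass(frozen=True)
class RelatednessMatrix:
    """Pairwise shared-mutation counts and the induced clone partition."""

    samples: tuple[str, ...]
    shared_counts: np.ndarray  # symmetric; diagonal = somatic-set sizes
    related_groups: tuple[frozenset[str], ...]
    share_threshold: int

    def group_of(self, clone: str) -> frozenset[str]:
        for group in self.related_groups:
            if clone in group:
                return group
        raise KeyError(clone)

    def are_related(self, a: str, b: str) -> bool:
        return a != b and b in self.group_of(a)

    def pair_count(self, a: str, b: str) -> int:
        i, j = self.samples.index(a), self.samples.index(b)
        return int(self.shared_counts[i, j])


def relatedness(
    sets: Sequence[SomaticSet], share_threshold: int = DEFAULT_SHARE_THRESHOLD
) -> RelatednessMatrix:
    """Pairwise shared counts; groups are connected components of the
    "shares >= threshold" graph (transitive closure of pairwise relatedness).
    """
    if len(sets) < 2:
        raise InputError("relatedness requires at least 2 clones")
    names = [s.clone for s in sets]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate clone names: {names}")
    n = len(sets)
    matrix = np.zeros((n, n), dtype=int)
    graph = nx.Graph()
    graph.add_nodes_from(names)
    for i in range(n):
        matrix[i, i] = len(sets[i])
        for j in range(i + 1, n):
            c = shared_count(sets[i], sets[j])
            matrix[i, j] = matrix[j, i] = c
            if c >= share_threshold:
                graph.add_edge(names[i], names[j])
    groups = tuple(
        sorted((frozenset(c) for c in nx.connected_components(graph)), key=min)
    )
    return RelatednessMatrix(
        samples=tuple(names), shared_counts=matrix,
        related_groups=groups, share_threshold=share_threshold,
    )


@dataclass(frozen=True)
class GeneCount:
    gene: str
    raw_count: int          # clones with >= 1 qualifying variant
    collapsed_count: int    # related groups with >= 1 mutated member
    clones: tuple[str, ...]
    consequence_classes: tuple[str, ...]
    recurrent_codons: tuple[int, ...]


@dataclass(frozen=True)
class CodonCount:
    gene: str
    codon_index: int
    substitutions: tuple[str, ...]  # distinct aa changes, e.g. ("G142A", "G142S")
    clones: tuple[str, ...]
    n_unrelated: int                # distinct related groups among the clones


@dataclass(frozen=True)
class RecurrenceReport:
    gene_counts: dict[str, GeneCount]
    codon_counts: dict[tuple[str, int], CodonCount]
    ranking: tuple[str, ...]
    relatedness: RelatednessMatrix


def gene_recurrence(
    sets: Sequence[SomaticSet], related: RelatednessMatrix
) -> RecurrenceReport:
    """Per-gene and per-codon recurrence across clones.

    A codon is recurrent when >= 2 unrelated clones (distinct related
    groups) carry a variant at the same (gene, codon_index). Genes are
    ranked by collapsed count, then number of recurrent codons, then
    name.
    """
    gene_clones: dict[str, set[str]] = {}
    gene_classes: dict[str, set[str]] = {}
    codon_hits: dict[tuple[str, int], dict[str, set[str]]] = {}
    for somatic in sets:
        for key in sorted(somatic.variants):
            v = somatic.variants[key]
            gene = v.consequence.gene
            if gene is None:
                continue
            gene_clones.setdefault(gene, set()).add(somatic.clone)
            gene_classes.setdefault(gene, set()).add(
                v.consequence.consequence_class.value
            )
            codon = v.consequence.codon_index
            if codon is not None:
                entry = codon_hits.setdefault((gene, codon), {"subs": set(), "clones": set()})
                entry["clones"].add(somatic.clone)
                if v.consequence.aa_change is not None:
                    entry["subs"].add(v.consequence.aa_change)

    def n_groups(clones: Iterable[str]) -> int:
        return len({related.group_of(c) for c in clones})

    codon_counts = {
        (gene, codon): CodonCount(
            gene=gene, codon_index=codon,
            substitutions=tuple(sorted(entry["subs"])),
            clones=tuple(sorted(entry["clones"])),
            n_unrelated=n_groups(entry["clones"]),
        )
        for (gene, codon), entry in sorted(codon_hits.items())
    }

    gene_counts: dict[str, GeneCount] = {}
    for gene in sorted(gene_clones):
        clones = tuple(sorted(gene_clones[gene]))
        recurrent = tuple(
            codon
            for (g, codon), cc in sorted(codon_counts.items())
            if g == gene and cc.n_unrelated >= 2
        )
        gene_counts[gene] = GeneCount(
            gene=gene,
            raw_count=len(clones),
            collapsed_count=n_groups(clones),
            clones=clones,
            consequence_classes=tuple(sorted(gene_classes[gene])),
            recurrent_codons=recurrent,
        )

    ranking = tuple(
        sorted(
            gene_counts,
            key=lambda g: (
                -gene_counts[g].collapsed_count,
                -len(gene_counts[g].recurrent_codons),
                g,
            ),
        )
    )
    return RecurrenceReport(
        gene_counts=gene_counts, codon_counts=codon_counts,
        ranking=ranking, relatedness=related,
    )


def rank_candidates(report: RecurrenceReport, min_clones: int) -> tuple[str, ...]:
    """Genes whose collapsed count reaches ``min_clones``, in ranking order."""
    return tuple(
        g for g in report.ranking
        if report.gene_counts[g].collapsed_count >= min_clones
    )


def write_gene_table(report: RecurrenceReport, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "gene\traw_count\tcollapsed_count\tclones\tconsequence_classes\t"
            "recurrent_codons\n"
        )
        for gene in report.ranking:
            gc = report.gene_counts[gene]
            fh.write(
                f"{gene}\t{gc.raw_count}\t{gc.collapsed_count}\t"
                f"{','.join(gc.clones)}\t{','.join(gc.consequence_classes)}\t"
                f"{','.join(map(str, gc.recurrent_codons)) or '.'}\n"
            )
    return path


def write_codon_table(report: RecurrenceReport, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene\tcodon\tsubstitutions\tclones\tn_unrelated\n")
        for (gene, codon), cc in sorted(report.codon_counts.items()):
            fh.write(
                f"{gene}\t{codon}\t{','.join(cc.substitutions) or '.'}\t"
                f"{','.join(cc.clones)}\t{cc.n_unrelated}\n"
            )
    return path


def write_relatedness_tsv(matrix: RelatednessMatrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("clone\t" + "\t".join(matrix.samples) + "\n")
        for i, name in enumerate(matrix.samples):
            fh.write(name + "\t" + "\t".join(map(str, matrix.shared_counts[i])) + "\n")
    return path


def write_report_json(report: RecurrenceReport, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "share_threshold": report.relatedness.share_threshold,
        "related_groups": [sorted(g) for g in report.relatedness.related_groups],
        "shared_counts": {
            "samples": list(report.relatedness.samples),
            "matrix": report.relatedness.shared_counts.tolist(),
        },
        "ranking": list(report.ranking),
        "genes": {
            gene: {
                "raw_count": gc.raw_count,
                "collapsed_count": gc.collapsed_count,
                "clones": list(gc.clones),
                "consequence_classes": list(gc.consequence_classes),
                "recurrent_codons": list(gc.recurrent_codons),
            }
            for gene, gc in report.gene_counts.items()
        },
        "codons": [
            {
                "gene": cc.gene,
                "codon": cc.codon_index,
                "substitutions": list(cc.substitutions),
                "clones": list(cc.clones),
                "n_unrelated": cc.n_unrelated,
            }
            for cc in report.codon_counts.values()
        ],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
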