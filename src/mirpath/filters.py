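"""Expression / intragenic filtering and the random-pathway control.

Two biological filters narrow the analyzed miRNA set: (1) keep miRNAs with
documented expression in the relevant tissue or cell types; (2) keep
intragenic miRNAs hosted by a gene (or extension TF) belonging to one of
the studied pathways, since intragenic miRNAs tend to be co-expressed with
their host.  Filtering touches membership only — never a p-value.

The random-pathway control replays the whole enrichment pipeline on a
random draw of pathways from a large pool; a sharp drop in the number of
selected miRNAs relative to the curated pathway list indicates that the
selection is specific to that list rather than an artifact of the method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ParseError, ValidationError
from .gene_sets import PathwayRecord, RelevanceClass, normalize_gene
from .targets import TargetMap
from .enrichment import EnrichmentResult, enrichment_analysis

log = logging.getLogger(__name__)

#: Tissue / cell vocabulary used by the expression filter by default.
DEFAULT_TISSUES: tuple[str, ...] = (
    "lung tissue",
    "B lymphocytes",
    "natural killer lymphocytes",
    "monocytes",
    "dendritic cells",
    "granulocytes",
    "A549",
)

CLASS_POLICIES = ("preserve_proportions", "all_B")


def load_expression_table(
    path: str | Path, vocabulary: Iterable[str] | None = None
) -> dict[str, frozenset[str]]:
    """Read a (mirna, tissue) TSV with header; labels outside the active
    vocabulary are rejected."""
    vocab = frozenset(DEFAULT_TISSUES if vocabulary is None else vocabulary)
    records: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: missing header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(f"{path}:{lineno}: expected 'mirna<TAB>tissue'")
            tissue = parts[1].strip()
            if tissue not in vocab:
                raise ValidationError(
                    f"{path}:{lineno}: tissue label {tissue!r} not in the "
                    "declared vocabulary"
                )
            records.setdefault(parts[0].strip(), set()).add(tissue)
    return {m: frozenset(t) for m, t in records.items()}


def load_host_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a (host_gene, mirna) TSV with header into host → miRNA sets."""
    records: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: missing header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected 'host_gene<TAB>mirna'"
                )
            records.setdefault(normalize_gene(parts[0]), set()).add(
                parts[1].strip()
            )
    return {g: frozenset(m) for g, m in records.items()}


def expression_filter(
    mirnas: Iterable[str],
    table: Mapping[str, frozenset[str]],
    vocabulary: Iterable[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Retain miRNAs with >= 1 tissue label in the active vocabulary,
    annotated with those labels."""
    vocab = frozenset(DEFAULT_TISSUES if vocabulary is None else vocabulary)
    out = {}
    for m in mirnas:
        labels = frozenset(table.get(m, frozenset())) & vocab
        if labels:
            out[m] = labels
    return out


def intragenic_filter(
    mirnas: Iterable[str],
    pathways: Sequence[PathwayRecord],
    hosts: Mapping[str, frozenset[str]],
) -> dict[str, frozenset[str]]:
    """Retain miRNAs hosted by any gene (core or TF) of the pathways,
    annotated with their hosting gene(s)."""
    pathway_genes: set[str] = set()
    for pw in pathways:
        pathway_genes |= pw.extended_genes
    hosted_by: dict[str, set[str]] = {}
    for gene, hosted in hosts.items():
        if gene in pathway_genes:
            for m in hosted:
                hosted_by.setdefault(m, set()).add(gene)
    return {
        m: frozenset(hosted_by[m]) for m in mirnas if m in hosted_by
    }


def candidate_set(
    expr_pass: Mapping[str, frozenset[str]],
    intragenic_pass: Mapping[str, frozenset[str]],
    mode: str = "union",
) -> dict[str, frozenset[str]]:
    """Combine the two filter criteria; values record which criterion
    admitted each miRNA ('expression', 'intragenic' or both)."""
    if mode not in ("union", "intersection"):
        raise ValidationError("mode must be 'union' or 'intersection'")
    names = (
        set(expr_pass) | set(intragenic_pass)
        if mode == "union"
        else set(expr_pass) & set(intragenic_pass)
    )
    out = {}
    for m in sorted(names):
        prov = set()
        if m in expr_pass:
            prov.add("expression")
        if m in intragenic_pass:
            prov.add("intragenic")
        out[m] = frozenset(prov)
    return out


@dataclass
class ControlResult:
    """Outcome of a random-pathway control run."""

    sampled_ids: list[str]
    class_labels: dict[str, str]
    seed: int
    result: EnrichmentResult


def random_control(
    pool: Sequence[PathwayRecord],
    tmap: TargetMap,
    k: int = 39,
    class_policy: str = "preserve_proportions",
    class_proportions: Mapping[str, float] | None = None,
    seed: int = 0,
    weights: Mapping[str, float] | None = None,
    **analysis_kwargs,
) -> ControlResult:
    """Run the full pipeline on ``k`` pathways sampled from ``pool``.

    Random pathways carry no curated relevance class, so one is assigned:
    ``preserve_proportions`` samples labels matching the curated list's
    A/B/C proportions (uniform thirds when none are given), ``all_B``
    assigns every sampled pathway the middle class.
    """
    if class_policy not in CLASS_POLICIES:
        raise ValidationError(f"class policy must be one of {CLASS_POLICIES}")
    if k < 1 or k > len(pool):
        raise ValidationError(
            f"cannot sample k={k} pathways from a pool of {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    sampled = [pool[i] for i in idx]
    if class_policy == "all_B":
        labels = ["B"] * k
    else:
        props = class_proportions or {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}
        keys = sorted(props)
        pvec = np.array([props[c] for c in keys], dtype=float)
        pvec = pvec / pvec.sum()
        labels = [keys[i] for i in rng.choice(len(keys), size=k, p=pvec)]
    relabeled = [
        PathwayRecord(
            pathway_id=pw.pathway_id,
            name=pw.name,
            relevance=RelevanceClass.from_label(lab, weights),
            core_genes=pw.core_genes,
            tf_genes=pw.tf_genes,
        )
        for pw, lab in zip(sampled, labels)
    ]
    analysis_kwargs.setdefault("seed", seed)
    result = enrichment_analysis(relabeled, tmap, **analysis_kwargs)
    return ControlResult(
        sampled_ids=[pw.pathway_id for pw in relabeled],
        class_labels={pw.pathway_id: lab for pw, lab in zip(relabeled, labels)},
        seed=seed,
        result=result,
    )
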