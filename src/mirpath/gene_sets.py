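"""Pathway gene sets with curator-assigned relevance classes and TF extension.

A pathway is a named set of gene symbols plus a relevance class (A, B or C)
that encodes how specific the pathway is believed to be for the disease
process under study.  Classes map to the weights used later when per-pathway
p-values are combined: highly specific pathways (A) weigh 2.0 — the weight at
which the weighted combination reduces to Fisher's classical combined
probability test — general-but-relevant pathways (B) weigh 1.0, and very
general pathways (C) weigh 0.5.

Because miRNAs frequently act on a gene indirectly, by repressing one of its
transcription factors, each pathway is extended with the upstream regulators
of its member genes before any counting happens.  The extension is a single
pass over an explicit regulator→target edge table: TFs of core genes are
added, TFs of TFs are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ParseError, ValidationError

#: Default relevance-class → Lancaster-weight mapping.
DEFAULT_CLASS_WEIGHTS: Mapping[str, float] = {"A": 2.0, "B": 1.0, "C": 0.5}


def normalize_gene(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Gene identity throughout the package is exact string equality after this
    single normalization; no identifier conversion is attempted.
    """
    sym = symbol.strip().upper()
    if not sym:
        raise ValidationError("empty gene symbol")
    return sym


@dataclass(frozen=True)
class RelevanceClass:
    """A pathway relevance label with its combination weight."""

    label: str
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError(
                f"relevance weight must be positive, got {self.weight}"
            )

    @classmethod
    def from_label(
        cls, label: str, weights: Mapping[str, float] | None = None
    ) -> "RelevanceClass":
        table = DEFAULT_CLASS_WEIGHTS if weights is None else weights
        label = label.strip()
        if label not in table:
            raise ValidationError(
                f"unknown relevance class {label!r}; expected one of "
                f"{sorted(table)}"
            )
        return cls(label=label, weight=float(table[label]))


@dataclass(frozen=True)
class PathwayRecord:
    """A pathway: core members, TF extension, and relevance class.

    ``extended_genes`` is always the union of core and TF members; a TF that
    is already a core gene collapses under the union.
    """

    pathway_id: str
    name: str
    relevance: RelevanceClass
    core_genes: frozenset[str]
    tf_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.core_genes:
            raise ValidationError(
                f"pathway {self.pathway_id!r} has no core genes"
            )

    @property
    def extended_genes(self) -> frozenset[str]:
        return self.core_genes | self.tf_genes

    @property
    def weight(self) -> float:
        return self.relevance.weight


@dataclass(frozen=True)
class TfEdgeTable:
    """Directed regulator→target edges; duplicate pairs collapse."""

    edges: frozenset[tuple[str, str]]

    def regulators_of(self, genes: Iterable[str]) -> frozenset[str]:
        """All regulators with at least one target in ``genes``."""
        targets = set(genes)
        return frozenset(r for r, t in self.edges if t in targets)


def load_class_table(
    path: str | Path, weights: Mapping[str, float] | None = None
) -> dict[str, RelevanceClass]:
    """Read a headerless two-column TSV mapping pathway_id → class label."""
    classes: dict[str, RelevanceClass] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected 'pathway_id<TAB>class'"
                )
            pid = parts[0].strip()
            if pid in classes:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate pathway id {pid!r}"
                )
            classes[pid] = RelevanceClass.from_label(parts[1], weights)
    return classes


def load_pathways(
    gene_set_path: str | Path,
    class_table_path: str | Path,
    weights: Mapping[str, float] | None = None,
) -> list[PathwayRecord]:
    """Load pathways from a GMT file plus a relevance-class table.

    GMT dialect: one pathway per line, tab-separated — identifier,
    description, then one or more member gene symbols.  Every pathway must
    have a class entry; records come back with an empty TF extension.
    """
    classes = load_class_table(class_table_path, weights)
    records: list[PathwayRecord] = []
    seen: set[str] = set()
    with open(gene_set_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0].strip():
                raise ParseError(
                    f"{gene_set_path}:{lineno}: malformed GMT line "
                    "(need id, description, >=1 gene)"
                )
            pid = parts[0].strip()
            if pid in seen:
                raise ValidationError(
                    f"{gene_set_path}:{lineno}: duplicate pathway id {pid!r}"
                )
            seen.add(pid)
            if pid not in classes:
                raise ValidationError(
                    f"{gene_set_path}:{lineno}: pathway {pid!r} has no "
                    "relevance-class entry"
                )
            genes = frozenset(normalize_gene(g) for g in parts[2:] if g.strip())
            if not genes:
                raise ParseError(
                    f"{gene_set_path}:{lineno}: pathway {pid!r} lists no genes"
                )
            records.append(
                PathwayRecord(
                    pathway_id=pid,
                    name=parts[1].strip(),
                    relevance=classes[pid],
                    core_genes=genes,
                )
            )
    return records


def load_tf_edges(path: str | Path) -> TfEdgeTable:
    """Read a regulator→target edge table (two-column TSV with header)."""
    edges: set[tuple[str, str]] = set()
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
                    f"{path}:{lineno}: expected 'regulator<TAB>target'"
                )
            edges.add((normalize_gene(parts[0]), normalize_gene(parts[1])))
    return TfEdgeTable(edges=frozenset(edges))


def extend_with_tfs(
    pathways: Iterable[PathwayRecord], edges: TfEdgeTable
) -> list[PathwayRecord]:
    """Attach to each pathway the regulators of its core genes.

    Single-pass, one level deep: only regulators of *core* genes are added,
    never regulators of regulators, so re-running on the output (restricted
    to core targets) is a no-op.  Core membership is never modified.
    """
    out = []
    for pw in pathways:
        tf = edges.regulators_of(pw.core_genes)
        out.append(replace(pw, tf_genes=tf))
    return out
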