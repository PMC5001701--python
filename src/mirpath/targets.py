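"""miRNA→target maps and the target universe used as statistical background.

Two modes carry the same structure: VMT (experimentally validated targets)
and CMT (computationally predicted targets, supplied pre-aggregated across
prediction repositories and typically a superset of the VMT sets).  The
*target universe* — the union of all miRNAs' target sets — is the background
population of the enrichment tests: a gene that has never been annotated as
anybody's target carries no information about targeting and is excluded from
every contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import ParseError, ValidationError
from .gene_sets import normalize_gene

MODES = ("VMT", "CMT")


@dataclass(frozen=True)
class TargetMap:
    """miRNA name → target gene set, tagged with its evidence mode."""

    mode: str
    targets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")

    def nonempty(self) -> dict[str, frozenset[str]]:
        """Target sets that can actually be scored (at least one target)."""
        return {m: t for m, t in self.targets.items() if t}


def load_alias_table(path: str | Path) -> dict[str, str]:
    """Read an old-name → new-name miRNA alias table (TSV with header).

    The mapping must be functional and acyclic; chains (a→b, b→c) are
    allowed and resolved to the terminal name.
    """
    raw: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: missing header line")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(f"{path}:{lineno}: expected 'old<TAB>new'")
            old, new = parts[0].strip(), parts[1].strip()
            if old in raw and raw[old] != new:
                raise ValidationError(
                    f"{path}:{lineno}: alias {old!r} maps to two names"
                )
            raw[old] = new
    # resolve chains, refuse cycles
    resolved: dict[str, str] = {}
    for old in raw:
        seen = [old]
        cur = old
        while cur in raw:
            cur = raw[cur]
            if cur in seen:
                raise ValidationError(f"alias cycle through {cur!r}")
            seen.append(cur)
        resolved[old] = cur
    return resolved


def resolve_alias(name: str, aliases: Mapping[str, str] | None) -> str:
    if not aliases:
        return name
    return aliases.get(name, name)


def load_target_map(
    path: str | Path,
    mode: str,
    aliases: Mapping[str, str] | None = None,
) -> TargetMap:
    """Load a (mirna, gene) TSV (with header) into a grouped target map.

    Alias renaming is applied to miRNA names *before* grouping, so rows
    filed under a deprecated name merge with rows under the current one.
    """
    grouped: dict[str, set[str]] = {}
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
                    f"{path}:{lineno}: expected 'mirna<TAB>gene' with both "
                    "fields non-empty"
                )
            mirna = resolve_alias(parts[0].strip(), aliases)
            grouped.setdefault(mirna, set()).add(normalize_gene(parts[1]))
    return TargetMap(
        mode=mode, targets={m: frozenset(g) for m, g in grouped.items()}
    )


def build_universe(tmap: TargetMap) -> frozenset[str]:
    """Union of all miRNAs' target sets — the background population."""
    if not tmap.targets:
        raise ValidationError("target map is empty")
    universe: set[str] = set()
    for genes in tmap.targets.values():
        universe |= genes
    if not universe:
        raise ValidationError(
            "every target set is empty; no statistical background exists"
        )
    return frozenset(universe)
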