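"""Seeded synthetic inputs with controllable planted enrichment.

The generator emulates every input the pipeline consumes — pathway gene
sets with relevance classes, a TF edge table, validated (VMT) and
computational (CMT) target maps, a tissue-expression table and an
intragenic host-gene table — entirely offline, with deterministic names
(G000001…, mir-0001…) so fixtures diff cleanly and the same scenario +
seed reproduces byte-identical files.

Enrichment signal is planted by biased target sampling: a planted miRNA
draws each target with sampling weight ``enrichment_odds`` on the genes of
its planted pathways and weight 1 elsewhere, so the expected in-pathway
target count is |T|·(odds·|P|)/(odds·|P| + |U\\P|).  Pathway overlap is
controlled through a shared gene pool: each pathway takes a fraction
f = 2j/(1+j) of its members from the pool, giving expected pairwise
Jaccard ≈ j; j = 0 carves exactly disjoint pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .filters import DEFAULT_TISSUES
from .gene_sets import PathwayRecord, RelevanceClass, TfEdgeTable
from .targets import TargetMap
from .enrichment import MiRNAScore


@dataclass(frozen=True)
class PlantedSignal:
    """One miRNA enriched in a set of pathways with a given odds ratio."""

    mirna: str
    pathway_ids: tuple[str, ...]
    enrichment_odds: float

    def __post_init__(self) -> None:
        if self.enrichment_odds < 1.0:
            raise ValidationError("enrichment_odds must be >= 1")
        if not self.pathway_ids:
            raise ValidationError("planted signal needs >= 1 pathway")


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterization of one synthetic study.

    Defaults describe a realistically sized desk-scale study: a 4000-gene
    annotated background, 39 pathways of 25-60 genes split evenly across
    the three relevance classes, and 500 miRNAs with 100-300 targets each.
    """

    n_genes: int = 4000
    n_pathways: int = 39
    pathway_size_range: tuple[int, int] = (25, 60)
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}
    )
    overlap_jaccard: float = 0.0
    n_mirnas: int = 500
    target_size_range: tuple[int, int] = (100, 300)
    planted: tuple[PlantedSignal, ...] = ()
    tf_edge_density: float = 0.01
    expression_coverage: float = 0.8
    intragenic_fraction: float = 0.3
    cmt_extra_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        tlo, thi = self.target_size_range
        if not (0 < lo <= hi) or not (0 < tlo <= thi):
            raise ValidationError("size ranges must be non-degenerate")
        if not 0 <= self.overlap_jaccard < 1:
            raise ValidationError("overlap_jaccard must lie in [0, 1)")
        if hi > self.n_genes or thi > self.n_genes:
            raise ValidationError("sizes exceed the gene universe")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValidationError("class proportions must sum to 1")
        for frac in (self.tf_edge_density, self.expression_coverage,
                     self.intragenic_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must lie in [0, 1]")
        ids = {f"P{i + 1:03d}" for i in range(self.n_pathways)}
        for sig in self.planted:
            missing = set(sig.pathway_ids) - ids
            if missing:
                raise ValidationError(
                    f"planted pathways {sorted(missing)} do not exist"
                )

    def class_label(self, pathway_index: int) -> str:
        """Deterministic block assignment: A-block first, then B, then C."""
        labels = sorted(self.class_proportions)
        bounds, acc = [], 0.0
        for lab in labels:
            acc += self.class_proportions[lab]
            bounds.append(round(acc * self.n_pathways))
        for lab, b in zip(labels, bounds):
            if pathway_index < b:
                return lab
        return labels[-1]

    def class_a_ids(self) -> list[str]:
        return [
            f"P{i + 1:03d}"
            for i in range(self.n_pathways)
            if self.class_label(i) == "A"
        ]


def planted_scenario(
    n_planted: int = 10,
    pathways_each: int = 3,
    enrichment_odds: float = 5.0,
    **kwargs,
) -> SyntheticScenario:
    """Scenario with ``n_planted`` miRNAs each enriched (round-robin) in
    ``pathways_each`` class-A pathways."""
    base = SyntheticScenario(**kwargs)
    a_ids = base.class_a_ids()
    if len(a_ids) < pathways_each:
        raise ValidationError("not enough class-A pathways to plant into")
    planted = []
    for i in range(n_planted):
        ids = tuple(
            a_ids[(pathways_each * i + j) % len(a_ids)]
            for j in range(pathways_each)
        )
        planted.append(
            PlantedSignal(
                mirna=f"mir-{i + 1:04d}",
                pathway_ids=ids,
                enrichment_odds=enrichment_odds,
            )
        )
    return SyntheticScenario(**{**kwargs, "planted": tuple(planted)})


@dataclass
class SyntheticDataset:
    """In-memory realization of a scenario."""

    scenario: SyntheticScenario
    genes: list[str]
    pathways: list[PathwayRecord]     # tf_genes empty; extend at analysis
    tf_edges: TfEdgeTable
    vmt: TargetMap
    cmt: TargetMap
    expression: dict[str, frozenset[str]]
    hosts: dict[str, frozenset[str]]
    truth: list[PlantedSignal]


def simulate(scenario: SyntheticScenario) -> SyntheticDataset:
    """Draw one dataset; identical scenario + seed → identical dataset."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    genes = [f"G{i:06d}" for i in range(1, sc.n_genes + 1)]
    gene_arr = np.arange(sc.n_genes)

    # --- pathways -----------------------------------------------------
    lo, hi = sc.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=sc.n_pathways)
    j = sc.overlap_jaccard
    member_idx: list[np.ndarray] = []
    if j == 0.0:
        if int(sizes.sum()) > sc.n_genes:
            raise ValidationError(
                f"disjoint pathways need {int(sizes.sum())} genes but the "
                f"universe has {sc.n_genes}"
            )
        perm = rng.permutation(sc.n_genes)
        off = 0
        for s in sizes:
            member_idx.append(np.sort(perm[off:off + s]))
            off += int(s)
    else:
        f = 2.0 * j / (1.0 + j)
        pool_size = max(1, round(f * float(sizes.mean())))
        shared = np.minimum(np.round(f * sizes).astype(int), pool_size)
        private = sizes - shared
        if pool_size + int(private.sum()) > sc.n_genes:
            raise ValidationError(
                f"overlap {j} with these sizes needs "
                f"{pool_size + int(private.sum())} genes but the universe "
                f"has {sc.n_genes}"
            )
        perm = rng.permutation(sc.n_genes)
        pool = perm[:pool_size]
        off = pool_size
        for s_shared, s_priv in zip(shared, private):
            take = rng.choice(pool, size=int(s_shared), replace=False)
            priv = perm[off:off + int(s_priv)]
            off += int(s_priv)
            member_idx.append(np.sort(np.concatenate([take, priv])))

    pathways = []
    for i, idx in enumerate(member_idx):
        pid = f"P{i + 1:03d}"
        pathways.append(
            PathwayRecord(
                pathway_id=pid,
                name=f"synthetic pathway {pid}",
                relevance=RelevanceClass.from_label(sc.class_label(i)),
                core_genes=frozenset(genes[k] for k in idx),
            )
        )

    # --- TF edges -----------------------------------------------------
    n_tfs = max(5, round(0.05 * sc.n_genes))
    tf_idx = rng.choice(sc.n_genes, size=n_tfs, replace=False)
    n_edges = round(sc.tf_edge_density * n_tfs * sc.n_genes)
    edges: set[tuple[str, str]] = set()
    if n_edges:
        flat = rng.choice(n_tfs * sc.n_genes, size=n_edges, replace=False)
        for e in flat:
            edges.add((genes[tf_idx[e // sc.n_genes]], genes[e % sc.n_genes]))
    tf_edges = TfEdgeTable(edges=frozenset(edges))

    # --- target maps ---------------------------------------------------
    planted_by_name = {p.mirna: p for p in sc.planted}
    tlo, thi = sc.target_size_range
    vmt: dict[str, frozenset[str]] = {}
    cmt: dict[str, frozenset[str]] = {}
    # plant into the TF-extended sets: enrichment_odds is defined relative
    # to the gene set the analysis will actually test
    extended_by_id = {
        pw.pathway_id: pw.core_genes | tf_edges.regulators_of(pw.core_genes)
        for pw in pathways
    }
    gene_pos = {g: i for i, g in enumerate(genes)}
    for m in range(1, sc.n_mirnas + 1):
        name = f"mir-{m:04d}"
        s = int(rng.integers(tlo, thi + 1))
        sig = planted_by_name.get(name)
        if sig is None:
            idx = rng.choice(gene_arr, size=s, replace=False)
        else:
            in_pathway: set[int] = set()
            for pid in sig.pathway_ids:
                in_pathway.update(gene_pos[g] for g in extended_by_id[pid])
            w = np.ones(sc.n_genes)
            w[sorted(in_pathway)] = sig.enrichment_odds
            idx = rng.choice(gene_arr, size=s, replace=False, p=w / w.sum())
        v = frozenset(genes[k] for k in idx)
        extra_n = min(round(sc.cmt_extra_fraction * s), sc.n_genes - s)
        if extra_n:
            remaining = np.setdiff1d(gene_arr, idx, assume_unique=False)
            extra = rng.choice(remaining, size=extra_n, replace=False)
            c = v | frozenset(genes[k] for k in extra)
        else:
            c = v
        vmt[name] = v
        cmt[name] = c

    # --- expression and host tables ------------------------------------
    expression: dict[str, frozenset[str]] = {}
    for m in range(1, sc.n_mirnas + 1):
        name = f"mir-{m:04d}"
        if rng.random() < sc.expression_coverage:
            n_t = int(rng.integers(1, 4))
            labs = rng.choice(len(DEFAULT_TISSUES), size=n_t, replace=False)
            expression[name] = frozenset(DEFAULT_TISSUES[k] for k in labs)

    hosts: dict[str, set[str]] = {}
    n_hosted = round(sc.intragenic_fraction * sc.n_mirnas)
    hosted = rng.choice(sc.n_mirnas, size=n_hosted, replace=False)
    for m in np.sort(hosted):
        host_gene = genes[int(rng.integers(sc.n_genes))]
        hosts.setdefault(host_gene, set()).add(f"mir-{int(m) + 1:04d}")

    return SyntheticDataset(
        scenario=sc,
        genes=genes,
        pathways=pathways,
        tf_edges=tf_edges,
        vmt=TargetMap(mode="VMT", targets=vmt),
        cmt=TargetMap(mode="CMT", targets=cmt),
        expression=expression,
        hosts={g: frozenset(s) for g, s in hosts.items()},
        truth=list(sc.planted),
    )


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def generate(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture file set; returns name → path.

    Files use exactly the dialects the loaders read: GMT for pathways, a
    headerless class TSV, and headered TSVs for everything else.  All rows
    are sorted so identical scenarios produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate(scenario)
    paths = {
        "pathways": out / "pathways.gmt",
        "classes": out / "classes.tsv",
        "tf_edges": out / "tf_edges.tsv",
        "targets_vmt": out / "targets_vmt.tsv",
        "targets_cmt": out / "targets_cmt.tsv",
        "expression": out / "expression.tsv",
        "hosts": out / "hosts.tsv",
        "truth": out / "truth.tsv",
    }
    with open(paths["pathways"], "w", encoding="utf-8") as fh:
        for pw in ds.pathways:
            fh.write(
                "\t".join([pw.pathway_id, pw.name, *sorted(pw.core_genes)])
                + "\n"
            )
    with open(paths["classes"], "w", encoding="utf-8") as fh:
        for pw in ds.pathways:
            fh.write(f"{pw.pathway_id}\t{pw.relevance.label}\n")
    with open(paths["tf_edges"], "w", encoding="utf-8") as fh:
        fh.write("regulator\ttarget\n")
        for r, t in sorted(ds.tf_edges.edges):
            fh.write(f"{r}\t{t}\n")
    for key, tmap in (("targets_vmt", ds.vmt), ("targets_cmt", ds.cmt)):
        with open(paths[key], "w", encoding="utf-8") as fh:
            fh.write("mirna\tgene\n")
            for m in sorted(tmap.targets):
                for g in sorted(tmap.targets[m]):
                    fh.write(f"{m}\t{g}\n")
    with open(paths["expression"], "w", encoding="utf-8") as fh:
        fh.write("mirna\ttissue\n")
        for m in sorted(ds.expression):
            for t in sorted(ds.expression[m]):
                fh.write(f"{m}\t{t}\n")
    with open(paths["hosts"], "w", encoding="utf-8") as fh:
        fh.write("host_gene\tmirna\n")
        for g in sorted(ds.hosts):
            for m in sorted(ds.hosts[g]):
                fh.write(f"{g}\t{m}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("mirna\tpathway_id\tenrichment_odds\n")
        for sig in ds.truth:
            for pid in sig.pathway_ids:
                fh.write(f"{sig.mirna}\t{pid}\t{sig.enrichment_odds:g}\n")
    return paths


def load_truth(path: str | Path) -> list[PlantedSignal]:
    """Read a truth TSV back into planted-signal records."""
    grouped: dict[str, tuple[list[str], float]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            m, pid, odds = line.rstrip("\n").split("\t")
            ids, _ = grouped.setdefault(m, ([], float(odds)))
            ids.append(pid)
    return [
        PlantedSignal(mirna=m, pathway_ids=tuple(ids), enrichment_odds=odds)
        for m, (ids, odds) in sorted(grouped.items())
    ]


@dataclass
class RecoveryReport:
    """How well planted miRNAs were recovered by the ranking."""

    per_mirna: list[tuple[str, float, bool]]  # (name, rank, selected)
    top_decile_fraction: float
    n_scored: int


def truth_recovery_report(
    truth: Sequence[PlantedSignal] | str | Path,
    scores: Sequence[MiRNAScore],
) -> RecoveryReport:
    """Join the planted truth against a ranked score list.

    A planted miRNA absent from the results gets rank = inf (and counts
    against the top-decile fraction), not an exception.
    """
    if isinstance(truth, (str, Path)):
        truth = load_truth(truth)
    rank_by_name = {s.mirna: (s.rank, bool(s.selected)) for s in scores}
    n = len(scores)
    cutoff = math.ceil(0.1 * n) if n else 0
    rows: list[tuple[str, float, bool]] = []
    hits = 0
    for sig in truth:
        rank, sel = rank_by_name.get(sig.mirna, (None, False))
        if rank is None:
            rows.append((sig.mirna, math.inf, False))
        else:
            rows.append((sig.mirna, float(rank), sel))
            if rank <= cutoff:
                hits += 1
    frac = hits / len(truth) if truth else 0.0
    return RecoveryReport(
        per_mirna=rows, top_decile_fraction=frac, n_scored=n
    )
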