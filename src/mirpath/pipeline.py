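"""End-to-end orchestration: config, file IO, manifests, deterministic TSVs.

``run_enrichment`` executes load → TF-extend → (pre-)filter → contingency →
Fisher → FDR → Lancaster → rank/select → write; ``run_control`` replays the
same pipeline on a random pathway draw.  Outputs are plain TSVs with a
fixed column order and probabilities serialized to 6 significant digits, so
two runs with the same config are byte-identical — including permutation-
null runs, which are seeded from the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .errors import ValidationError
from .gene_sets import (
    DEFAULT_CLASS_WEIGHTS, load_pathways, load_tf_edges, extend_with_tfs,
)
from .targets import load_alias_table, load_target_map, build_universe, TargetMap
from .filters import (
    load_expression_table, load_host_table,
    expression_filter, intragenic_filter, candidate_set, random_control,
)
from .enrichment import EnrichmentResult, enrichment_analysis

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; every methodological switch surfaces here
    with its default matching the reference analysis."""

    pathways: str = ""
    classes: str = ""
    tf_edges: str = ""
    targets_vmt: str = ""
    targets_cmt: str = ""
    expression: str = ""
    hosts: str = ""
    aliases: str = ""
    mode: str = "VMT"
    class_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    fdr_scope: str = "per_mirna"
    null_kind: str = "moment_matched"
    n_permutations: int = 1000
    alpha: float = 0.01
    combine_on: str = "adjusted"
    filter_mode: str = "union"
    filter_position: str = "pre"
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.mode not in ("VMT", "CMT"):
            raise ValidationError("mode must be VMT or CMT")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.filter_position not in ("pre", "post"):
            raise ValidationError("filter_position must be 'pre' or 'post'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def targets_path(self) -> str:
        path = self.targets_vmt if self.mode == "VMT" else self.targets_cmt
        if not path:
            raise ValidationError(f"no target file configured for {self.mode}")
        return path


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt_p(p: float) -> str:
    return f"{p:.6g}"


def write_pair_table(result: EnrichmentResult, path: Path) -> None:
    cols = ("mirna", "pathway_id", "np_plus", "np_minus", "nm_plus",
            "nm_minus", "p_raw", "p_adj")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in result.pairs:
            t = r.table
            fh.write(
                f"{r.mirna}\t{r.pathway_id}\t{t.np_plus}\t{t.np_minus}\t"
                f"{t.nm_plus}\t{t.nm_minus}\t{_fmt_p(r.p_raw)}\t"
                f"{_fmt_p(r.p_adj)}\n"
            )


def write_score_table(result: EnrichmentResult, path: Path) -> None:
    cols = ("mirna", "lancaster_T", "df", "p_combined",
            "neg_log10_p", "rank", "selected")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in result.scores:
            fh.write(
                f"{s.mirna}\t{s.lancaster_T:.6g}\t{s.df_nominal:.6g}\t"
                f"{_fmt_p(s.p_combined)}\t{s.neg_log_p:.6g}\t{s.rank}\t"
                f"{int(bool(s.selected))}\n"
            )


@dataclass
class RunResult:
    config: RunConfig
    result: EnrichmentResult
    analyzed_mirnas: list[str]
    filter_provenance: dict[str, frozenset[str]]
    out_paths: dict[str, Path]


def _load_inputs(config: RunConfig):
    pathways = load_pathways(
        config.pathways, config.classes, config.class_weights
    )
    if config.tf_edges:
        pathways = extend_with_tfs(pathways, load_tf_edges(config.tf_edges))
    aliases = load_alias_table(config.aliases) if config.aliases else None
    tmap = load_target_map(config.targets_path(), config.mode, aliases)
    return pathways, tmap


def _apply_filters(config: RunConfig, pathways, tmap: TargetMap):
    """Combined expression/intragenic candidate set with provenance."""
    names = sorted(tmap.targets)
    expr = (
        expression_filter(names, load_expression_table(config.expression))
        if config.expression else {}
    )
    intr = (
        intragenic_filter(names, pathways, load_host_table(config.hosts))
        if config.hosts else {}
    )
    if not config.expression and not config.hosts:
        return None  # no filtering configured
    return candidate_set(expr, intr, mode=config.filter_mode)


def run_enrichment(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write pair/score TSVs + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pathways, tmap = _load_inputs(config)
    provenance = _apply_filters(config, pathways, tmap)

    if provenance is not None and config.filter_position == "pre":
        kept = {
            m: t for m, t in tmap.targets.items() if m in provenance
        }
        log.info(
            "pre-filter kept %d of %d miRNAs", len(kept), len(tmap.targets)
        )
        if not kept:
            raise ValidationError("filtering removed every miRNA")
        tmap = TargetMap(mode=tmap.mode, targets=kept)

    universe = build_universe(tmap)
    result = enrichment_analysis(
        pathways, tmap, universe,
        null_kind=config.null_kind,
        n_permutations=config.n_permutations,
        seed=config.seed,
        fdr_scope=config.fdr_scope,
        combine_on=config.combine_on,
        alpha=config.alpha,
    )

    if provenance is not None and config.filter_position == "post":
        for s in result.scores:
            if s.mirna not in provenance:
                s.selected = False

    paths = {
        "pairs": out / "pairs.tsv",
        "scores": out / "mirna_scores.tsv",
        "manifest": out / "manifest.json",
    }
    write_pair_table(result, paths["pairs"])
    write_score_table(result, paths["scores"])
    _write_manifest(config, result, paths["manifest"])
    return RunResult(
        config=config,
        result=result,
        analyzed_mirnas=[s.mirna for s in result.scores],
        filter_provenance=provenance or {},
        out_paths=paths,
    )


def _write_manifest(config: RunConfig, result: EnrichmentResult,
                    path: Path, extra: dict | None = None) -> None:
    manifest: dict = {"mirpath_version": __version__}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        manifest[f"config.{f.name}"] = (
            dict(v) if isinstance(v, Mapping) else v
        )
    for key in ("pathways", "classes", "tf_edges", "targets_vmt",
                "targets_cmt", "expression", "hosts", "aliases"):
        p = getattr(config, key)
        if p:
            manifest[f"sha256.{key}"] = _sha256(p)
    manifest["n_pathways_scored"] = len(result.pathway_ids)
    manifest["n_pathways_degenerate"] = len(result.degenerate_pathways)
    manifest["n_mirnas_scored"] = len(result.scores)
    manifest["n_mirnas_skipped_empty"] = len(result.skipped_mirnas)
    manifest["n_selected"] = len(result.selected)
    manifest["null.kind"] = result.null.kind
    manifest["null.scale"] = result.null.scale
    manifest["null.df_effective"] = result.null.df_effective
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_control(config: RunConfig, pool_path: str | Path,
                pool_classes_path: str | Path | None = None,
                k: int = 39) -> RunResult:
    """Random-pathway control: sample ``k`` pathways from a pool GMT and
    rerun the pipeline; writes the control report plus the sampled ids."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # pool pathways need a class to load; the control reassigns them anyway
    if pool_classes_path is None:
        import tempfile
        with open(pool_path, encoding="utf-8") as fh:
            ids = [ln.split("\t", 1)[0] for ln in fh if ln.strip()]
        tmp = tempfile.NamedTemporaryFile(
            "w", suffix=".tsv", delete=False, encoding="utf-8"
        )
        for pid in ids:
            tmp.write(f"{pid}\tB\n")
        tmp.close()
        pool_classes_path = tmp.name
    pool = load_pathways(pool_path, pool_classes_path, config.class_weights)
    if config.tf_edges:
        pool = extend_with_tfs(pool, load_tf_edges(config.tf_edges))

    aliases = load_alias_table(config.aliases) if config.aliases else None
    tmap = load_target_map(config.targets_path(), config.mode, aliases)
    provenance = _apply_filters(config, pool, tmap)
    if provenance is not None and config.filter_position == "pre":
        kept = {m: t for m, t in tmap.targets.items() if m in provenance}
        if not kept:
            raise ValidationError("filtering removed every miRNA")
        tmap = TargetMap(mode=tmap.mode, targets=kept)

    ctrl = random_control(
        pool, tmap, k=k, seed=config.seed, weights=config.class_weights,
        null_kind=config.null_kind, n_permutations=config.n_permutations,
        fdr_scope=config.fdr_scope, combine_on=config.combine_on,
        alpha=config.alpha,
    )
    paths = {
        "pairs": out / "control_pairs.tsv",
        "scores": out / "control_mirna_scores.tsv",
        "sampled": out / "control_pathways.tsv",
        "manifest": out / "control_manifest.json",
    }
    write_pair_table(ctrl.result, paths["pairs"])
    write_score_table(ctrl.result, paths["scores"])
    with open(paths["sampled"], "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tassigned_class\n")
        for pid in ctrl.sampled_ids:
            fh.write(f"{pid}\t{ctrl.class_labels[pid]}\n")
    _write_manifest(
        config, ctrl.result, paths["manifest"],
        extra={"control.k": k, "control.seed": ctrl.seed,
               "control.sampled_ids": ",".join(ctrl.sampled_ids)},
    )
    return RunResult(
        config=config,
        result=ctrl.result,
        analyzed_mirnas=[s.mirna for s in ctrl.result.scores],
        filter_provenance=provenance or {},
        out_paths=paths,
    )
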