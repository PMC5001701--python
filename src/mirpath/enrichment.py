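"""Over-representation statistics and the weighted Lancaster combination.

For one miRNA and one pathway the data reduce to a 2x2 contingency table
over the target universe U (the union of all miRNAs' target sets):

    Np+ = |T ∩ P|        targeted genes in the pathway
    Np- = |P| - Np+      non-targeted genes in the pathway
    Nm+ = |T|            all targets of the miRNA
    Nm- = |U| - |T|      universe genes the miRNA does not target

where T is the miRNA's target set and P the TF-extended pathway restricted
to U (genes never annotated as anyone's target are excluded, so the test is
run on a background where targeting is observable).  Enrichment is the
upper tail of the hypergeometric distribution, i.e. the one-tailed Fisher
exact test P(X >= Np+) with population N = |U|, K = |P| success states and
n = |T| draws.

Per miRNA, the pathway p-values are Benjamini-Hochberg adjusted and then
combined with Lancaster's weighted generalization of Fisher's combined
probability test: each p is mapped through the (1-p) quantile of a
chi-square with df equal to the pathway's relevance weight w (realized as
Gamma(w/2, scale=2) so fractional weights are exact) and the transforms are
summed into T_L.  With all weights equal to 2 this is exactly Fisher's
method.  Under independence T_L ~ chi-square(sum w); because pathways share
genes the single tests are correlated, so the default null instead
moment-matches T_L against permuted pseudo-miRNAs (Brown-style scaled
chi-square), with a pure permutation p-value as a third option.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2, gamma, hypergeom

from .errors import ValidationError
from .gene_sets import PathwayRecord
from .targets import TargetMap, build_universe

log = logging.getLogger(__name__)

#: Smallest positive probability used when clamping p = 0 (float underflow).
MIN_P = float(np.finfo(float).tiny)

NULL_KINDS = ("independent", "moment_matched", "permutation")
FDR_SCOPES = ("per_mirna", "global")


# ---------------------------------------------------------------------------
# contingency tables and the Fisher test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """The four counts for one miRNA-pathway pair."""

    np_plus: int
    np_minus: int
    nm_plus: int
    nm_minus: int

    def __post_init__(self) -> None:
        c = (self.np_plus, self.np_minus, self.nm_plus, self.nm_minus)
        if any(v < 0 for v in c):
            raise ValidationError(f"negative count in contingency table {c}")
        if self.np_plus > self.nm_plus:
            raise ValidationError(
                f"np_plus={self.np_plus} exceeds nm_plus={self.nm_plus}"
            )
        if self.np_minus > self.nm_minus:
            raise ValidationError(
                f"np_minus={self.np_minus} exceeds nm_minus={self.nm_minus}"
            )

    @property
    def population(self) -> int:
        """N: size of the target universe."""
        return self.nm_plus + self.nm_minus

    @property
    def pathway_size(self) -> int:
        """K: testable pathway genes."""
        return self.np_plus + self.np_minus


class DegeneratePathwayError(ValidationError):
    """Pathway has no genes in the target universe; the pair is untestable."""


def build_contingency(
    mirna: str,
    pathway: PathwayRecord,
    tmap: TargetMap,
    universe: frozenset[str],
) -> ContingencyTable:
    """Counts for one pair, with the pathway restricted to the universe."""
    targets = tmap.targets.get(mirna)
    if not targets:
        raise ValidationError(f"miRNA {mirna!r} has no targets")
    p_genes = pathway.extended_genes & universe
    if not p_genes:
        raise DegeneratePathwayError(
            f"pathway {pathway.pathway_id!r} has no genes in the target "
            "universe"
        )
    np_plus = len(targets & p_genes)
    return ContingencyTable(
        np_plus=np_plus,
        np_minus=len(p_genes) - np_plus,
        nm_plus=len(targets),
        nm_minus=len(universe) - len(targets),
    )


def fisher_one_tailed(table: ContingencyTable) -> float:
    """Upper-tail hypergeometric probability P(X >= np_plus), in (0, 1]."""
    p = hypergeom.sf(
        table.np_plus - 1,
        table.population,
        table.pathway_size,
        table.nm_plus,
    )
    return float(min(max(p, MIN_P), 1.0))


def fisher_one_tailed_many(
    np_plus: np.ndarray, population: int | np.ndarray,
    pathway_size: np.ndarray, draws: np.ndarray,
) -> np.ndarray:
    """Vectorized upper-tail test: same quantity as :func:`fisher_one_tailed`.

    Arguments broadcast; used by the pipeline to score all pairs at once.
    """
    p = hypergeom.sf(np.asarray(np_plus) - 1, population, pathway_size, draws)
    return np.clip(p, MIN_P, 1.0)


# ---------------------------------------------------------------------------
# multiple-testing correction
# ---------------------------------------------------------------------------

def fdr_adjust(
    p_values: Sequence[float] | np.ndarray,
    groups: Sequence | np.ndarray | None = None,
) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    ``groups`` optionally labels each p-value with a correction scope (e.g.
    its miRNA); adjustment is then applied within each scope independently.
    Output order matches input order; values are clipped to <= 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if groups is None:
        return _bh(p)
    groups = np.asarray(groups)
    out = np.empty_like(p)
    for g in np.unique(groups):
        mask = groups == g
        out[mask] = _bh(p[mask])
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = (p[order] * m) / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Lancaster combination
# ---------------------------------------------------------------------------

def lancaster_transform(p, w):
    """(1-p) quantile of a chi-square with ``w`` degrees of freedom.

    Realized as Gamma(w/2, scale=2) so fractional df are exact.  At w = 2
    this is Fisher's -2 ln p; at p = 1 it is 0.  p = 0 (underflow) is
    clamped to the smallest positive float before transforming.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("Lancaster weight must be positive")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    n_clamped = int(np.sum(p < MIN_P))
    if n_clamped:
        log.info("clamped %d underflowed p-values to %.3g", n_clamped, MIN_P)
        p = np.maximum(p, MIN_P)
    out = gamma.isf(p, a=w / 2.0, scale=2.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class NullModel:
    """Null distribution for the combined statistic T_L.

    ``independent``: T_L ~ chi-square(sum w) — valid only when pathway tests
    are independent.  ``moment_matched``: T_L ~ scale * chi-square
    (df_effective) with both parameters fitted to permuted pseudo-miRNA
    statistics.  ``permutation``: empirical upper tail of the stored
    permutation statistics.
    """

    kind: str
    scale: float = 1.0
    df_effective: float = float("nan")
    n_permutations: int = 0
    seed: int | None = None
    perm_T: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in NULL_KINDS:
            raise ValidationError(f"null kind must be one of {NULL_KINDS}")
        if self.kind == "independent" and self.scale != 1.0:
            raise ValidationError("independent null requires scale = 1")


@dataclass(frozen=True)
class PairResult:
    """Per-pair outcome: raw and FDR-adjusted p plus the counts behind them."""

    mirna: str
    pathway_id: str
    p_raw: float
    p_adj: float
    table: ContingencyTable


@dataclass
class MiRNAScore:
    """Per-miRNA combined outcome."""

    mirna: str
    lancaster_T: float
    df_nominal: float
    p_combined: float
    rank: int | None = None
    selected: bool | None = None

    @property
    def neg_log_p(self) -> float:
        return -math.log10(self.p_combined)


def _p_combined_from_T(T, null: NullModel, df_nominal: float):
    """Upper-tail probability of T_L under the chosen null (vectorized)."""
    T = np.asarray(T, dtype=float)
    if null.kind == "independent":
        p = chi2.sf(T, df=df_nominal)
    elif null.kind == "moment_matched":
        p = chi2.sf(T / null.scale, df=null.df_effective)
    else:  # permutation
        if null.perm_T is None or null.n_permutations < 1:
            raise ValidationError(
                "permutation null requires stored permutation statistics"
            )
        perm = np.sort(null.perm_T)
        # #{T_perm >= T} via binary search on the sorted permutation values
        ge = null.n_permutations - np.searchsorted(perm, T, side="left")
        p = (1.0 + ge) / (1.0 + null.n_permutations)
    return np.clip(p, MIN_P, 1.0)


def combine_lancaster(
    pair_results: Sequence[PairResult],
    weights: Mapping[str, float],
    null: NullModel,
    use_raw: bool = False,
) -> MiRNAScore:
    """Combine one miRNA's per-pathway p-values into a single score.

    ``weights`` must cover exactly the pathways present in ``pair_results``.
    By default the FDR-adjusted p-values are combined; ``use_raw`` switches
    to the unadjusted ones for sensitivity analysis.
    """
    if not pair_results:
        raise ValidationError("no pair results to combine")
    mirnas = {r.mirna for r in pair_results}
    if len(mirnas) != 1:
        raise ValidationError("pair results span more than one miRNA")
    ids = [r.pathway_id for r in pair_results]
    if set(ids) != set(weights) or len(ids) != len(set(ids)):
        raise ValidationError("pathway set and weight set do not match")
    p = np.array(
        [r.p_raw if use_raw else r.p_adj for r in pair_results], dtype=float
    )
    w = np.array([weights[i] for i in ids], dtype=float)
    T = float(np.sum(lancaster_transform(p, w)))
    df_nominal = float(w.sum())
    p_comb = float(_p_combined_from_T(T, null, df_nominal))
    return MiRNAScore(
        mirna=next(iter(mirnas)),
        lancaster_T=T,
        df_nominal=df_nominal,
        p_combined=p_comb,
    )


def rank_and_select(
    scores: Iterable[MiRNAScore], alpha: float = 0.01
) -> list[MiRNAScore]:
    """Sort ascending by combined p and flag strict p < alpha.

    Ties break by descending T_L, then lexicographic miRNA name, so the
    ordering is stable across runs.  All scores are returned, ranked;
    ``selected`` marks the retained set.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    ordered = sorted(
        scores, key=lambda s: (s.p_combined, -s.lancaster_T, s.mirna)
    )
    for i, s in enumerate(ordered, start=1):
        s.rank = i
        s.selected = bool(s.p_combined < alpha)
    return ordered


# ---------------------------------------------------------------------------
# vectorized scoring core (shared by the real analysis and the null)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Background:
    """Pre-indexed pathways over the universe, ready for matrix counting."""

    gene_index: dict[str, int]
    pathway_ids: list[str]
    weights: np.ndarray          # per retained pathway
    membership: np.ndarray       # (n_universe, n_pathways) boolean
    pathway_sizes: np.ndarray    # |P_i| = |extended ∩ universe|
    degenerate_ids: list[str]    # pathways with no universe genes (dropped)


def _index_background(
    pathways: Sequence[PathwayRecord], universe: frozenset[str]
) -> _Background:
    gene_index = {g: i for i, g in enumerate(sorted(universe))}
    ids, w_list, cols, sizes, degenerate = [], [], [], [], []
    for pw in pathways:
        members = pw.extended_genes & universe
        if not members:
            degenerate.append(pw.pathway_id)
            continue
        col = np.zeros(len(gene_index), dtype=bool)
        col[[gene_index[g] for g in members]] = True
        ids.append(pw.pathway_id)
        w_list.append(pw.weight)
        cols.append(col)
        sizes.append(len(members))
    if not ids:
        raise ValidationError("every pathway is degenerate on this universe")
    if degenerate:
        log.info(
            "dropped %d degenerate pathway(s) with no universe genes: %s",
            len(degenerate), ", ".join(degenerate),
        )
    return _Background(
        gene_index=gene_index,
        pathway_ids=ids,
        weights=np.array(w_list),
        membership=np.column_stack(cols),
        pathway_sizes=np.array(sizes, dtype=int),
        degenerate_ids=degenerate,
    )


def _score_matrix(
    target_sets: Sequence[frozenset[str]],
    bg: _Background,
    fdr_scope: str,
    combine_on: str,
):
    """All-pairs counts → p_raw → p_adj → T_L for a batch of target sets.

    Returns (np_plus counts, p_raw, p_adj, T) with rows in target-set order
    and columns in ``bg.pathway_ids`` order.
    """
    n_u = len(bg.gene_index)
    M = np.zeros((len(target_sets), n_u), dtype=bool)
    sizes = np.empty(len(target_sets), dtype=int)
    for i, t in enumerate(target_sets):
        idx = [bg.gene_index[g] for g in t if g in bg.gene_index]
        M[i, idx] = True
        sizes[i] = len(t)
    # bool @ bool is a logical matmul in numpy; cast to get real counts
    counts = M.astype(np.int32) @ bg.membership.astype(np.int32)
    p_raw = fisher_one_tailed_many(
        counts, n_u, bg.pathway_sizes[None, :], sizes[:, None]
    )
    if fdr_scope == "global":
        p_adj = fdr_adjust(p_raw.ravel()).reshape(p_raw.shape)
    elif fdr_scope == "per_mirna":
        p_adj = np.empty_like(p_raw)
        for i in range(p_raw.shape[0]):
            p_adj[i] = _bh(p_raw[i])
    else:
        raise ValidationError(f"fdr_scope must be one of {FDR_SCOPES}")
    p_comb_src = p_raw if combine_on == "raw" else p_adj
    transforms = lancaster_transform(p_comb_src, bg.weights[None, :])
    T = transforms.sum(axis=1)
    return counts, p_raw, p_adj, T


def _pseudo_target_sets(
    real_sizes: np.ndarray,
    universe_sorted: list[str],
    n_permutations: int,
    rng: np.random.Generator,
) -> list[frozenset[str]]:
    """Random pseudo-miRNAs: uniform gene subsets of the universe whose
    sizes are resampled from the empirical real target-set sizes."""
    n_u = len(universe_sorted)
    draw_sizes = rng.choice(real_sizes, size=n_permutations, replace=True)
    out = []
    for s in draw_sizes:
        idx = rng.choice(n_u, size=min(int(s), n_u), replace=False)
        out.append(frozenset(universe_sorted[i] for i in idx))
    return out


def estimate_null(
    pathways: Sequence[PathwayRecord],
    tmap: TargetMap,
    universe: frozenset[str],
    n_permutations: int = 1000,
    seed: int = 0,
    fdr_scope: str = "per_mirna",
    combine_on: str = "adjusted",
) -> NullModel:
    """Fit the correlation-aware null by permuting pseudo-miRNAs.

    Each pseudo-miRNA is a uniform random subset of the universe (size
    resampled from the real target-set sizes) pushed through the identical
    count → Fisher → FDR → Lancaster pipeline.  The null is the Brown-style
    moment match: scale = Var(T)/(2 Mean(T)), df_eff = 2 Mean(T)^2/Var(T);
    the raw permutation statistics are stored for the permutation option.
    Degenerate variance falls back to the independent null with a warning.
    """
    if n_permutations < 100:
        raise ValidationError("need at least 100 permutations")
    bg = _index_background(pathways, universe)
    real_sizes = np.array(
        [len(t) for t in tmap.nonempty().values()], dtype=int
    )
    if real_sizes.size == 0:
        raise ValidationError("no non-empty target sets to calibrate against")
    rng = np.random.default_rng(seed)
    pseudo = _pseudo_target_sets(
        real_sizes, sorted(universe), n_permutations, rng
    )
    _, _, _, T = _score_matrix(pseudo, bg, fdr_scope, combine_on)
    mean, var = float(np.mean(T)), float(np.var(T, ddof=1))
    if var <= 1e-12 * max(1.0, mean * mean) or mean <= 0:
        warnings.warn(
            "permutation statistic variance is degenerate; falling back to "
            "the independent null",
            RuntimeWarning,
        )
        return NullModel(
            kind="independent",
            scale=1.0,
            df_effective=float(bg.weights.sum()),
            n_permutations=n_permutations,
            seed=seed,
            perm_T=T,
        )
    return NullModel(
        kind="moment_matched",
        scale=var / (2.0 * mean),
        df_effective=2.0 * mean * mean / var,
        n_permutations=n_permutations,
        seed=seed,
        perm_T=T,
    )


# ---------------------------------------------------------------------------
# full analysis over a target map
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Everything the analysis produced, in deterministic order."""

    pairs: list[PairResult]
    scores: list[MiRNAScore]
    null: NullModel
    pathway_ids: list[str]
    weights: dict[str, float]
    degenerate_pathways: list[str]
    skipped_mirnas: list[str]

    @property
    def selected(self) -> list[MiRNAScore]:
        return [s for s in self.scores if s.selected]


def enrichment_analysis(
    pathways: Sequence[PathwayRecord],
    tmap: TargetMap,
    universe: frozenset[str] | None = None,
    *,
    null_kind: str = "moment_matched",
    n_permutations: int = 1000,
    seed: int = 0,
    fdr_scope: str = "per_mirna",
    combine_on: str = "adjusted",
    alpha: float = 0.01,
) -> EnrichmentResult:
    """Score every miRNA in ``tmap`` against the (TF-extended) pathways.

    Pipeline: contingency → one-tailed Fisher → BH FDR (per miRNA by
    default) → weighted Lancaster combination under ``null_kind`` → rank
    and strict p < alpha selection.  miRNAs with empty target sets are
    skipped and reported, not scored.
    """
    if null_kind not in NULL_KINDS:
        raise ValidationError(f"null_kind must be one of {NULL_KINDS}")
    if combine_on not in ("adjusted", "raw"):
        raise ValidationError("combine_on must be 'adjusted' or 'raw'")
    if universe is None:
        universe = build_universe(tmap)
    scorable = tmap.nonempty()
    skipped = sorted(set(tmap.targets) - set(scorable))
    if skipped:
        log.info("skipping %d miRNA(s) with empty target sets", len(skipped))
    if not scorable:
        raise ValidationError("no miRNA has a non-empty target set")
    bg = _index_background(pathways, universe)
    names = sorted(scorable)
    counts, p_raw, p_adj, T = _score_matrix(
        [scorable[m] for m in names], bg, fdr_scope, combine_on
    )
    df_nominal = float(bg.weights.sum())
    if null_kind == "independent":
        null = NullModel(
            kind="independent", scale=1.0, df_effective=df_nominal, seed=seed
        )
    else:
        null = estimate_null(
            pathways, tmap, universe,
            n_permutations=n_permutations, seed=seed,
            fdr_scope=fdr_scope, combine_on=combine_on,
        )
        if null.kind == "moment_matched" and null_kind == "permutation":
            null = NullModel(
                kind="permutation", scale=null.scale,
                df_effective=null.df_effective,
                n_permutations=null.n_permutations, seed=null.seed,
                perm_T=null.perm_T,
            )
    p_comb = _p_combined_from_T(T, null, df_nominal)

    pairs: list[PairResult] = []
    n_u, sizes = len(universe), {m: len(scorable[m]) for m in names}
    for i, m in enumerate(names):
        for j, pid in enumerate(bg.pathway_ids):
            table = ContingencyTable(
                np_plus=int(counts[i, j]),
                np_minus=int(bg.pathway_sizes[j] - counts[i, j]),
                nm_plus=sizes[m],
                nm_minus=n_u - sizes[m],
            )
            pairs.append(
                PairResult(
                    mirna=m, pathway_id=pid,
                    p_raw=float(p_raw[i, j]), p_adj=float(p_adj[i, j]),
                    table=table,
                )
            )
    scores = [
        MiRNAScore(
            mirna=m, lancaster_T=float(T[i]), df_nominal=df_nominal,
            p_combined=float(p_comb[i]),
        )
        for i, m in enumerate(names)
    ]
    scores = rank_and_select(scores, alpha=alpha)
    weights = dict(zip(bg.pathway_ids, (float(w) for w in bg.weights)))
    return EnrichmentResult(
        pairs=pairs,
        scores=scores,
        null=null,
        pathway_ids=list(bg.pathway_ids),
        weights=weights,
        degenerate_pathways=list(bg.degenerate_ids),
        skipped_mirnas=skipped,
    )
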