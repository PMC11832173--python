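"""Multiview AUC-ROC evaluation and the joint-view trustworthiness (JVT) test.

A marker's discriminative power on one comparison is its rank-based
(Mann-Whitney) AUC-ROC, with tied scores contributing 1/2 per tied
cross-pair. Across several comparisons the per-comparison AUCs are
reduced to a single *joint multiview* value, by default the minimum —
the conservative choice: a marker is only as good as its worst view.

JVT asks how easy it is to obtain an equally good multiview marker at
random. For a single gene the null model draws genes uniformly from the
pool of Z genes common to all datasets and records their multiview
scores; for an m-gene combinatorial marker each null draw samples m
distinct genes and rebuilds the *entire* marker (reference selection,
alignment fit on the inference dataset, per-dataset compression) before
scoring. The empirical p value is the proportion of the T null scores
greater than or equal to the observed score. When the number of
distinct draws is at most T, the null is enumerated exhaustively
instead of sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .datasets import ComparisonSpec, ExpressionDataset
from . import marker as marker_mod

OPERATORS = {"min": np.min, "mean": np.mean, "median": np.median}


@dataclass
class AUCResult:
    comparison: ComparisonSpec | None
    auc: float
    sidedness: str = "two_sided"


@dataclass
class MultiviewScore:
    per_comparison: list[AUCResult]
    operator: str
    value: float


@dataclass
class JVTResult:
    """Outcome of one joint-view trustworthiness test."""

    observed: float
    null_sample: np.ndarray
    T: int
    pool_size: int
    p_value: float
    p_smoothed: float
    seed: int
    mode: str                      # "single" or "combinatorial"
    m: int = 1
    sampling: str = "monte_carlo"  # or "exhaustive"
    operator: str = "min"
    sidedness: str = "two_sided"
    per_comparison: list[AUCResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# AUC-ROC
# ---------------------------------------------------------------------------

def _auc_rows(values: np.ndarray, positive: np.ndarray, two_sided: bool) -> np.ndarray:
    """Rank-based AUC of each row of ``values`` against a boolean positive mask."""
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC-ROC requires both classes to be non-empty")
    ranks = rankdata(values, axis=-1)
    auc = (ranks[..., positive].sum(axis=-1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    if two_sided:
        auc = np.maximum(auc, 1.0 - auc)
    return auc


def auc_roc(
    scores: Sequence[float],
    labels: Sequence,
    sidedness: str = "two_sided",
    positive_label=None,
) -> float:
    """Rank-based AUC-ROC of a score vector against binary class labels.

    Ties contribute 1/2 per tied cross-pair (midrank convention).
    ``labels`` may be boolean (True = positive class) or any two-valued
    vector together with ``positive_label``. ``two_sided`` returns
    ``max(auc, 1 - auc)``, making the value direction-agnostic.
    """
    if sidedness not in ("one_sided", "two_sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.dtype == bool and positive_label is None:
        positive = labels
    else:
        if positive_label is None:
            raise ValueError("positive_label is required for non-boolean labels")
        positive = labels == positive_label
    return float(_auc_rows(scores[None, :], positive, sidedness == "two_sided")[0])


def multiview_score(
    aucs: Sequence[AUCResult | float], operator: str = "min"
) -> MultiviewScore:
    """Reduce per-comparison AUCs to one joint multiview value."""
    if operator not in OPERATORS:
        raise ValueError(f"unknown operator {operator!r}")
    if len(aucs) == 0:
        raise ValueError("multiview score of an empty comparison list")
    results = [
        a if isinstance(a, AUCResult) else AUCResult(comparison=None, auc=float(a))
        for a in aucs
    ]
    value = float(OPERATORS[operator]([r.auc for r in results]))
    return MultiviewScore(per_comparison=results, operator=operator, value=value)


def empirical_pvalue(null_sample: Sequence[float], observed: float,
                     smoothed: bool = False) -> float:
    """Proportion of the null sample >= the observed value (inclusive).

    The plain proportion can return 0; ``smoothed`` applies the
    (1 + count) / (1 + T) convention instead.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    count = int((null_sample >= observed).sum())
    if smoothed:
        return (1 + count) / (1 + null_sample.size)
    return count / null_sample.size


# ---------------------------------------------------------------------------
# JVT machinery
# ---------------------------------------------------------------------------

def common_gene_pool(datasets: Sequence[ExpressionDataset]) -> list[str]:
    """Genes present in every dataset, in sorted order."""
    pool: set[str] = set(datasets[0].genes)
    for ds in datasets[1:]:
        pool &= set(ds.genes)
    if not pool:
        raise ValueError("datasets share no genes")
    return sorted(pool)


def _resolve_comparisons(
    datasets: Sequence[ExpressionDataset],
    comparisons: Sequence[ComparisonSpec],
    pool: Sequence[str],
):
    """Pool-aligned value matrices and class masks per comparison."""
    by_name = {ds.name: ds for ds in datasets}
    resolved = []
    for comp in comparisons:
        if comp.dataset_name not in by_name:
            raise KeyError(f"comparison references unknown dataset {comp.dataset_name!r}")
        ds = by_name[comp.dataset_name].subset_genes(pool)
        mask_a, mask_b = comp.resolve(ds)
        cols = np.where(mask_a | mask_b)[0]
        resolved.append((ds.values[:, cols], mask_a[cols]))
    return resolved


def _pool_multiview_scores(resolved, operator: str, two_sided: bool) -> np.ndarray:
    """Multiview score of every pool gene, vectorized per comparison."""
    per_comp = np.stack(
        [_auc_rows(values, pos, two_sided) for values, pos in resolved]
    )
    return OPERATORS[operator](per_comp, axis=0)


def _iteration_seeds(seed: int, T: int) -> np.ndarray:
    """Deterministic per-iteration substream keys derived from one seed.

    Draws are keyed by iteration index, so results do not depend on how
    iterations might be batched or parallelized.
    """
    return np.random.SeedSequence(seed).generate_state(T, dtype=np.uint64)


def jvt_single(
    gene: str,
    datasets: Sequence[ExpressionDataset],
    comparisons: Sequence[ComparisonSpec],
    T: int = 10_000,
    seed: int = 0,
    sidedness: str = "two_sided",
    operator: str = "min",
) -> JVTResult:
    """JVT for a single gene.

    The observed statistic is the gene's multiview AUC; each null
    iteration draws one gene uniformly from the common pool (the tested
    gene included) and scores it identically. Runs in O(Z + T): the
    per-gene multiview scores of the whole pool are computed once and
    null draws index into them.
    """
    pool = common_gene_pool(datasets)
    gene = gene.strip().upper()
    if gene not in pool:
        raise KeyError(f"gene {gene!r} is not in the common gene pool")
    two_sided = sidedness == "two_sided"
    resolved = _resolve_comparisons(datasets, comparisons, pool)
    per_comp = np.stack([_auc_rows(v, p, two_sided) for v, p in resolved])
    scores = OPERATORS[operator](per_comp, axis=0)
    gi = pool.index(gene)
    observed = float(scores[gi])
    per_comparison = [
        AUCResult(comparison=c, auc=float(per_comp[k, gi]), sidedness=sidedness)
        for k, c in enumerate(comparisons)
    ]
    Z = len(pool)
    if Z <= T:
        null = scores.copy()
        sampling = "exhaustive"
    else:
        keys = _iteration_seeds(seed, T)
        idx = keys % np.uint64(Z)
        null = scores[idx.astype(np.intp)]
        sampling = "monte_carlo"
    return JVTResult(
        observed=observed,
        null_sample=null,
        T=len(null),
        pool_size=Z,
        p_value=empirical_pvalue(null, observed),
        p_smoothed=empirical_pvalue(null, observed, smoothed=True),
        seed=seed,
        mode="single",
        m=1,
        sampling=sampling,
        operator=operator,
        sidedness=sidedness,
        per_comparison=per_comparison,
    )


def _score_geneset(
    idx: np.ndarray,
    inference_values: np.ndarray,
    resolved,
    operator: str,
    two_sided: bool,
) -> tuple[float, list[float]]:
    """Full combinatorial-marker score of one gene-index set.

    Replicates the complete marker construction: reference selection
    and alignment flags on the inference dataset, then per-comparison
    compression (alignment means re-centered on the scored samples).
    """
    inf = inference_values[idx]
    ref = marker_mod.reference_index(inf)
    flags = marker_mod.alignment_flags(inf, ref)
    aucs = []
    for values, pos in resolved:
        g_comb, _ = marker_mod.compress_values(values[idx], flags)
        aucs.append(float(_auc_rows(g_comb[None, :], pos, two_sided)[0]))
    return float(OPERATORS[operator](aucs)), aucs


def jvt_combinatorial(
    geneset: Sequence[str],
    datasets: Sequence[ExpressionDataset],
    comparisons: Sequence[ComparisonSpec],
    T: int = 10_000,
    seed: int = 0,
    sidedness: str = "two_sided",
    operator: str = "min",
    inference_dataset: str | None = None,
) -> JVTResult:
    """JVT for an m-gene combinatorial marker.

    Each null iteration draws m distinct genes from the common pool and
    rebuilds the full marker — reference gene, alignment flags on the
    inference dataset (default: the first dataset), mean compression on
    each comparison's samples — so the null competes on equal footing
    with the tested marker. When C(Z, m) <= T the null is enumerated
    exhaustively.
    """
    geneset = [g.strip().upper() for g in geneset]
    m = len(geneset)
    if m < 2:
        raise ValueError("a combinatorial marker needs at least two genes")
    pool = common_gene_pool(datasets)
    Z = len(pool)
    if m > Z:
        raise ValueError(f"marker size {m} exceeds common pool size {Z}")
    missing = [g for g in geneset if g not in pool]
    if missing:
        raise KeyError(f"marker genes outside the common pool: {missing}")
    two_sided = sidedness == "two_sided"
    by_name = {ds.name: ds for ds in datasets}
    inf_name = inference_dataset or datasets[0].name
    if inf_name not in by_name:
        raise KeyError(f"unknown inference dataset {inf_name!r}")
    inference_values = by_name[inf_name].subset_genes(pool).values
    resolved = _resolve_comparisons(datasets, comparisons, pool)

    obs_idx = np.array([pool.index(g) for g in geneset])
    observed, obs_aucs = _score_geneset(
        obs_idx, inference_values, resolved, operator, two_sided
    )
    per_comparison = [
        AUCResult(comparison=c, auc=a, sidedness=sidedness)
        for c, a in zip(comparisons, obs_aucs)
    ]

    n_draws = math.comb(Z, m)
    if n_draws <= T:
        null = np.array(
            [
                _score_geneset(np.array(idx), inference_values, resolved, operator, two_sided)[0]
                for idx in combinations(range(Z), m)
            ]
        )
        sampling = "exhaustive"
    else:
        keys = _iteration_seeds(seed, T)
        null = np.empty(T)
        for t in range(T):
            rng = np.random.default_rng(keys[t])
            idx = rng.choice(Z, size=m, replace=False)
            null[t] = _score_geneset(idx, inference_values, resolved, operator, two_sided)[0]
        sampling = "monte_carlo"
    return JVTResult(
        observed=observed,
        null_sample=null,
        T=len(null),
        pool_size=Z,
        p_value=empirical_pvalue(null, observed),
        p_smoothed=empirical_pvalue(null, observed, smoothed=True),
        seed=seed,
        mode="combinatorial",
        m=m,
        sampling=sampling,
        operator=operator,
        sidedness=sidedness,
        per_comparison=per_comparison,
    )
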