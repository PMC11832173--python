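"""Combinatorial marker: reference gene, direction alignment, compression.

A gene module found by network inference is compressed into a single
per-sample score in three steps: (1) the dataset is normalized
(log or z-score); (2) genes anticorrelated with a reference gene —
the module gene with the highest average pairwise Pearson correlation
to the others — are direction-aligned by reflection about their mean,
``align(g) = 2*mean(g) - g``, so that anticorrelated genes reinforce
rather than cancel; (3) the per-sample mean over the (aligned) module
genes is the combinatorial marker score ``g_comb``.

Alignment flags are fitted once on the inference dataset and reused on
validation datasets; the reflection mean is always taken on the dataset
being scored.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import ExpressionDataset, canonicalize_gene

logger = logging.getLogger(__name__)


@dataclass
class CombinatorialMarker:
    """A fitted combinatorial marker: gene set, reference, alignment flags."""

    genes: list[str]
    reference: str
    align_flags: dict[str, bool]
    normalization: str = "log1p"

    def __post_init__(self) -> None:
        if self.reference not in self.genes:
            raise ValueError("reference gene must be one of the marker genes")
        if self.align_flags.get(self.reference, False):
            raise ValueError("the reference gene is never aligned")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "genes": self.genes,
                    "reference": self.reference,
                    "align_flags": self.align_flags,
                    "normalization": self.normalization,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CombinatorialMarker":
        d = json.loads(Path(path).read_text())
        return cls(
            genes=list(d["genes"]),
            reference=d["reference"],
            align_flags={k: bool(v) for k, v in d["align_flags"].items()},
            normalization=d.get("normalization", "log1p"),
        )


@dataclass
class MarkerScores:
    """Per-sample compressed marker values on one dataset."""

    dataset_name: str
    samples: list[str]
    values: np.ndarray       # g_comb per sample
    gene_means: np.ndarray   # per-gene means used for alignment reflection


# ---------------------------------------------------------------------------
# Array-level primitives (shared with the JVT null-model machinery)
# ---------------------------------------------------------------------------

def _pairwise_corr(matrix: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.atleast_2d(np.corrcoef(matrix))


def reference_index(matrix: np.ndarray) -> int:
    """Index of the row with the highest mean correlation to the others.

    Ties break to the earliest row. Constant rows make the reference
    choice undefined and raise.
    """
    m = matrix.shape[0]
    if m < 2:
        raise ValueError("reference selection needs at least two genes")
    corr = _pairwise_corr(matrix)
    if np.isnan(corr).any():
        raise ValueError("constant gene row: reference correlation undefined")
    avg = (corr.sum(axis=1) - 1.0) / (m - 1)
    return int(np.argmax(avg))


def alignment_flags(matrix: np.ndarray, ref: int) -> np.ndarray:
    """Boolean flag per row: True where correlation with the reference < 0.

    Constant rows get correlation 0 (flag False) with a warning.
    """
    corr = _pairwise_corr(matrix)[ref]
    if np.isnan(corr).any():
        logger.warning("constant gene row(s): correlation with reference set to 0")
        corr = np.nan_to_num(corr, nan=0.0)
    flags = corr < 0
    flags[ref] = False
    return flags


def compress_values(matrix: np.ndarray, flags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-compress rows of ``matrix``, reflecting flagged rows about their mean.

    Returns ``(g_comb, row_means)``; the means are those of the matrix
    being scored, so alignment is re-centered per dataset.
    """
    means = matrix.mean(axis=1)
    aligned = np.where(flags[:, None], 2.0 * means[:, None] - matrix, matrix)
    return aligned.mean(axis=0), means


# ---------------------------------------------------------------------------
# Dataset-level operations
# ---------------------------------------------------------------------------

def _marker_matrix(ds: ExpressionDataset, genes: Sequence[str]) -> np.ndarray:
    genes = [canonicalize_gene(g) for g in genes]
    missing = [g for g in genes if g not in ds.genes]
    if missing:
        raise KeyError(f"marker genes absent from dataset {ds.name!r}: {missing}")
    return ds.values[[ds.genes.index(g) for g in genes]]


def select_reference_gene(ds: ExpressionDataset, genes: Sequence[str]) -> str:
    """The module gene with the highest average pairwise correlation."""
    genes = [canonicalize_gene(g) for g in genes]
    return genes[reference_index(_marker_matrix(ds, genes))]


def fit_alignment(
    ds: ExpressionDataset, genes: Sequence[str], reference: str
) -> dict[str, bool]:
    """Fit per-gene alignment flags on the inference dataset."""
    genes = [canonicalize_gene(g) for g in genes]
    ref = genes.index(canonicalize_gene(reference))
    flags = alignment_flags(_marker_matrix(ds, genes), ref)
    return dict(zip(genes, map(bool, flags)))


def align_gene(g: np.ndarray) -> np.ndarray:
    """Reflect an expression vector about its mean: ``2*mean(g) - g``.

    An involution that preserves the mean and negates every correlation
    with any fixed vector.
    """
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise ValueError("cannot align an empty expression vector")
    return 2.0 * g.mean() - g


def build_marker(
    ds: ExpressionDataset, genes: Sequence[str], normalization: str | None = None
) -> CombinatorialMarker:
    """Fit a combinatorial marker (reference + flags) on an inference dataset."""
    genes = [canonicalize_gene(g) for g in genes]
    reference = select_reference_gene(ds, genes)
    flags = fit_alignment(ds, genes, reference)
    return CombinatorialMarker(
        genes=genes,
        reference=reference,
        align_flags=flags,
        normalization=normalization or ds.norm_state,
    )


def compress(ds: ExpressionDataset, marker: CombinatorialMarker) -> MarkerScores:
    """Score a dataset with a fitted marker.

    The dataset must carry the marker's normalization state; alignment
    means are computed on this dataset's samples.
    """
    if ds.norm_state != marker.normalization:
        raise ValueError(
            f"dataset {ds.name!r} is {ds.norm_state}-normalized but the marker "
            f"expects {marker.normalization}"
        )
    matrix = _marker_matrix(ds, marker.genes)
    flags = np.array([marker.align_flags[g] for g in marker.genes])
    values, means = compress_values(matrix, flags)
    return MarkerScores(
        dataset_name=ds.name, samples=list(ds.samples), values=values, gene_means=means
    )


def write_scores(scores: MarkerScores, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tg_comb\n")
        for s, v in zip(scores.samples, scores.values):
            fh.write(f"{s}\t{v!r}\n")
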