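"""Expression-dataset container, I/O, normalization, and gene-set alignment.

A study is a collection of named *views*: gene-by-sample expression
matrices with a two-group (or multi-group) sample annotation. All
downstream analysis (PCA loadings, PC-corr networks, combinatorial
markers, JVT) operates on :class:`ExpressionDataset` objects produced
here. Gene identifiers are canonicalized by upper-casing so that, e.g.,
human ``CAV1`` and mouse ``Cav1`` match when datasets from different
species are intersected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Normalization states a dataset can be in.
NORM_STATES = ("raw", "log10", "zscore", "log1p")


class DataValidationError(ValueError):
    """Raised when an input matrix or annotation violates the data contract."""


def canonicalize_gene(symbol: str) -> str:
    """Canonical gene identifier: stripped, upper-cased symbol."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionDataset:
    """One view of a study: a gene x sample real matrix with group labels.

    Parameters
    ----------
    name
        Label for the view (e.g. ``"glioblastoma"``).
    genes
        Ordered unique canonicalized gene identifiers (rows).
    samples
        Ordered unique sample identifiers (columns).
    values
        Real matrix of shape ``(len(genes), len(samples))``, no missing
        values.
    sample_groups
        Total map sample id -> group label.
    norm_state
        One of ``raw``, ``log10``, ``zscore``, ``log1p``.
    """

    name: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    sample_groups: dict[str, str]
    norm_state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            bad = np.argwhere(np.isnan(self.values))[0]
            raise DataValidationError(
                f"missing value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r} (imputation is not performed)"
            )
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise DataValidationError(f"duplicate sample identifiers: {dupes}")
        missing = [s for s in self.samples if s not in self.sample_groups]
        if missing:
            raise DataValidationError(
                f"samples without group annotation in dataset {self.name!r}: {missing}"
            )
        if self.norm_state not in NORM_STATES:
            raise DataValidationError(f"unknown norm_state {self.norm_state!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(canonicalize_gene(gene))
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset {self.name!r}") from None

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across samples."""
        return self.values[self.gene_index(gene)]

    def group_vector(self) -> np.ndarray:
        """Group label per sample, aligned with :attr:`samples`."""
        return np.array([self.sample_groups[s] for s in self.samples])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given genes, in the given order."""
        genes = [canonicalize_gene(g) for g in genes]
        idx = [self.gene_index(g) for g in genes]
        return replace(self, genes=list(genes), values=self.values[idx])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        idx = [self.samples.index(s) for s in samples]
        return replace(self, samples=list(samples), values=self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-class comparison within one named dataset.

    ``group_a`` is by convention the positive (stiff) side, ``group_b``
    the soft side; each is a set of group labels pooled into one class.
    """

    dataset_name: str
    group_a: frozenset[str]
    group_b: frozenset[str]

    def __init__(self, dataset_name: str, group_a: Iterable[str], group_b: Iterable[str]):
        object.__setattr__(self, "dataset_name", dataset_name)
        object.__setattr__(self, "group_a", frozenset([group_a] if isinstance(group_a, str) else group_a))
        object.__setattr__(self, "group_b", frozenset([group_b] if isinstance(group_b, str) else group_b))
        if self.group_a & self.group_b:
            raise DataValidationError(
                f"group_a and group_b overlap: {sorted(self.group_a & self.group_b)}"
            )

    def resolve(self, ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks (is_a, is_b) over the dataset's samples."""
        groups = ds.group_vector()
        mask_a = np.isin(groups, list(self.group_a))
        mask_b = np.isin(groups, list(self.group_b))
        if not mask_a.any() or not mask_b.any():
            raise DataValidationError(
                f"comparison {self} resolves to an empty class in dataset {ds.name!r}"
            )
        return mask_a, mask_b


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_annotations(annotation_path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table with columns sample_id, dataset, group."""
    ann = pd.read_csv(annotation_path, sep=_sep_for(Path(annotation_path)), dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(ann.columns):
        raise DataValidationError(
            f"annotation file {annotation_path} must have columns "
            f"'sample_id' and 'group' (found {list(ann.columns)})"
        )
    return ann


def read_expression_matrix(
    matrix_path: str | Path,
    annotation_path: str | Path,
    dataset_name: str,
    *,
    transpose: bool = False,
) -> ExpressionDataset:
    """Load a delimited expression matrix plus its sample annotation.

    The matrix is delimited text (TSV, or CSV by extension) with gene
    identifiers in the first column and sample identifiers in the header
    row; ``transpose=True`` accepts sample-major files. The annotation
    table must cover every sample in the matrix; annotation rows for
    absent samples are ignored with a warning.
    """
    matrix_path = Path(matrix_path)
    sep = _sep_for(matrix_path)
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise DataValidationError(
            f"duplicate sample identifiers in {matrix_path}: {dupes}"
        )
    try:
        df = pd.read_csv(matrix_path, sep=sep, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise DataValidationError(f"malformed matrix file {matrix_path}: {exc}") from exc
    if transpose:
        df = df.T
    # locate non-numeric cells before coercion so the error can name them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gi, si = np.argwhere(bad.values)[0]
        raise DataValidationError(
            f"non-numeric value {df.iat[gi, si]!r} at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r} in {matrix_path}"
        )
    if numeric.isna().any().any():
        gi, si = np.argwhere(numeric.isna().values)[0]
        raise DataValidationError(
            f"missing value at gene {df.index[gi]!r}, sample {df.columns[si]!r} "
            f"in {matrix_path}"
        )
    samples = [str(c) for c in df.columns]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise DataValidationError(f"duplicate sample identifiers in {matrix_path}: {dupes}")

    ann = read_annotations(annotation_path)
    if "dataset" in ann.columns:
        scoped = ann[ann["dataset"] == dataset_name]
        ann = scoped if not scoped.empty else ann
    groups = dict(zip(ann["sample_id"], ann["group"]))
    unknown = [s for s in samples if s not in groups]
    if unknown:
        raise DataValidationError(
            f"samples missing from annotations for dataset {dataset_name!r}: {unknown}"
        )
    extra = set(groups) - set(samples)
    if extra:
        logger.warning(
            "annotation rows for %d sample(s) absent from matrix %s ignored: %s",
            len(extra), matrix_path.name, sorted(extra)[:5],
        )
    genes = [canonicalize_gene(g) for g in df.index]
    return ExpressionDataset(
        name=dataset_name,
        genes=genes,
        samples=samples,
        values=numeric.values.astype(float),
        sample_groups={s: groups[s] for s in samples},
        norm_state="raw",
    )


def write_expression_matrix(ds: ExpressionDataset, matrix_path: str | Path,
                            annotation_path: str | Path | None = None) -> None:
    """Write the dataset in the same dialect ``read_expression_matrix`` accepts.

    Numeric text uses full repr precision, so a write/read round-trip
    reproduces the values exactly.
    """
    matrix_path = Path(matrix_path)
    sep = _sep_for(matrix_path)
    with open(matrix_path, "w") as fh:
        fh.write("gene" + sep + sep.join(ds.samples) + "\n")
        for g, row in zip(ds.genes, ds.values):
            fh.write(g + sep + sep.join(repr(float(v)) for v in row) + "\n")
    if annotation_path is not None:
        pd.DataFrame(
            {
                "sample_id": ds.samples,
                "dataset": ds.name,
                "group": [ds.sample_groups[s] for s in ds.samples],
            }
        ).to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def collapse_duplicates(ds: ExpressionDataset) -> ExpressionDataset:
    """Average rows that share a canonicalized gene identifier.

    Microarray platforms report multiple probes per gene; following the
    convention of averaging them, rows with the same canonical symbol
    are replaced by their per-sample arithmetic mean. Output order is
    first occurrence. Idempotent on already-unique input.
    """
    if ds.norm_state != "raw":
        raise DataValidationError("collapse_duplicates expects a raw dataset")
    canon = [canonicalize_gene(g) for g in ds.genes]
    if len(set(canon)) == len(canon):
        return replace(ds, genes=canon)
    order: list[str] = []
    rows: dict[str, list[int]] = {}
    for i, g in enumerate(canon):
        if g not in rows:
            rows[g] = []
            order.append(g)
        rows[g].append(i)
    values = np.vstack([ds.values[rows[g]].mean(axis=0) for g in order])
    return replace(ds, genes=order, values=values)


def normalize(
    ds: ExpressionDataset,
    mode: str,
    pseudocount: float = 1.0,
) -> ExpressionDataset:
    """Normalize a raw dataset.

    ``log10``: x -> log10(x + pseudocount); ``log1p``: x -> ln(x + 1);
    ``zscore``: per-gene standardization across samples with the sample
    (n-1) standard deviation. Constant gene rows z-score to all zeros
    with a warning. Log modes require nonnegative values.
    """
    if ds.norm_state != "raw":
        raise DataValidationError(
            f"dataset {ds.name!r} is already normalized ({ds.norm_state})"
        )
    if mode not in ("log10", "zscore", "log1p"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    x = ds.values
    if mode in ("log10", "log1p") and (x < 0).any():
        raise DataValidationError(
            f"negative values in dataset {ds.name!r}; log normalization undefined"
        )
    if mode == "log10":
        out = np.log10(x + pseudocount)
    elif mode == "log1p":
        out = np.log1p(x)
    else:
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        constant = (sd == 0).ravel()
        if constant.any():
            logger.warning(
                "%d constant gene row(s) in %s map to zeros under z-score",
                int(constant.sum()), ds.name,
            )
        sd[sd == 0] = 1.0
        out = (x - mean) / sd
    return replace(ds, values=out, norm_state=mode)


def intersect_genes(datasets: Sequence[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the common gene set, rows in lexicographic order."""
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to intersect")
    common: set[str] = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise DataValidationError("gene intersection across datasets is empty")
    ordered = sorted(common)
    return [ds.subset_genes(ordered) for ds in datasets]
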