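"""PC-corr discriminative co-expression network inference.

Classical co-expression networks rank gene pairs by correlation alone.
PC-corr additionally weighs each pair by how strongly both genes
contribute to the phenotype separation captured by a principal
component: for dataset *n* and genes *i, j*,

    PC-corr_ij = sgn(c_ij) * min(|V_i|, |V_j|, |c_ij|),

where c_ij is the Pearson correlation of the two gene rows and V is the
*processed* PC loading vector — the raw loadings V0 log-compressed,

    V*_i = sgn(V0_i) * log10(1 + |V0_i| / <|V0|>),

and affinely rescaled in magnitude onto [0, 1] with signs restored, so
that V is comparable with correlation values on [-1, 1]. Per-dataset
PC-corr matrices from several views are merged into a combined score
(mean or minimum of magnitudes, sign by consensus; pairs with no sign
consensus are masked to zero), and thresholding the combined score
yields a conserved discriminative network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .datasets import ExpressionDataset
from .evaluation import auc_roc

logger = logging.getLogger(__name__)


@dataclass
class ComponentLoadings:
    """Loadings and sample scores of one principal component.

    ``raw`` holds the unit-norm per-gene loading vector (V0),
    ``normalized`` the log-compressed vector (V*), ``processed`` the
    magnitude-rescaled vector (V) on [-1, 1], and ``scores`` the
    per-sample coordinates on the component. ``component_index`` is
    1-based (PC1 = 1).
    """

    component_index: int
    raw: np.ndarray
    normalized: np.ndarray
    processed: np.ndarray
    scores: np.ndarray
    explained_variance: float = 0.0

    def flipped(self) -> "ComponentLoadings":
        """The same component with all signs inverted."""
        return ComponentLoadings(
            component_index=self.component_index,
            raw=-self.raw,
            normalized=-self.normalized,
            processed=-self.processed,
            scores=-self.scores,
            explained_variance=self.explained_variance,
        )


@dataclass
class PCCorrResult:
    """Per-dataset pairwise PC-corr scores."""

    dataset_name: str
    genes: list[str]
    corr: np.ndarray      # symmetric Pearson matrix c
    pccorr: np.ndarray    # symmetric PC-corr matrix, zero diagonal
    loadings: ComponentLoadings | None = None


@dataclass
class CombinedNetwork:
    """Cross-dataset combined PC-corr matrix and its thresholded network."""

    genes: list[str]
    comb: np.ndarray          # combined PC-corr, masked pairs = 0
    sign_mask: np.ndarray     # delta in {-1, 0, 1}
    method: str               # "mean" or "min"
    n_datasets: int
    cutoff: float = 0.0
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    node_loading: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b, _ in self.edges:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, mean_processed_loading=self.node_loading.get(node, 0.0))
        for a, b, w in self.edges:
            g.add_edge(a, b, pccorr_comb=w, sign=int(np.sign(w)))
        return g


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def compute_pca(ds: ExpressionDataset, n_components: int) -> list[ComponentLoadings]:
    """PCA of a normalized dataset with genes as features.

    Each gene row is mean-centered across samples; the centered
    samples x genes matrix is decomposed by SVD. Per-gene loadings are
    the unit-norm right singular vectors, per-sample scores their
    projections. Components are oriented so the gene with the largest
    absolute loading has a positive loading, which makes the
    decomposition deterministic.
    """
    if ds.norm_state == "raw":
        raise ValueError("compute_pca expects a normalized dataset")
    if n_components < 1:
        raise ValueError("n_components must be positive")
    max_comp = min(ds.n_genes, ds.n_samples)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples)={max_comp}"
        )
    centered = ds.values - ds.values.mean(axis=1, keepdims=True)  # genes x samples
    if not centered.any():
        raise ValueError("all-constant matrix has no principal components")
    # samples x genes orientation: scores = U*S rows, loadings = V columns
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(centered.shape) * np.finfo(float).eps))
    if n_components > rank:
        logger.warning(
            "requested %d components but rank is %d; truncating", n_components, rank
        )
        n_components = rank
    components: list[ComponentLoadings] = []
    denom = max(ds.n_samples - 1, 1)
    for k in range(n_components):
        loadings = vt[k]
        scores = u[:, k] * s[k]
        top = int(np.argmax(np.abs(loadings)))
        if loadings[top] < 0:
            loadings, scores = -loadings, -scores
        normalized, processed = process_loadings(loadings)
        components.append(
            ComponentLoadings(
                component_index=k + 1,
                raw=loadings,
                normalized=normalized,
                processed=processed,
                scores=scores,
                explained_variance=float(s[k] ** 2 / denom),
            )
        )
    return components


def orient_to_groups(
    component: ComponentLoadings, mask_a: np.ndarray, mask_b: np.ndarray
) -> ComponentLoadings:
    """Flip the component so the mean score of class a >= class b.

    Ties keep the current sign, so orientation is deterministic.
    """
    if component.scores[mask_a].mean() < component.scores[mask_b].mean():
        return component.flipped()
    return component


def select_component(
    components: Sequence[ComponentLoadings],
    labels: Sequence,
    strategy: int | str = "auto",
) -> int:
    """Choose the component whose scores best separate the two classes.

    ``strategy`` may be a fixed 1-based component index, or ``"auto"``,
    which returns the component with the highest two-sided AUC-ROC of
    its sample scores against the class labels (ties -> smallest index).
    """
    if isinstance(strategy, int):
        if not 1 <= strategy <= len(components):
            raise ValueError(f"component index {strategy} out of range")
        return strategy
    if strategy != "auto":
        raise ValueError(f"unknown strategy {strategy!r}")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(
            f"auto component selection needs exactly two classes, got {len(classes)}"
        )
    binary = labels == classes[0]
    best_idx, best_auc = 1, -1.0
    for comp in components:
        auc = auc_roc(comp.scores, binary, sidedness="two_sided")
        if auc > best_auc + 1e-12:
            best_idx, best_auc = comp.component_index, auc
    return best_idx


def select_components_joint(
    views: Sequence[tuple[ExpressionDataset, Sequence[ComponentLoadings]]],
    method: str = "mean",
    top_edges: int = 10,
) -> list[int]:
    """Choose one component per view by maximizing cross-view conservation.

    Per-view score-based selection is unreliable when the
    discriminative module is small relative to the background: with few
    samples, several noise components can separate the classes as well
    as the signal component does. The quantity that survives across
    independent views, however, is the conserved PC-corr structure
    itself. This selector therefore scores a candidate component
    combination by the strength of the top ``top_edges`` combined
    PC-corr values it would produce (sign-agreeing pairs only, combined
    by ``method``) and returns the combination with the strongest
    conserved edges — the automated analogue of overlaying per-dataset
    networks and keeping the component pair whose overlap is strongest.

    For two views all component pairs are scored exhaustively; further
    views are added greedily against the running combination. Returns
    1-based component indices, one per view.
    """
    if len(views) < 2:
        raise ValueError("joint selection needs at least two views")
    if method not in ("mean", "min"):
        raise ValueError(f"unknown combination method {method!r}")
    n_genes = views[0][0].n_genes
    iu, ju = np.triu_indices(n_genes, k=1)
    top_edges = min(top_edges, len(iu))

    def pair_vectors(ds: ExpressionDataset, comps: Sequence[ComponentLoadings]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.nan_to_num(np.corrcoef(ds.values), nan=0.0)
        absc = np.abs(corr[iu, ju])
        sgnc = np.sign(corr[iu, ju])
        out = []
        for comp in comps:
            absv = np.abs(comp.processed)
            bound = np.minimum(np.minimum(absv[iu], absv[ju]), absc)
            out.append(sgnc * bound)
        return out

    per_view = [pair_vectors(ds, comps) for ds, comps in views]

    def combine(vectors: Sequence[np.ndarray]) -> np.ndarray:
        signs = np.sign(vectors[0])
        agree = np.ones_like(signs, dtype=bool)
        for v in vectors[1:]:
            agree &= np.sign(v) == signs
        mags = np.abs(np.stack(vectors))
        m = mags.mean(axis=0) if method == "mean" else mags.min(axis=0)
        return np.where(agree & (signs != 0), m, 0.0)

    def top_score(m: np.ndarray) -> float:
        return float(np.partition(m, len(m) - top_edges)[-top_edges:].mean())

    best_pair, best_score = (0, 0), -1.0
    for k, p1 in enumerate(per_view[0]):
        for l, p2 in enumerate(per_view[1]):
            s = top_score(combine([p1, p2]))
            if s > best_score:
                best_pair, best_score = (k, l), s
    chosen = [best_pair[0], best_pair[1]]
    for view_vectors in per_view[2:]:
        current = [per_view[i][chosen[i]] for i in range(len(chosen))]
        scores = [top_score(combine(current + [v])) for v in view_vectors]
        chosen.append(int(np.argmax(scores)))
    return [k + 1 for k in chosen]


# ---------------------------------------------------------------------------
# Loading processing
# ---------------------------------------------------------------------------

def process_loadings(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-compress and rescale PC loadings onto [-1, 1].

    Returns ``(normalized, processed)``. The normalization divides each
    absolute loading by the mean absolute loading and log-compresses;
    the scaling maps magnitudes affinely so min -> 0 and max -> 1,
    restoring signs. When all magnitudes are equal the affine step is
    degenerate; magnitudes are then set to 1 (equal importance) with
    signs preserved.
    """
    raw = np.asarray(raw, dtype=float)
    mean_abs = np.abs(raw).mean()
    if mean_abs == 0:
        raise ValueError("all-zero loading vector cannot be processed")
    normalized = np.sign(raw) * np.log10(1.0 + np.abs(raw) / mean_abs)
    mags = np.abs(normalized)
    lo, hi = mags.min(), mags.max()
    if hi == lo:
        processed = np.sign(normalized).astype(float)
    else:
        processed = np.sign(normalized) * (mags - lo) / (hi - lo)
    return normalized, processed


# ---------------------------------------------------------------------------
# PC-corr scoring and combination
# ---------------------------------------------------------------------------

def pccorr_matrix(ds: ExpressionDataset, processed: np.ndarray) -> PCCorrResult:
    """Pairwise PC-corr scores for one dataset.

    ``processed`` is the processed loading vector V aligned with
    ``ds.genes``. Constant gene rows have undefined correlation; their
    pairs are set to zero with a warning.
    """
    processed = np.asarray(processed, dtype=float)
    if processed.shape != (ds.n_genes,):
        raise ValueError("processed loadings not aligned with dataset genes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(ds.values)
    corr = np.atleast_2d(corr)
    if np.isnan(corr).any():
        logger.warning(
            "constant gene rows in %s: correlations set to 0 for their pairs", ds.name
        )
        corr = np.nan_to_num(corr, nan=0.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    absv = np.abs(processed)
    bound = np.minimum(np.minimum.outer(absv, absv), np.abs(corr))
    pcc = np.sign(corr) * bound
    np.fill_diagonal(pcc, 0.0)
    np.fill_diagonal(corr, 1.0)
    return PCCorrResult(dataset_name=ds.name, genes=list(ds.genes), corr=corr, pccorr=pcc)


def combine_pccorr(results: Sequence[PCCorrResult], method: str = "mean") -> CombinedNetwork:
    """Merge per-dataset PC-corr matrices into a combined score.

    The magnitude is the mean or the minimum of the per-dataset
    |PC-corr| values; the sign is the mode of the per-dataset signs.
    Pairs without a strict sign majority among nonzero signs are masked
    to zero — for two datasets this is exactly "opposing signs are
    masked".
    """
    if method not in ("mean", "min"):
        raise ValueError(f"unknown combination method {method!r}")
    if not results:
        raise ValueError("no PC-corr results to combine")
    genes = results[0].genes
    for r in results[1:]:
        if r.genes != genes:
            raise ValueError(
                f"gene lists differ between {results[0].dataset_name!r} "
                f"and {r.dataset_name!r}; intersect and reorder first"
            )
    stack = np.stack([r.pccorr for r in results])  # N x G x G
    signs = np.sign(stack)
    pos = (signs > 0).sum(axis=0)
    neg = (signs < 0).sum(axis=0)
    delta = np.where(pos > neg, 1, np.where(neg > pos, -1, 0)).astype(int)
    mags = np.abs(stack)
    combined_mag = mags.mean(axis=0) if method == "mean" else mags.min(axis=0)
    comb = delta * combined_mag
    np.fill_diagonal(comb, 0.0)
    np.fill_diagonal(delta, 0)
    return CombinedNetwork(
        genes=list(genes),
        comb=comb,
        sign_mask=delta,
        method=method,
        n_datasets=len(results),
    )


def build_network(
    combined: CombinedNetwork,
    cutoff: float,
    node_loadings: Sequence[np.ndarray] | None = None,
    *,
    strict: bool = False,
) -> CombinedNetwork:
    """Threshold the combined PC-corr matrix into an edge list.

    Edges are unordered gene pairs with |comb| >= cutoff (or > cutoff
    when ``strict``); nodes are the endpoints of surviving edges. Node
    attributes carry the mean of the per-dataset processed loadings.
    An empty network is a valid outcome.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    mag = np.abs(combined.comb)
    keep = mag > cutoff if strict else mag >= cutoff
    keep &= combined.comb != 0
    iu, ju = np.triu_indices(len(combined.genes), k=1)
    sel = keep[iu, ju]
    edges = [
        (combined.genes[i], combined.genes[j], float(combined.comb[i, j]))
        for i, j in zip(iu[sel], ju[sel])
    ]
    if node_loadings is not None:
        mean_loading = np.mean(np.stack(node_loadings), axis=0)
        node_loading = dict(zip(combined.genes, mean_loading.astype(float)))
    else:
        node_loading = {}
    endpoints = {g for a, b, _ in edges for g in (a, b)}
    return CombinedNetwork(
        genes=combined.genes,
        comb=combined.comb,
        sign_mask=combined.sign_mask,
        method=combined.method,
        n_datasets=combined.n_datasets,
        cutoff=cutoff,
        edges=edges,
        node_loading={g: node_loading.get(g, 0.0) for g in endpoints},
    )


def percentile_cutoff(combined: CombinedNetwork, percentile: float) -> float:
    """Cutoff at the given percentile of |comb| over all unordered pairs."""
    iu, ju = np.triu_indices(len(combined.genes), k=1)
    return float(np.percentile(np.abs(combined.comb[iu, ju]), percentile))


def export_network(
    net: CombinedNetwork,
    path: str | Path,
    formats: Sequence[str] = ("edge-tsv", "graphml"),
) -> list[Path]:
    """Write the thresholded network as edge/node tables and/or GraphML."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "edge-tsv" in formats:
        edge_path = path / "network_edges.tsv"
        with open(edge_path, "w") as fh:
            fh.write("gene_i\tgene_j\tpccorr_comb\tsign\n")
            for a, b, w in net.edges:
                fh.write(f"{a}\t{b}\t{w!r}\t{int(np.sign(w))}\n")
        node_path = path / "network_nodes.tsv"
        with open(node_path, "w") as fh:
            fh.write("gene\tmean_processed_loading\n")
            for g in net.nodes:
                fh.write(f"{g}\t{net.node_loading.get(g, 0.0)!r}\n")
        written += [edge_path, node_path]
    if "graphml" in formats:
        gml_path = path / "network.graphml"
        nx.write_graphml(net.to_graph(), gml_path)
        written.append(gml_path)
    return written
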