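"""Synthetic multi-view two-class expression studies with a planted module.

The generator emulates the statistical structure the discriminative
network analysis is designed to detect: K independent views (datasets)
of two-class samples (stiff vs soft), a small module of m mutually
correlated genes that also carry the class effect, and a large iid
Gaussian background with no signal.

For sample s with class code y_s in {-1, +1} (stiff = +1), planted
gene g in view k takes the value

    sqrt(rho) * f_s + sqrt(1 - rho) * eps_gs + a_gk * (d / 2) * y_s,

where f_s is a per-sample latent factor shared by the module (within-
class pairwise correlation rho), eps_gs is independent unit noise, d is
the class effect in noise-sd units, and a_gk in {-1, +1} is the per-
gene, per-view effect direction, flipped with probability ``flip_prob``
— mirroring markers whose direction of change differs between
biological systems. Background genes are iid standard normal.

A null variant forces d = 0 while keeping the correlated module, so
specificity of downstream tests can be probed against a module that is
coherent but not discriminative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datasets import ExpressionDataset

STIFF, SOFT = "stiff", "soft"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study design for the synthetic generator.

    Defaults describe the reference design exercised throughout the
    test suite: two views of 6 + 6 samples, 500 genes with a planted
    5-gene module at effect d = 2 (class means two noise-sds apart) and
    within-module correlation 0.6, no direction flips.
    """

    K: int = 2
    G: int = 500
    m: int = 5
    d: float = 2.0
    rho: float = 0.6
    n_a: int = 6
    n_b: int = 6
    flip_prob: float = 0.0
    seed: int = 0
    lognormal: bool = False  # exponentiate to positive "raw" values

    def __post_init__(self) -> None:
        if not 0 < self.m <= self.G:
            raise ValueError("need 0 < m <= G")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.d < 0:
            raise ValueError("effect size d must be nonnegative")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be a probability")
        if min(self.K, self.n_a, self.n_b) < 1:
            raise ValueError("K, n_a, n_b must be positive")


@dataclass
class GroundTruth:
    """What was planted: module genes, per-view effect directions, classes."""

    planted_genes: list[str]
    directions: dict[str, np.ndarray]          # view name -> per-gene sign
    class_of_sample: dict[str, dict[str, str]] = field(default_factory=dict)


def _gene_names(config: SyntheticConfig) -> list[str]:
    width = len(str(config.G))
    planted = [f"MOD{i + 1:0{width}d}" for i in range(config.m)]
    background = [f"BG{i + 1:0{width}d}" for i in range(config.G - config.m)]
    return planted + background


def generate_view(
    config: SyntheticConfig,
    view_index: int,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionDataset, np.ndarray]:
    """One view of the study; returns the dataset and the direction signs.

    With an explicit ``rng`` the caller controls the substream; by
    default the stream is derived from ``(config.seed, view_index)``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, view_index)))
    n = config.n_a + config.n_b
    y = np.concatenate([np.ones(config.n_a), -np.ones(config.n_b)])

    directions = np.where(rng.random(config.m) < config.flip_prob, -1.0, 1.0)
    factor = rng.standard_normal(n)
    eps = rng.standard_normal((config.m, n))
    planted = (
        np.sqrt(config.rho) * factor[None, :]
        + np.sqrt(1.0 - config.rho) * eps
        + directions[:, None] * (config.d / 2.0) * y[None, :]
    )
    background = rng.standard_normal((config.G - config.m, n))
    values = np.vstack([planted, background])
    if config.lognormal:
        values = np.exp(values)

    name = f"view{view_index + 1}"
    samples = [f"{name}_s{i + 1:02d}" for i in range(n)]
    groups = {s: (STIFF if y[i] > 0 else SOFT) for i, s in enumerate(samples)}
    ds = ExpressionDataset(
        name=name,
        genes=_gene_names(config),
        samples=samples,
        values=values,
        sample_groups=groups,
        norm_state="raw",
    )
    return ds, directions


def generate_study(config: SyntheticConfig) -> tuple[list[ExpressionDataset], GroundTruth]:
    """K views from per-view substreams of one seed.

    The planted gene identifiers are identical across views; effect
    directions are resampled per view with ``flip_prob``.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.K)
    datasets: list[ExpressionDataset] = []
    truth = GroundTruth(planted_genes=_gene_names(config)[: config.m], directions={})
    for k, stream in enumerate(streams):
        ds, directions = generate_view(config, k, np.random.default_rng(stream))
        datasets.append(ds)
        truth.directions[ds.name] = directions
        truth.class_of_sample[ds.name] = {
            s: ("a" if g == STIFF else "b") for s, g in ds.sample_groups.items()
        }
    return datasets, truth


def generate_null_study(config: SyntheticConfig) -> tuple[list[ExpressionDataset], GroundTruth]:
    """The same study with the class effect removed (d = 0).

    The ground truth keeps the (now non-discriminative) module identity
    so specificity tests can target it.
    """
    return generate_study(replace(config, d=0.0))


def write_study(
    datasets: Sequence[ExpressionDataset],
    truth: GroundTruth,
    outdir,
) -> None:
    """Write matrices + annotations in the standard dialect plus truth JSON."""
    import json
    from pathlib import Path

    from .datasets import write_expression_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        write_expression_matrix(
            ds, outdir / f"{ds.name}_matrix.tsv", outdir / f"{ds.name}_annotations.tsv"
        )
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "planted_genes": truth.planted_genes,
                "directions": {k: v.tolist() for k, v in truth.directions.items()},
                "class_of_sample": truth.class_of_sample,
            },
            indent=2,
        )
    )
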