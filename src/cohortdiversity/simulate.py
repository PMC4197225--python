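"""Hierarchical log-normal expression simulator with latent subgroups.

The generative model for one latent group of a cohort:

.. math::

    \\mu_g \\sim \\mathrm{Normal}(\\mu_0, \\sigma_g), \\qquad
    \\sigma_P \\sim \\mathrm{InvGamma}(\\alpha, \\beta), \\qquad
    \\log_2 X_{ij} \\sim \\mathrm{Normal}(\\mu_g, \\sigma_P)

i.e. every gene *g* gets a mean log2 expression drawn around the overall
mean ``mu0`` with spread ``sigma_g`` (the *within-sample* SD: how much gene
levels differ from each other inside one profile), and a *between-sample*
SD ``sigma_P`` drawn from an inverse-gamma prior (shape ``ig_alpha``, scale
``ig_beta``) controlling how much that gene varies across patients.  With
the defaults ``ig_alpha=15, ig_beta=7`` the prior mean of ``sigma_P`` is
``beta/(alpha-1) = 0.5``.

A cohort with several latent subgroups is built by redrawing the whole set
of per-gene parameters independently for each subgroup with the *same*
hyperparameters — subgroups are exchangeable sub-populations, and more of
them means a more diverse cohort.

Binary profiles for categorical metrics are obtained by z-thresholding the
continuous matrix against its grand mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import CategoricalMatrix, ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "binarize_profiles",
    "ExpressionMatrix",
    "CategoricalMatrix",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All hyperparameters of the hierarchical generative model.

    Parameters
    ----------
    n_genes, n_samples
        Cohort dimensions (genes x samples).
    group_sizes
        Sizes of the latent subgroups; must sum to ``n_samples`` and each
        be at least 1.  ``[n_samples]`` means a homogeneous cohort.
    mu0
        Overall mean log2 expression.
    sigma_g
        Within-sample SD: spread of per-gene means across genes.
    ig_alpha, ig_beta
        Inverse-gamma hyperparameters for the between-sample variability
        draw; ``ig_alpha`` must exceed 1 so the prior mean
        ``ig_beta / (ig_alpha - 1)`` is finite.
    ig_on
        Scale the inverse-gamma draw lives on: ``"sd"`` (default) draws
        ``sigma_P`` itself, so its prior mean is ``beta/(alpha-1)`` on the
        SD scale; ``"variance"`` draws the variance and takes its root.
    seed
        Root seed; per-group streams are derived deterministically so the
        draws of group *k* do not depend on how many groups follow it.
    """

    n_genes: int
    n_samples: int
    group_sizes: tuple = ()
    mu0: float = 8.0
    sigma_g: float = 1.5
    ig_alpha: float = 15.0
    ig_beta: float = 7.0
    ig_on: str = "sd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be positive")
        sizes = tuple(int(s) for s in (self.group_sizes or (self.n_samples,)))
        object.__setattr__(self, "group_sizes", sizes)
        if any(s < 1 for s in sizes):
            raise ValueError("every group size must be >= 1")
        if sum(sizes) != self.n_samples:
            raise ValueError(
                f"group_sizes {sizes} sum to {sum(sizes)}, not n_samples="
                f"{self.n_samples}"
            )
        if self.ig_alpha <= 1:
            raise ValueError("ig_alpha must be > 1 for a finite prior mean")
        if self.ig_beta <= 0:
            raise ValueError("ig_beta must be positive")
        if self.sigma_g < 0:
            raise ValueError("sigma_g must be non-negative")
        if self.ig_on not in ("sd", "variance"):
            raise ValueError("ig_on must be 'sd' or 'variance'")

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "group_sizes": list(self.group_sizes),
            "mu0": self.mu0,
            "sigma_g": self.sigma_g,
            "ig_alpha": self.ig_alpha,
            "ig_beta": self.ig_beta,
            "ig_on": self.ig_on,
            "seed": self.seed,
        }


def simulate_cohort(config: SimulationConfig) -> ExpressionMatrix:
    """Draw one cohort from the hierarchical model.

    Each latent group independently redraws the per-gene means ``mu_g`` and
    per-gene between-sample SDs ``sigma_P`` (gene identity is positional
    across groups), then fills its block of samples with
    ``Normal(mu_g, sigma_P)`` values on the log2 scale.

    Returns an :class:`ExpressionMatrix` whose ``group_labels`` record the
    latent membership (``g1``, ``g2``, ...) and whose metadata echoes the
    config.  Bit-identical for identical config (including seed).
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.group_sizes))
    blocks = []
    labels = []
    for k, (size, ss) in enumerate(zip(config.group_sizes, streams), start=1):
        rng = np.random.default_rng(ss)
        mu_g = rng.normal(config.mu0, config.sigma_g, size=config.n_genes)
        draw = stats.invgamma.rvs(
            config.ig_alpha,
            scale=config.ig_beta,
            size=config.n_genes,
            random_state=rng,
        )
        sigma_p = draw if config.ig_on == "sd" else np.sqrt(draw)
        blocks.append(
            rng.normal(mu_g[:, None], sigma_p[:, None], size=(config.n_genes, size))
        )
        labels.extend([f"g{k}"] * size)
    values = np.concatenate(blocks, axis=1)
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    sample_ids = [f"S{j + 1:03d}" for j in range(config.n_samples)]
    return ExpressionMatrix(
        values,
        gene_ids,
        sample_ids,
        group_labels=labels,
        metadata={"simulation": config.to_dict()},
    )


def binarize_profiles(
    X: ExpressionMatrix, z_threshold: float = 1.5
) -> CategoricalMatrix:
    """Threshold a continuous matrix into 0/1 calls.

    An entry is 1 iff ``(x - M) / SD > z_threshold`` where *M* and *SD* are
    the grand (whole-matrix) mean and population (ddof=0) standard
    deviation.  A constant matrix (SD = 0) is rejected.
    """
    m = float(X.values.mean())
    sd = float(X.values.std(ddof=0))
    if sd == 0.0:
        raise ValueError(
            "cannot binarize a constant expression matrix (overall SD is zero)"
        )
    calls = ((X.values - m) / sd > z_threshold).astype(int)
    return CategoricalMatrix(
        calls,
        list(X.gene_ids),
        list(X.sample_ids),
        alphabet=(0, 1),
        metadata={
            "binarize": {
                "z_threshold": float(z_threshold),
                "grand_mean": m,
                "grand_sd": sd,
                "sd_flavor": "population (ddof=0)",
                "center": "whole-matrix grand mean",
            }
        },
    )
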