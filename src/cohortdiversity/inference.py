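"""Bootstrap diversity estimation, permutation testing, variance decomposition.

Within-group diversity is estimated by resampling ``group_size`` samples
with replacement ``n_boot`` times and summarizing the chosen distance on
each resample.  Two groups' bootstrap vectors are compared with a
permutation test on the difference of means,
``p = (1 + #(D > d)) / (1 + R)``, whose smallest attainable value is
``1/(1+R)``.

The variance decomposition estimates the hierarchical model parameters
from a cohort: the within-sample SD from the SD of the per-gene centroid
vector, the between-sample SD from the mean of the per-gene across-sample
variances.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .containers import CategoricalMatrix, ExpressionMatrix
from .metrics import (
    _cosine_distances,
    _gower_diag,
    _hamming_distances,
    _pearson_distances,
)

__all__ = [
    "DiversityResult",
    "VarianceEstimates",
    "bootstrap_diversity",
    "permutation_test",
    "estimate_variances",
]

METRICS_EXPRESSION = ("pearson", "cosine", "dispersion")
METRICS_CATEGORICAL = ("hamming",)


@dataclass
class DiversityResult:
    """Bootstrap distribution of a group's diversity summary."""

    group_id: str
    boot_values: np.ndarray
    n_boot: int
    group_size: int
    metric: str
    summary_stat: str
    seed: int

    def __post_init__(self) -> None:
        self.boot_values = np.asarray(self.boot_values, dtype=float)
        if self.boot_values.shape != (self.n_boot,):
            raise ValueError("boot_values length must equal n_boot")
        if not np.all(np.isfinite(self.boot_values)):
            raise ValueError("boot_values contains non-finite entries")

    @property
    def mean(self) -> float:
        return float(self.boot_values.mean())


@dataclass
class VarianceEstimates:
    """Hierarchical-model parameter estimates from one cohort."""

    mu0_hat: float
    sigma_g_hat: float
    sigma_p_hat: float


def _group_stream(seed: int, group: str) -> np.random.Generator:
    # per-group stream keyed by group name, independent of which other
    # groups are present in the run
    h = int.from_bytes(hashlib.sha256(group.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


def _summary(arr: np.ndarray, stat: str) -> float:
    return float(np.median(arr)) if stat == "median" else float(arr.mean())


def bootstrap_diversity(
    matrix,
    labels,
    metric: str = "dispersion",
    group_size: int = 100,
    n_boot: int = 500,
    summary_stat: str = "mean",
    seed: int = 0,
    pearson_scale: str = "half",
) -> dict:
    """Bootstrap the within-group diversity of each labeled group.

    Parameters
    ----------
    matrix
        :class:`ExpressionMatrix` (metrics ``pearson``, ``cosine``,
        ``dispersion``) or :class:`CategoricalMatrix` (``hamming``).
    labels
        Group name per sample: a sequence aligned with the columns or a
        mapping from sample id to group.
    metric
        ``dispersion`` (default) embeds the pairwise Pearson distance
        matrix of the resample and summarizes per-sample centroid
        distances; the pairwise metrics summarize the unique off-diagonal
        distances.
    group_size, n_boot
        Resample size (with replacement; duplicates are retained as
        coincident points) and number of bootstrap iterations.

    Returns
    -------
    dict mapping group name to :class:`DiversityResult`.
    """
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if summary_stat not in ("mean", "median"):
        raise ValueError("summary_stat must be 'mean' or 'median'")
    if isinstance(matrix, ExpressionMatrix):
        if metric not in METRICS_EXPRESSION:
            raise ValueError(
                f"metric {metric!r} is not valid for expression data "
                f"(choose from {METRICS_EXPRESSION})"
            )
        values = matrix.values
    elif isinstance(matrix, CategoricalMatrix):
        if metric not in METRICS_CATEGORICAL:
            raise ValueError(
                f"metric {metric!r} is not valid for categorical data "
                f"(choose from {METRICS_CATEGORICAL})"
            )
        _, codes = np.unique(matrix.values, return_inverse=True)
        values = codes.reshape(matrix.values.shape)
    else:
        raise TypeError("matrix must be an ExpressionMatrix or CategoricalMatrix")

    if isinstance(labels, dict):
        missing = [s for s in matrix.sample_ids if s not in labels]
        if missing:
            raise ValueError(f"labels missing for sample(s) {missing[:10]}")
        per_sample = [str(labels[s]) for s in matrix.sample_ids]
    else:
        per_sample = [str(x) for x in labels]
        if len(per_sample) != matrix.n_samples:
            raise ValueError("labels must have one entry per sample")

    groups = sorted(set(per_sample))
    indices = {g: np.flatnonzero([lab == g for lab in per_sample]) for g in groups}

    iu = np.triu_indices(group_size, k=1)
    results: dict[str, DiversityResult] = {}
    for g in groups:
        rng = _group_stream(seed, g)
        pool = indices[g]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.choice(pool, size=group_size, replace=True)
            sub = values[:, idx]
            if metric == "pearson":
                boots[b] = _summary(_pearson_distances(sub, pearson_scale)[iu],
                                    summary_stat)
            elif metric == "cosine":
                boots[b] = _summary(_cosine_distances(sub)[iu], summary_stat)
            elif metric == "hamming":
                boots[b] = _summary(_hamming_distances(sub)[iu], summary_stat)
            else:  # dispersion over Pearson distances
                d = _pearson_distances(sub, pearson_scale)
                per = np.sqrt(np.clip(_gower_diag(d), 0.0, None))
                boots[b] = _summary(per, summary_stat)
        results[g] = DiversityResult(
            group_id=g,
            boot_values=boots,
            n_boot=n_boot,
            group_size=group_size,
            metric=metric,
            summary_stat=summary_stat,
            seed=seed,
        )
    return results


def permutation_test(boot_a, boot_b, n_perm: int = 100_000, seed: int = 0) -> float:
    """Permutation p-value for the difference in bootstrap means.

    The two equal-length bootstrap vectors are concatenated; each of the
    ``n_perm`` permutations shuffles the pooled vector without replacement
    and takes ``D = |mean(first half) - mean(second half)|``; the observed
    statistic is ``d = |mean(a) - mean(b)|``, and

    ``p = (1 + #(D > d)) / (1 + n_perm)``

    so the smallest attainable p-value is ``1/(1 + n_perm)``.  Symmetric
    in its arguments.
    """
    a = np.asarray(getattr(boot_a, "boot_values", boot_a), dtype=float).ravel()
    b = np.asarray(getattr(boot_b, "boot_values", boot_b), dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(
            f"bootstrap vectors must have equal length (got {a.size} and {b.size})"
        )
    if a.size == 0:
        raise ValueError("bootstrap vectors are empty")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    m = a.size
    # the permutation law is invariant to the pooled order; sorting makes the
    # p-value exactly symmetric under swapping the two arguments
    pooled = np.sort(np.concatenate([a, b]))
    total = pooled.sum()
    d = abs(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    exceed = 0
    # chunked vectorized permutations: shuffle via argsort of random keys
    chunk = max(1, min(n_perm, 20_000_000 // (2 * m)))
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        order = np.argsort(rng.random((c, 2 * m)), axis=1)[:, :m]
        first = pooled[order].sum(axis=1)
        big_d = np.abs(first / m - (total - first) / m)
        exceed += int((big_d > d).sum())
        done += c
    return (1 + exceed) / (1 + n_perm)


def estimate_variances(X: ExpressionMatrix) -> VarianceEstimates:
    """Decompose a cohort into hierarchical-model parameter estimates.

    With ``m_i`` the mean of gene *i* across samples (the centroid
    vector) and ``s_i^2`` its across-sample variance:

    * ``mu0_hat``     = mean over genes of ``m``,
    * ``sigma_g_hat`` = SD over genes of ``m`` (within-sample SD),
    * ``sigma_p_hat`` = sqrt of the mean over genes of ``s_i^2``
      (between-sample SD).

    Sample (ddof=1) variances throughout.  In cohorts with several latent
    subgroups the between-group spread inflates ``sigma_p_hat`` and
    deflates ``sigma_g_hat`` relative to the generating values.
    """
    if X.n_genes < 2 or X.n_samples < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    m = X.values.mean(axis=1)
    s2 = X.values.var(axis=1, ddof=1)
    return VarianceEstimates(
        mu0_hat=float(m.mean()),
        sigma_g_hat=float(m.std(ddof=1)),
        sigma_p_hat=float(np.sqrt(s2.mean())),
    )
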