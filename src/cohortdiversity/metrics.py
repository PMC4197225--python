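"""Pairwise distance matrices and the principal-coordinate dispersion distance.

Four distances over sample profiles are provided:

* Pearson distance ``d = (1 - rho) / 2`` (columns correlated over genes),
* cosine distance ``d = angle(x, y) / pi`` (normalized angle),
* Hamming distance (fraction of mismatching positions, categorical data),
* dispersion distance: each sample's Euclidean distance to the cohort
  centroid in the principal-coordinate (PCoA) embedding of any pairwise
  distance matrix.

The dispersion step never builds the embedding explicitly: after Gower
double-centering ``G = J (-1/2 D∘D) J`` with ``J = I - 11'/n``, the
diagonal ``G_ii`` *is* the squared distance of sample *i* to the centroid,
with negative eigenvalues ("imaginary" axes of a non-Euclidean input)
entering with a minus sign.  Negative squared distances are clamped to
zero and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import CategoricalMatrix, DistanceMatrix, ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "DispersionResult",
    "pearson_distance_matrix",
    "cosine_distance_matrix",
    "hamming_distance_matrix",
    "dispersion_distances",
    "summarize_diversity",
    "filter_expression",
    "gower_center",
]

logger = logging.getLogger(__name__)
logger.addHandler(logging.NullHandler())

#: eigenvalues below -EIG_TOL * max|eig| count as genuinely negative
EIG_TOL = 1e-10


# ---------------------------------------------------------------------------
# array-level kernels (no container validation; used by the bootstrap loop)
# ---------------------------------------------------------------------------

def _pearson_distances(values: np.ndarray, scale: str = "half") -> np.ndarray:
    """Pairwise Pearson distances between the columns of ``values``."""
    sds = values.std(axis=0)
    if np.any(sds == 0):
        raise ValueError(
            f"constant column(s) at positions {np.flatnonzero(sds == 0).tolist()}: "
            "Pearson correlation is undefined"
        )
    rho = np.clip(np.corrcoef(values, rowvar=False), -1.0, 1.0)
    if scale == "half":
        d = (1.0 - rho) / 2.0
    elif scale == "one-minus-rho":
        d = 1.0 - rho
    else:
        raise ValueError("pearson scale must be 'half' or 'one-minus-rho'")
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def _cosine_distances(values: np.ndarray) -> np.ndarray:
    """Pairwise normalized-angle distances between the columns."""
    norms = np.linalg.norm(values, axis=0)
    if np.any(norms == 0):
        raise ValueError(
            f"zero-norm column(s) at positions {np.flatnonzero(norms == 0).tolist()}: "
            "cosine distance is undefined"
        )
    unit = values / norms
    cos = np.clip(unit.T @ unit, -1.0, 1.0)
    d = np.arccos(cos) / np.pi
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return d


def _hamming_distances(codes: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Pairwise Hamming distances between columns of an integer-coded matrix."""
    d = squareform(pdist(codes.T, metric="hamming"))
    if not normalized:
        d = d * codes.shape[0]
    return d


def _gower_diag(d: np.ndarray) -> np.ndarray:
    """Diagonal of the Gower-centered matrix without forming it.

    For ``A = -1/2 D∘D``, ``diag(JAJ)_i = a_ii - 2 rowmean_i + grandmean``
    and ``a_ii = 0``, so only row means are needed.
    """
    a = -0.5 * d * d
    rm = a.mean(axis=1)
    return -2.0 * rm + a.mean()


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def pearson_distance_matrix(
    X: ExpressionMatrix,
    genes=None,
    scale: str = "half",
) -> DistanceMatrix:
    """Pairwise Pearson distances between sample profiles.

    ``d_ij = (1 - rho_ij) / 2`` (default scale) where ``rho_ij`` is the
    Pearson correlation of sample columns *i*, *j* over the selected genes,
    mapping [-1, 1] onto [0, 1].  ``scale="one-minus-rho"`` gives
    ``1 - rho`` instead.
    """
    if genes is not None:
        X = X.subset_genes(genes)
    if X.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sds = X.values.std(axis=0)
    if np.any(sds == 0):
        bad = [X.sample_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant expression column(s) for sample(s) {bad}")
    return DistanceMatrix(_pearson_distances(X.values, scale=scale), list(X.sample_ids))


def cosine_distance_matrix(X: ExpressionMatrix) -> DistanceMatrix:
    """Pairwise normalized-angle cosine distances between sample profiles.

    ``d_ij = arccos(cos(theta_ij)) / pi`` in [0, 1]; identical vectors map
    to 0, orthogonal to 0.5, antiparallel to 1.
    """
    if X.n_samples < 2:
        raise ValueError("need at least 2 samples")
    norms = np.linalg.norm(X.values, axis=0)
    if np.any(norms == 0):
        bad = [X.sample_ids[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm column(s) for sample(s) {bad}")
    return DistanceMatrix(_cosine_distances(X.values), list(X.sample_ids))


def hamming_distance_matrix(
    C: CategoricalMatrix, normalized: bool = True
) -> DistanceMatrix:
    """Pairwise Hamming distances between categorical profiles.

    The proportion (or, with ``normalized=False``, the count) of the L
    genes at which two samples carry different labels.
    """
    if C.n_samples < 2:
        raise ValueError("need at least 2 samples")
    _, codes = np.unique(C.values, return_inverse=True)
    codes = codes.reshape(C.values.shape)
    return DistanceMatrix(
        _hamming_distances(codes, normalized=normalized), list(C.sample_ids)
    )


@dataclass
class DispersionResult:
    """Per-sample distances to the cohort centroid in PCoA space."""

    per_sample_distance: np.ndarray
    sample_ids: list[str]
    eigenvalues: np.ndarray
    n_negative_eigenvalues: int
    clamped_samples: list[str] = field(default_factory=list)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower double-centering ``G = J (-1/2 D∘D) J`` of a square distance matrix."""
    d = np.asarray(d, dtype=float)
    a = -0.5 * d * d
    rm = a.mean(axis=1, keepdims=True)
    cm = a.mean(axis=0, keepdims=True)
    return a - rm - cm + a.mean()


def dispersion_distances(
    D: DistanceMatrix, centering: str = "gower"
) -> DispersionResult:
    """Distance of every sample to the overall centroid in PCoA space.

    With Gower centering (default, the cited PCoA procedure), the squared
    centroid distance of sample *i* is exactly ``G_ii``: real axes
    (positive eigenvalues) contribute positively and imaginary axes
    (negative eigenvalues, from semimetric inputs) negatively.  Squared
    distances that come out negative are clamped to 0 and listed in
    ``clamped_samples``.

    ``centering="literal"`` double-centers the distance matrix itself
    (no ``-1/2 D^2`` step); provided as a diagnostic only.
    """
    n = D.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    if centering == "gower":
        g = gower_center(D.values)
    elif centering == "literal":
        a = D.values
        g = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()
    else:
        raise ValueError("centering must be 'gower' or 'literal'")
    eigvals = np.linalg.eigvalsh(g)
    tol = EIG_TOL * max(1.0, float(np.abs(eigvals).max(initial=0.0)))
    n_neg = int(np.sum(eigvals < -tol))
    sq = np.diag(g).copy()
    clamped = [D.sample_ids[i] for i in np.flatnonzero(sq < -tol)]
    if clamped:
        logger.warning(
            "%d sample(s) had negative squared centroid distances (clamped to 0): %s",
            len(clamped),
            clamped[:10],
        )
    per = np.sqrt(np.clip(sq, 0.0, None))
    return DispersionResult(
        per_sample_distance=per,
        sample_ids=list(D.sample_ids),
        eigenvalues=eigvals[::-1],  # descending
        n_negative_eigenvalues=n_neg,
        clamped_samples=clamped,
    )


def summarize_diversity(values, stat: str = "mean") -> float:
    """Mean or median summary of a diversity distribution.

    Accepts a :class:`DistanceMatrix` (only the n(n-1)/2 unique
    off-diagonal entries enter), a :class:`DispersionResult` (per-sample
    centroid distances), or any non-empty array of values.  The mean is
    the default summary throughout the package.
    """
    if isinstance(values, DistanceMatrix):
        arr = values.condensed()
    elif isinstance(values, DispersionResult):
        arr = np.asarray(values.per_sample_distance, dtype=float)
    else:
        arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    if stat == "mean":
        return float(arr.mean())
    if stat == "median":
        return float(np.median(arr))
    raise ValueError("stat must be 'mean' or 'median'")


def filter_expression(
    X: ExpressionMatrix,
    low_expr_quantile: float = 0.25,
    low_mad_quantile: float = 0.10,
) -> ExpressionMatrix:
    """Drop low-expression then low-variability genes.

    Step 1 removes genes whose mean expression falls strictly below the
    ``low_expr_quantile`` quantile of gene means; step 2 removes remaining
    genes whose median absolute deviation (MAD) falls strictly below the
    ``low_mad_quantile`` quantile of the remaining MADs.  Genes exactly at
    a cutoff are kept (inclusive threshold).  The filter settings, order
    and ranking statistics are recorded in the output metadata.
    """
    for q, name in ((low_expr_quantile, "low_expr_quantile"),
                    (low_mad_quantile, "low_mad_quantile")):
        if not (0.0 <= q < 1.0):
            raise ValueError(f"{name} must be in [0, 1)")
    means = X.values.mean(axis=1)
    keep1 = means >= np.quantile(means, low_expr_quantile)
    if not keep1.any():
        raise ValueError("expression filter removed all genes")
    vals = X.values[keep1, :]
    mads = np.median(np.abs(vals - np.median(vals, axis=1, keepdims=True)), axis=1)
    keep2 = mads >= np.quantile(mads, low_mad_quantile)
    if not keep2.any():
        raise ValueError("MAD filter removed all genes")
    rows = np.flatnonzero(keep1)[keep2]
    out = ExpressionMatrix(
        X.values[rows, :],
        [X.gene_ids[i] for i in rows],
        list(X.sample_ids),
        group_labels=list(X.group_labels) if X.group_labels else None,
        metadata=dict(X.metadata),
    )
    out.metadata["filter"] = {
        "order": ["mean-expression quartile", "MAD decile"],
        "ranking": {"step1": "mean expression per gene", "step2": "MAD per gene"},
        "low_expr_quantile": float(low_expr_quantile),
        "low_mad_quantile": float(low_mad_quantile),
        "tie_rule": "genes exactly at a cutoff are kept",
        "n_genes_in": X.n_genes,
        "n_genes_out": int(len(rows)),
    }
    return out
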