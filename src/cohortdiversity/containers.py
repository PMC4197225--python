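"""Core in-memory containers shared by all modules.

Matrices are gene x sample (expression, categorical calls) or
sample x sample (distances), with unique string labels on every axis.
Validation happens at construction so downstream code can assume
well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "CategoricalMatrix",
    "DistanceMatrix",
]

#: absolute tolerance used when checking symmetry of distance matrices
SYMMETRY_TOL = 1e-10


def _check_labels(labels, n: int, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"{what}: expected {n} labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for x in labels:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"{what}: duplicate labels {sorted(set(dups))}")
    return labels


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix of log2 expression values.

    Parameters
    ----------
    values
        2-D float array, genes in rows, samples in columns; all finite.
    gene_ids, sample_ids
        Unique row / column labels.
    group_labels
        Optional latent-group or phenotype label per sample.
    metadata
        Free-form provenance (simulation config echo, filter settings, ...).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self.gene_ids = _check_labels(self.gene_ids, self.values.shape[0], "gene_ids")
        self.sample_ids = _check_labels(
            self.sample_ids, self.values.shape[1], "sample_ids"
        )
        if self.group_labels is not None:
            self.group_labels = [str(x) for x in self.group_labels]
            if len(self.group_labels) != self.n_samples:
                raise ValueError("group_labels must have one entry per sample")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to the listed genes (order as given); unknown ids error."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows, :],
            [self.gene_ids[i] for i in rows],
            list(self.sample_ids),
            group_labels=list(self.group_labels) if self.group_labels else None,
            metadata=dict(self.metadata),
        )


@dataclass
class CategoricalMatrix:
    """Gene x sample matrix over a finite label alphabet.

    Used for binary mutation indicators (alphabet ``(0, 1)``) and
    trichotomized copy-number states (``("del", "none", "amp")``).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    alphabet: tuple = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("categorical values must be a 2-D matrix")
        if not self.alphabet:
            self.alphabet = tuple(sorted({x for x in self.values.ravel()}, key=str))
        bad = ~np.isin(self.values, np.asarray(self.alphabet, dtype=self.values.dtype))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"entry {self.values[i, j]!r} at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} not in alphabet {self.alphabet}"
            )
        self.gene_ids = _check_labels(self.gene_ids, self.values.shape[0], "gene_ids")
        self.sample_ids = _check_labels(
            self.sample_ids, self.values.shape[1], "sample_ids"
        )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample x sample matrix with zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} sample ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("distance matrix is not symmetric within tolerance")
        if np.abs(np.diag(self.values)).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("distance matrix diagonal is not zero")
        if self.values.min(initial=0.0) < -SYMMETRY_TOL:
            raise ValueError("distance matrix has negative entries")
        # exact invariants after tolerance checks
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)
        self.sample_ids = _check_labels(self.sample_ids, n, "sample_ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """The n(n-1)/2 unique off-diagonal entries (upper triangle, row order)."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]
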