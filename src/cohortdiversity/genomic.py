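"""Gene-level categorical calls from copy-number segments and mutation tables.

Segmented log2 copy-number ratios are trichotomized into deletion
(ratio < -0.3), amplification (ratio > 0.3) or no effect, then aggregated
to genes: a gene is called deleted or amplified in a sample only if its
entire transcribed region lies inside a single segment carrying that call.
Genes straddling segment boundaries or in uncovered regions are "none".

All interval arithmetic is done on 0-based half-open coordinates;
containment means ``segment.start <= gene.start and gene.end <= segment.end``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CategoricalMatrix

__all__ = [
    "trichotomize_segments",
    "aggregate_to_genes",
    "mutation_matrix",
    "CNA_ALPHABET",
]

CNA_ALPHABET = ("amp", "del", "none")

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "log2_ratio"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end"]


def _validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SEGMENT_COLUMNS if c not in segments.columns]
    if missing:
        raise ValueError(f"segment table missing column(s) {missing}")
    seg = segments.copy()
    if not np.all(np.isfinite(seg["log2_ratio"].to_numpy(dtype=float))):
        raise ValueError("segment table contains non-finite log2 ratios")
    if (seg["start"] < 0).any():
        raise ValueError("segment coordinates must be non-negative")
    bad = seg["start"] >= seg["end"]
    if bad.any():
        rows = seg.index[bad].tolist()[:10]
        raise ValueError(f"segments with start >= end at rows {rows}")
    return seg


def trichotomize_segments(
    segments: pd.DataFrame,
    del_cut: float = -0.3,
    amp_cut: float = 0.3,
) -> pd.DataFrame:
    """Label each segment del / none / amp by its log2 ratio.

    Strict inequalities: ``ratio < del_cut`` is a deletion, ``ratio >
    amp_cut`` an amplification; values exactly at a cutoff are "none".
    Returns a copy with a ``call`` column added.
    """
    if not del_cut < amp_cut:
        raise ValueError("del_cut must be below amp_cut")
    seg = _validate_segments(segments)
    ratio = seg["log2_ratio"].to_numpy(dtype=float)
    call = np.full(len(seg), "none", dtype=object)
    call[ratio < del_cut] = "del"
    call[ratio > amp_cut] = "amp"
    seg["call"] = call
    return seg


def aggregate_to_genes(
    segments: pd.DataFrame,
    genes: pd.DataFrame,
    altered_only: bool = True,
) -> CategoricalMatrix:
    """Aggregate labeled segments to gene-level del/none/amp calls.

    ``segments`` must carry a ``call`` column (see
    :func:`trichotomize_segments`); ``genes`` has columns
    ``gene_id, chrom, start, end``.  A gene gets a sample's segment call
    only when the segment fully contains the transcribed region on the
    same chromosome; otherwise (straddling, uncovered) it is "none".

    Same-sample segments that overlap on a chromosome are an error;
    chromosomes present in only one of the two inputs produce a warning.
    With ``altered_only`` (default) genes called del or amp in no sample
    are dropped, matching the usual restriction of Hamming-distance
    panels to genes altered in at least one patient.
    """
    seg = _validate_segments(segments)
    if "call" not in seg.columns:
        raise ValueError("segments must carry a 'call' column; trichotomize first")
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing column(s) {missing}")
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()[:10]
        raise ValueError(f"duplicate gene id(s) {dups}; collapse transcripts first")

    seg_chroms = set(seg["chrom"])
    gene_chroms = set(genes["chrom"])
    only_seg, only_gene = seg_chroms - gene_chroms, gene_chroms - seg_chroms
    if only_seg or only_gene:
        warnings.warn(
            f"chromosome mismatch: {len(only_seg)} chromosome(s) only in segments, "
            f"{len(only_gene)} only in gene models",
            stacklevel=2,
        )

    samples = sorted(seg["sample"].astype(str).unique())
    gene_ids = genes["gene_id"].astype(str).tolist()
    calls = np.full((len(gene_ids), len(samples)), "none", dtype=object)

    # per (sample, chromosome): sorted, non-overlapping segment arrays
    lookup: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for (sample, chrom), grp in seg.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        overlap = starts[1:] < ends[:-1]
        if overlap.any():
            rows = grp.index[1:][overlap].tolist()[:10]
            raise ValueError(
                f"overlapping segments for sample {sample!r} on {chrom!r} "
                f"at rows {rows}"
            )
        lookup[(str(sample), str(chrom))] = (
            starts,
            ends,
            grp["call"].to_numpy(dtype=object),
        )

    g_chrom = genes["chrom"].astype(str).to_numpy()
    g_start = genes["start"].to_numpy(dtype=np.int64)
    g_end = genes["end"].to_numpy(dtype=np.int64)
    if (g_start >= g_end).any():
        rows = genes.index[g_start >= g_end].tolist()[:10]
        raise ValueError(f"genes with start >= end at rows {rows}")

    for j, sample in enumerate(samples):
        for i in range(len(gene_ids)):
            key = (sample, g_chrom[i])
            if key not in lookup:
                continue
            starts, ends, seg_calls = lookup[key]
            k = int(np.searchsorted(starts, g_start[i], side="right")) - 1
            if k >= 0 and ends[k] >= g_end[i]:
                calls[i, j] = seg_calls[k]

    if altered_only:
        keep = (calls != "none").any(axis=1)
        calls = calls[keep, :]
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        if not gene_ids:
            raise ValueError("no gene is amplified or deleted in any sample")
    return CategoricalMatrix(
        calls,
        gene_ids,
        samples,
        alphabet=CNA_ALPHABET,
        metadata={"altered_only": bool(altered_only)},
    )


def mutation_matrix(table: pd.DataFrame) -> CategoricalMatrix:
    """Collapse a gene x sample mutation-count table to any-vs-none 0/1 calls.

    Entries must be non-negative numbers; any positive count becomes 1.
    A non-codable entry (negative, missing, non-numeric) raises an error
    naming the offending cell.
    """
    values = table.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    bad = ~np.isfinite(numeric) | (numeric < 0)
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        i, j = divmod(flat, values.shape[1])
        raise ValueError(
            f"non-binary-codable entry {values[i, j]!r} at gene "
            f"{table.index[i]!r}, sample {table.columns[j]!r}"
        )
    calls = (numeric.reshape(values.shape) > 0).astype(int)
    return CategoricalMatrix(
        calls,
        [str(g) for g in table.index],
        [str(s) for s in table.columns],
        alphabet=(0, 1),
    )
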