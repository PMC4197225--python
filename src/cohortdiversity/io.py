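"""Readers and writers for the package's plain-text formats.

Supported formats: tab-delimited gene x sample matrices (expression and
categorical), two-column sample label tables, one-id-per-line gene lists,
GMT gene-set collections, SEG copy-number segment tables, BED-like gene
models, YAML simulation configs, and a JSON run manifest.

Missing values are rejected everywhere — the analyses operate on complete
matrices, and silent imputation would bias every distance downstream.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CategoricalMatrix, ExpressionMatrix
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_categorical_matrix",
    "write_categorical_matrix",
    "read_labels",
    "write_labels",
    "read_gene_list",
    "read_gmt",
    "write_gmt",
    "read_seg",
    "read_gene_models",
    "read_simulation_config",
    "write_simulation_config",
    "write_manifest",
    "generate_benchmark_fixtures",
    "BENCHMARK_SCENARIOS",
]

TOOL_VERSION = "cohortdiversity 0.1.0"


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate gene id(s) {dups[:10]}")
    if df.columns.has_duplicates:
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"{path}: duplicate sample id(s) {dups[:10]}")
    return df


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a tab-delimited matrix: genes in rows, sample-id header row.

    Ragged rows, duplicate ids and non-numeric or missing cells (``NA``,
    empty) are errors naming the offending location; nothing is imputed.
    """
    df = _read_table(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing value {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(
        numeric.to_numpy(dtype=float),
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
    )


def write_expression_matrix(X: ExpressionMatrix, path) -> None:
    pd.DataFrame(X.values, index=X.gene_ids, columns=X.sample_ids).to_csv(
        path, sep="\t", index_label="gene_id"
    )


def read_categorical_matrix(path, alphabet=()) -> CategoricalMatrix:
    """Read a tab-delimited categorical matrix (labels as written)."""
    df = _read_table(path)
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    values = df.to_numpy(dtype=object)
    # integer-looking alphabets (mutation 0/1) come back as ints
    try:
        values = df.astype(int).to_numpy()
    except (ValueError, TypeError):
        pass
    return CategoricalMatrix(
        values,
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        alphabet=tuple(alphabet),
    )


def write_categorical_matrix(C: CategoricalMatrix, path) -> None:
    pd.DataFrame(C.values, index=C.gene_ids, columns=C.sample_ids).to_csv(
        path, sep="\t", index_label="gene_id"
    )


# ---------------------------------------------------------------------------
# labels and gene lists
# ---------------------------------------------------------------------------

def read_labels(path) -> dict:
    """Two-column tab-delimited table: sample id, group label (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    first = str(df.iat[0, 0]).lower()
    if first in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    if df.iloc[:, 0].duplicated().any():
        dups = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()[:10]
        raise ValueError(f"{path}: duplicate sample id(s) {dups}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for k, v in labels.items():
            fh.write(f"{k}\t{v}\n")


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path):
    """Read a GMT file: name, description, tab-separated member genes."""
    from .pathways import GeneSetCollection

    sets = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{ln}: GMT line needs name, description and >=1 gene"
            )
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
        genes = [g for g in fields[2:] if g]
        if not genes:
            raise ValueError(f"{path}:{ln}: set {name!r} has no genes")
        sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection, path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# genomic formats
# ---------------------------------------------------------------------------

def read_seg(path, dialect: str = "seg") -> pd.DataFrame:
    """Read a SEG-style segment table.

    Columns: sample, chromosome, start, end, segment value (a num-marks
    column, if present, is ignored; the value is the last column).  A
    header line is tolerated.  ``dialect="seg"`` (default) treats
    coordinates as 1-based inclusive and shifts them to the internal
    0-based half-open convention; ``dialect="bed"`` reads them as already
    0-based half-open.
    """
    if dialect not in ("seg", "bed"):
        raise ValueError("dialect must be 'seg' or 'bed'")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 5:
        raise ValueError(f"{path}: SEG needs >=5 tab-separated columns")
    # sniff a header line: third column not numeric
    try:
        float(df.iat[0, 2])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no segment rows")
    out = pd.DataFrame(
        {
            "sample": df.iloc[:, 0].astype(str),
            "chrom": df.iloc[:, 1].astype(str),
            "start": pd.to_numeric(df.iloc[:, 2]).astype(np.int64),
            "end": pd.to_numeric(df.iloc[:, 3]).astype(np.int64),
            "log2_ratio": pd.to_numeric(df.iloc[:, df.shape[1] - 1]).astype(float),
        }
    )
    if dialect == "seg":
        out["start"] = out["start"] - 1  # 1-based inclusive -> 0-based half-open
    return out


def read_gene_models(path, dialect: str = "bed") -> pd.DataFrame:
    """Read BED-like gene models: chrom, start, end, gene id.

    ``dialect="bed"`` (default, UCSC txStart convention) is already
    0-based half-open; ``dialect="one-based"`` shifts start by -1.
    Duplicate transcripts of one gene id are collapsed to the union
    interval; a gene id spanning several chromosomes is an error.
    """
    if dialect not in ("bed", "one-based"):
        raise ValueError("dialect must be 'bed' or 'one-based'")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: gene models need chrom, start, end, gene id")
    try:
        float(df.iat[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 3].astype(str),
            "chrom": df.iloc[:, 0].astype(str),
            "start": pd.to_numeric(df.iloc[:, 1]).astype(np.int64),
            "end": pd.to_numeric(df.iloc[:, 2]).astype(np.int64),
        }
    )
    if dialect == "one-based":
        out["start"] = out["start"] - 1
    multi = out.groupby("gene_id")["chrom"].nunique()
    conflicted = multi.index[multi > 1].tolist()
    if conflicted:
        raise ValueError(
            f"{path}: gene id(s) on multiple chromosomes: {conflicted[:10]}"
        )
    collapsed = out.groupby(["gene_id", "chrom"], as_index=False).agg(
        start=("start", "min"), end=("end", "max")
    )
    return collapsed[["gene_id", "chrom", "start", "end"]]


# ---------------------------------------------------------------------------
# config and manifest
# ---------------------------------------------------------------------------

def read_simulation_config(path) -> SimulationConfig:
    """Read a YAML key-value file mirroring :class:`SimulationConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    known = {
        "n_genes", "n_samples", "group_sizes", "mu0", "sigma_g",
        "ig_alpha", "ig_beta", "ig_on", "seed",
    }
    stray = set(raw) - known
    if stray:
        raise ValueError(f"{path}: unknown config key(s) {sorted(stray)}")
    if "group_sizes" in raw and raw["group_sizes"] is not None:
        raw["group_sizes"] = tuple(int(s) for s in raw["group_sizes"])
    return SimulationConfig(**raw)


def write_simulation_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, seed=None, config=None,
                   inputs=(), outputs=()) -> None:
    """Write a JSON run manifest: command, seed, config echo, input digests."""
    manifest = {
        "tool": TOOL_VERSION,
        "command": command,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config or {},
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# fixture generator: the eight simulated benchmark scenarios
# ---------------------------------------------------------------------------

#: (n_groups, sigma_g) for the eight benchmark cohorts: group counts
#: {1, 2, 4, 40} crossed with high/low within-sample SD (1.5 / 0.5)
BENCHMARK_SCENARIOS = tuple(
    (k, sg) for sg in (1.5, 0.5) for k in (1, 2, 4, 40)
)


def _scenario_config(k: int, sigma_g: float, seed: int,
                     n_genes: int = 50, n_samples: int = 40) -> SimulationConfig:
    base, rem = divmod(n_samples, k)
    sizes = tuple(base + (1 if i < rem else 0) for i in range(k))
    return SimulationConfig(
        n_genes=n_genes,
        n_samples=n_samples,
        group_sizes=sizes,
        sigma_g=sigma_g,
        seed=seed,
    )


def generate_benchmark_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write the eight benchmark cohorts (50 genes x 40 samples).

    Group counts {1, 2, 4, 40} crossed with sigma_g in {1.5, 0.5};
    between-sample variability InvGamma(15, 7) and mu0 = 8 throughout.
    Each cohort gets a matrix TSV, a sidecar truth-label TSV and a config
    echo; deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, (k, sg) in enumerate(BENCHMARK_SCENARIOS):
        sub_seed = int(
            np.random.SeedSequence([int(seed), i]).generate_state(1)[0] & 0x7FFFFFFF
        )
        config = _scenario_config(k, sg, sub_seed)
        cohort = simulate_cohort(config)
        tag = f"groups{k:02d}_sg{sg:.1f}".replace(".", "p")
        mat = out_dir / f"cohort_{tag}.tsv"
        lab = out_dir / f"cohort_{tag}.labels.tsv"
        cfg = out_dir / f"cohort_{tag}.config.yaml"
        write_expression_matrix(cohort, mat)
        write_labels(dict(zip(cohort.sample_ids, cohort.group_labels)), lab)
        write_simulation_config(config, cfg)
        written.extend([mat, lab, cfg])
    return written
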