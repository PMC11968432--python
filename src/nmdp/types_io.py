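"""Core domain containers and file I/O shared by every pipeline stage.

Omics matrices are stored probes x samples (``m x n``), matching the
convention of a feature matrix ``X`` whose rows are gene probes and whose
columns are samples.  All on-disk formats are plain text: TSV for matrices,
a two-column SIF-like edge list for pathways, CSV for IC50 tables, YAML for
run configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "nmdp-schema 1"

OMICS_NAMES = ("expression", "copynumber", "methylation", "other")


class ParseError(ValueError):
    """Raised when an input file violates the expected schema."""


class ConfigError(ValueError):
    """Raised for out-of-range or unknown configuration values."""


@dataclass
class OmicsBlock:
    """One omics feature matrix: ``values[i, j]`` is probe i in sample j."""

    name: str
    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        m, n = self.values.shape
        if m != len(self.probe_ids):
            raise ParseError(f"{m} rows but {len(self.probe_ids)} probe ids")
        if n != len(self.sample_ids):
            raise ParseError(f"{n} columns but {len(self.sample_ids)} sample ids")
        if len(set(self.probe_ids)) != m:
            raise ParseError("duplicate probe identifiers")
        if len(set(self.sample_ids)) != n:
            raise ParseError("duplicate sample identifiers")
        if m < 2 or n < 3:
            raise ParseError(f"omics block too small: m={m}, n={n} (need m>=2, n>=3)")
        if not np.all(np.isfinite(self.values)):
            raise ParseError("non-finite values after loading")
        if self.name not in OMICS_NAMES:
            raise ParseError(f"unknown omics name {self.name!r}; expected one of {OMICS_NAMES}")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OmicsBlock(self.name, self.values[:, idx], list(self.probe_ids), list(sample_ids))


@dataclass
class PathwayEdgeSet:
    """Unordered gene-gene pairs with optional nonnegative per-edge weights."""

    edges: list[tuple[str, str]]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ParseError(f"self-loop edge {a!r}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.edges):
                raise ParseError("edge weights not length-matched to edges")
            if np.any(self.weights < 0):
                raise ParseError("negative edge weight")

    def __len__(self) -> int:
        return len(self.edges)

    def align(self, probe_ids: Sequence[str]) -> np.ndarray:
        """Resolve endpoints to probe indices; drop unresolvable edges with a warning.

        Returns an integer array of shape (l, 2).  Gene-level edges map onto
        probe-level vertices by exact ID match.
        """
        index = {p: i for i, p in enumerate(probe_ids)}
        kept, dropped = [], 0
        for a, b in self.edges:
            if a in index and b in index:
                kept.append((index[a], index[b]))
            else:
                dropped += 1
        if dropped:
            warnings.warn(f"{dropped} edge(s) dropped: endpoint not in probe list")
        return np.asarray(kept, dtype=int).reshape(-1, 2)


@dataclass
class SparseLoading:
    """A fitted sparse principal component: loading u, scores v, support."""

    u: np.ndarray
    v: np.ndarray
    support: np.ndarray
    k_edges: int
    iterations: int
    converged: bool = True
    sampled_edges: list[list[int]] = field(default_factory=list)


@dataclass
class ResponseLabels:
    """Binarized drug response: responsive (1) iff IC50 <= cutoff."""

    sample_ids: list[str]
    ic50: np.ndarray
    label: np.ndarray
    cutoff: float
    method: str

    def __post_init__(self) -> None:
        self.ic50 = np.asarray(self.ic50, dtype=float)
        self.label = np.asarray(self.label, dtype=int)

    @property
    def responsive_fraction(self) -> float:
        return float(np.mean(self.label))


@dataclass
class SimilarityMatrix:
    """Rank-correlation sample-similarity block, anchors (rows) x queries (cols)."""

    anchors: list[str]
    queries: list[str]
    values: np.ndarray
    kernel: str
    name: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.anchors), len(self.queries)):
            raise ParseError("similarity matrix shape does not match anchor/query lists")
        if np.any(self.values < -1 - 1e-9) or np.any(self.values > 1 + 1e-9):
            raise ParseError("similarity values outside [-1, 1]")


@dataclass
class FusedFeatures:
    """Weighted sum of similarity blocks: X' = sum_i alpha_i * beta_i * block_i."""

    values: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    anchors: list[str]
    queries: list[str]


# ---------------------------------------------------------------------------
# readers / writers


def read_omics_block(path: str | Path, name: str = "other", max_missing: float = 0.10) -> OmicsBlock:
    """Load a probes-x-samples TSV; header = sample IDs, first column = probe IDs.

    Probe rows with more than ``max_missing`` missing values are dropped;
    remaining missing entries are imputed with the probe median.
    """
    path = Path(path)
    # check header duplicates before pandas mangles repeated column names
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    cols = header.rstrip("\n").split("\t")[1:]
    if len(set(cols)) != len(cols):
        dups = sorted({c for c in cols if cols.count(c) > 1})
        raise ParseError(f"{path}: duplicate sample id(s) {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate probe id(s) {dups}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_na = df.isna().to_numpy()
    bad = ~np.isfinite(values) & ~raw_na
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(f"{path}: non-numeric cell at probe {df.index[i]!r}, sample {df.columns[j]!r}")
    missing_frac = np.mean(~np.isfinite(values), axis=1)
    keep = missing_frac <= max_missing
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("%s: dropped %d probe row(s) with >%.0f%% missing", path, n_dropped, 100 * max_missing)
    values = values[keep]
    probe_ids = df.index[keep].tolist()
    for i in range(values.shape[0]):
        row = values[i]
        nan = ~np.isfinite(row)
        if nan.any():
            row[nan] = np.median(row[~nan])
    return OmicsBlock(name=name, values=values, probe_ids=probe_ids, sample_ids=df.columns.tolist())


def write_omics_block(block: OmicsBlock, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION} omics name={block.name}\n")
        df = pd.DataFrame(block.values, index=block.probe_ids, columns=block.sample_ids)
        df.index.name = "probe_id"
        # no float_format: pandas' shortest-repr output round-trips bit-exactly
        df.to_csv(fh, sep="\t", lineterminator="\n")


def read_edge_set(path: str | Path) -> PathwayEdgeSet:
    """Read a SIF-like two-column edge list; dedupe unordered pairs, drop self-loops."""
    path = Path(path)
    seen: set[frozenset[str]] = set()
    edges: list[tuple[str, str]] = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            a, b = parts
            if a == b:
                n_self += 1
                continue
            key = frozenset((a, b))
            if key not in seen:
                seen.add(key)
                edges.append((a, b))
    if n_self:
        logger.info("%s: discarded %d self-loop(s)", path, n_self)
    if not edges:
        raise ParseError(f"{path}: no edges")
    return PathwayEdgeSet(edges=edges)


def write_edge_set(edges: PathwayEdgeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION} edges\n")
        for a, b in edges.edges:
            fh.write(f"{a}\t{b}\n")


def read_ic50(path: str | Path) -> pd.DataFrame:
    """Read a CSV with columns sample_id, ic50 (missing entries allowed)."""
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns or "ic50" not in df.columns:
        raise ParseError(f"{path}: need columns sample_id, ic50")
    df["ic50"] = pd.to_numeric(df["ic50"], errors="coerce")
    return df


def write_ic50(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION} ic50\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    kernel = "spearman"
    name = "other"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first.split():
                if token.startswith("kernel="):
                    kernel = token.split("=", 1)[1]
                if token.startswith("name="):
                    name = token.split("=", 1)[1]
    return SimilarityMatrix(
        anchors=df.index.astype(str).tolist(),
        queries=df.columns.astype(str).tolist(),
        values=df.to_numpy(dtype=float),
        kernel=kernel,
        name=name,
    )


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION} similarity kernel={sim.kernel} name={sim.name}\n")
        df = pd.DataFrame(sim.values, index=sim.anchors, columns=sim.queries)
        df.index.name = "anchor"
        df.to_csv(fh, sep="\t", lineterminator="\n", float_format="%.17g")


# ---------------------------------------------------------------------------
# run configuration

_DEFAULT_CONFIG: dict = {
    "seed": 0,
    # labeling
    "min_samples": 200,
    "strict_balance": False,
    # sswespca
    "k": 10,
    "omega": 1.0,
    "rho": 0.1,
    "n_pcs": 1,
    "tol": 1e-4,
    "max_iter": 100,
    "evaluator": "random_forest",
    "sqrt_edge_weights": False,
    # simnet
    "kernel_overrides": {},
    "kendall_variant": "tau_a",
    # fusion
    "a": 0.5,
    "b": 1.5,
    "n_boot": 2000,
    "dip_on_raw_features": False,
    # predictor
    "conv_channels": 2,
    "kernel_size": 5,
    "pool": 2,
    "kan_hidden": 4,
    "grid_size": 8,
    "spline_order": 3,
    "residual_act": "silu",
    "epochs": 200,
    "lr": 1e-3,
    "batch_size": 16,
    # pipeline
    "n_folds": 5,
    "ablation": None,
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted run configuration."""

    params: dict = field(default_factory=lambda: dict(_DEFAULT_CONFIG))

    def __getattr__(self, key: str):
        params = object.__getattribute__(self, "params")
        if key in params:
            return params[key]
        raise AttributeError(key)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load YAML config; unknown keys rejected, ranges validated."""
    params = dict(_DEFAULT_CONFIG)
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    if overrides:
        user.update(overrides)
    unknown = set(user) - set(params)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    params.update(user)
    if params["omega"] < 0:
        raise ConfigError("omega must be >= 0")
    if params["rho"] < 0:
        raise ConfigError("rho must be >= 0")
    if params["k"] < 1:
        raise ConfigError("k must be >= 1")
    if params["tol"] <= 0:
        raise ConfigError("tol must be > 0")
    if not params["a"] < params["b"]:
        raise ConfigError("a must be < b")
    if params["kernel_size"] % 2 == 0:
        raise ConfigError("kernel_size must be odd")
    if params["spline_order"] < 1 or params["grid_size"] < params["spline_order"] + 1:
        raise ConfigError("need spline_order >= 1 and grid_size >= spline_order + 1")
    valid_ablations = {None, "no-weighting", "no-conv", "no-similarity", "mlp-head"}
    if params["ablation"] not in valid_ablations:
        raise ConfigError(f"ablation must be one of {sorted(a for a in valid_ablations if a)} or null")
    return RunConfig(params=params)
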