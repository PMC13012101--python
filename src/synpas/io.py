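"""Data model and on-disk formats shared by all pipeline stages.

The reference interchange dialect is TSV (UTF-8, "." decimal). GCT 1.2 is
supported for expression matrices, and a minimal read-only GCTX (HDF5)
reader covers LINCS-style level-5 matrices. Networks round-trip through
JSON.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SCALES = ("linear", "log2")
VALID_ROLES = ("promoter", "attenuator")
ROLE_SIGN = {"promoter": +1, "attenuator": -1}
VALID_TIERS = ("first_degree", "upstream")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def validate_gene_id(symbol: str) -> str:
    if not isinstance(symbol, str) or not symbol or any(c.isspace() for c in symbol):
        raise ValueError(f"invalid gene id: {symbol!r}")
    return symbol


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    values: DataFrame indexed by gene symbol, columns are sample ids.
    scale: "linear" (values >= 0) or "log2".
    sample_meta: DataFrame indexed by sample id, aligned with columns;
        typical columns are group, region, braak_stage, age_at_death.
    """

    values: pd.DataFrame
    scale: str = "log2"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample names")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale matrix contains negative values")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        if len(self.sample_meta) != self.values.shape[1]:
            raise ValueError("sample_meta length must equal sample count")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """log2-transform a linear matrix; log2(x + pseudocount) handles zeros."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(
            values=np.log2(self.values + pseudocount),
            scale="log2",
            sample_meta=self.sample_meta,
        )


@dataclass(frozen=True)
class InteractionEdge:
    source: str
    target: str
    directed: bool = True

    def __post_init__(self):
        validate_gene_id(self.source)
        validate_gene_id(self.target)
        if self.source == self.target:
            raise ValueError(f"self-loop edge: {self.source}")


@dataclass(frozen=True)
class PNNode:
    gene: str
    role: str | None  # promoter/attenuator literature annotation, if any
    sign: int  # +1 aggregation-promoting activity, -1 attenuating
    tier: str  # first_degree or upstream

    def __post_init__(self):
        validate_gene_id(self.gene)
        if self.sign not in (+1, -1):
            raise ValueError(f"sign must be +1/-1, got {self.sign}")
        if self.role is not None and self.role not in VALID_ROLES:
            raise ValueError(f"unknown role: {self.role!r}")
        if self.tier not in VALID_TIERS:
            raise ValueError(f"unknown tier: {self.tier!r}")


@dataclass
class ProteostasisNetwork:
    """The focal protein's proteostasis subnetwork.

    nodes carry the pathway activation sign a_i used by the activity score;
    edges are restricted to the node set plus the focal gene.
    """

    focal: str
    nodes: list[PNNode]
    edges: list[InteractionEdge] = field(default_factory=list)

    def __post_init__(self):
        validate_gene_id(self.focal)
        genes = [n.gene for n in self.nodes]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate network nodes")
        if self.focal in genes:
            raise ValueError("focal gene must not be a scored node")
        allowed = set(genes) | {self.focal}
        for e in self.edges:
            if e.source not in allowed or e.target not in allowed:
                raise ValueError(f"edge endpoint outside network: {e}")

    @property
    def K(self) -> int:
        return len(self.nodes)

    @property
    def signs(self) -> dict[str, int]:
        return {n.gene: n.sign for n in self.nodes}

    def to_json(self, path) -> None:
        payload = {
            "focal": self.focal,
            "nodes": [
                {"gene": n.gene, "role": n.role, "sign": n.sign, "tier": n.tier}
                for n in sorted(self.nodes, key=lambda n: n.gene)
            ],
            "edges": [
                {"source": e.source, "target": e.target, "directed": e.directed}
                for e in sorted(self.edges, key=lambda e: (e.source, e.target, e.directed))
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "ProteostasisNetwork":
        payload = json.loads(Path(path).read_text())
        return cls(
            focal=payload["focal"],
            nodes=[PNNode(**n) for n in payload["nodes"]],
            edges=[InteractionEdge(**e) for e in payload["edges"]],
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _infer_scale(values: pd.DataFrame) -> str:
    arr = values.to_numpy()
    if (arr < 0).any():
        return "log2"
    return "log2" if arr.size and arr.max() < 50 else "linear"


def read_expression_table(path, scale_hint: str = "auto", meta_path=None) -> ExpressionMatrix:
    """Read a genes x samples expression table from TSV or GCT 1.2/1.3.

    TSV layout: first column gene id, remaining columns one per sample.
    scale_hint "auto" infers log2 when all values are below 50; negative
    values are only legal on the log2 scale.
    """
    path = Path(path)
    if path.suffix.lower() == ".gct":
        values = _read_gct(path)
    else:
        values = _read_tsv_matrix(path)
    values.index.name = "gene"
    values.columns.name = None
    scale = _infer_scale(values) if scale_hint == "auto" else scale_hint
    if scale not in VALID_SCALES:
        raise ValueError(f"scale_hint must be linear/log2/auto, got {scale_hint!r}")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta = meta.reindex(values.columns)
    return ExpressionMatrix(values=values, scale=scale, sample_meta=meta)


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample names")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene rows {dupes}; collapse probes first")
    df.index = df.index.astype(str)
    return df.astype(float)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise ValueError(f"{path}: malformed GCT header {version!r}")
        dims = fh.readline().split()
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t")
    # GCT 1.2: Name, Description, then samples; 1.3 may carry extra annotation columns
    n_annot = body.shape[1] - n_cols
    if n_annot < 1:
        raise ValueError(f"{path}: size line inconsistent with column count")
    values = body.set_index(body.columns[0]).iloc[:, n_annot - 1:]
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: size line {n_rows}x{n_cols} != body {values.shape}")
    values.index = values.index.astype(str)
    if values.index.duplicated().any():
        dupes = sorted(values.index[values.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate gene rows {dupes}; collapse probes first")
    return values.astype(float)


def read_gctx(path, rids=None, cids=None) -> pd.DataFrame:
    """Minimal read-only GCTX (HDF5) matrix reader, LINCS level-5 layout.

    Returns genes (rows) x signatures (columns). Optional rids/cids subset.
    """
    import h5py

    with h5py.File(path, "r") as f:
        mat = f["/0/DATA/0/matrix"][()]
        row_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["/0/META/ROW/id"][()]]
        col_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["/0/META/COL/id"][()]]
    # GCTX stores the matrix as signatures x genes
    df = pd.DataFrame(mat.T if mat.shape == (len(col_ids), len(row_ids)) else mat,
                      index=row_ids, columns=col_ids, dtype=float)
    if rids is not None:
        df = df.loc[[r for r in rids if r in df.index]]
    if cids is not None:
        df = df[[c for c in cids if c in df.columns]]
    return df


def read_single_cell_mtx(mtx_path, genes_path, barcodes_path) -> pd.DataFrame:
    """Read a MatrixMarket single-cell matrix (genes x cells)."""
    from scipy.io import mmread

    mat = mmread(mtx_path)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    dense = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
    return pd.DataFrame(dense, index=genes, columns=cells, dtype=float)


def collapse_probes(matrix: ExpressionMatrix, probe_map) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes.

    Per gene, the probe with the largest across-sample variance is kept
    (ties broken by lexicographic probe id). Probes missing from the map
    are dropped with a logged count.

    probe_map: mapping probe id -> gene symbol (dict or two-column frame).
    """
    if isinstance(probe_map, pd.DataFrame):
        probe_map = dict(zip(probe_map.iloc[:, 0].astype(str), probe_map.iloc[:, 1].astype(str)))
    mapped = [p for p in matrix.values.index if p in probe_map]
    n_unmapped = matrix.values.shape[0] - len(mapped)
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)
    sub = matrix.values.loc[mapped]
    variances = sub.var(axis=1, ddof=1).fillna(0.0)
    best: dict[str, str] = {}
    for probe in sorted(mapped):  # lexicographic order makes the tie-break deterministic
        gene = probe_map[probe]
        if gene not in best or variances[probe] > variances[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    out = sub.loc[[best[g] for g in genes]]
    out.index = genes
    return ExpressionMatrix(values=out, scale=matrix.scale, sample_meta=matrix.sample_meta)


def read_edgelist(path) -> list[InteractionEdge]:
    """Read a functional-interaction edgelist TSV.

    Columns: source, target, direction ("->" directed, "-" undirected).
    Duplicates are removed; self-loops are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "target", "direction"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: edgelist needs columns {sorted(required)}")
    edges: list[InteractionEdge] = []
    seen = set()
    n_self = 0
    for row in df.itertuples(index=False):
        if row.direction == "->":
            directed = True
        elif row.direction == "-":
            directed = False
        else:
            raise ValueError(f"{path}: unknown direction token {row.direction!r}")
        if row.source == row.target:
            n_self += 1
            continue
        key = (row.source, row.target, directed)
        if key in seen:
            continue
        seen.add(key)
        edges.append(InteractionEdge(row.source, row.target, directed))
    if n_self:
        logger.info("read_edgelist: dropped %d self-loops", n_self)
    return edges


def read_roles(path) -> dict[str, str]:
    """Read promoter/attenuator role annotations (TSV: gene, role)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "role"}.issubset(df.columns):
        raise ValueError(f"{path}: role table needs columns gene, role")
    roles: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.role not in VALID_ROLES:
            raise ValueError(f"{path}: unknown role {row.role!r} for {row.gene}")
        if row.gene in roles and roles[row.gene] != row.role:
            raise ValueError(f"{path}: conflicting roles for {row.gene}")
        roles[row.gene] = row.role
    return roles


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _format_float(x) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return "nan"
        return f"{x:.6g}"
    return str(x)


def write_table(records, path, sort_by=None, allow_empty: bool = False) -> None:
    """Write result records as deterministic TSV.

    Rows are sorted by `sort_by` (default: all columns left to right);
    floats are rendered at 6 significant digits.
    """
    df = pd.DataFrame(records)
    if df.empty and not allow_empty:
        raise ValueError("refusing to write empty table (pass allow_empty=True)")
    if not df.empty:
        keys = sort_by if sort_by is not None else list(df.columns)
        df = df.sort_values(by=keys, kind="mergesort").reset_index(drop=True)
    out = df.map(_format_float) if not df.empty else df
    out.to_csv(path, sep="\t", index=False)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    """Write a genes x samples matrix as TSV (gene id in the first column).

    Full float precision so matrices round-trip exactly.
    """
    df = matrix.values.copy()
    df.insert(0, "gene", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_json_mirror(records, path) -> None:
    """JSON mirror of a TSV output, for programmatic consumption."""
    df = pd.DataFrame(records)
    Path(path).write_text(json.dumps(df.to_dict(orient="records"), indent=1, sort_keys=True) + "\n")
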