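"""Proteostasis activity score (PAS) and its comparisons.

PAS over a network N of size K is the signed mean of within-sample z-scores,

    PAS = (1/K) * sum_{i in N} a_i * z_i,

where z_i is gene i's expression standardized across all genes within the
sample and a_i is the pathway activation sign (+1 aggregation-promoting,
-1 attenuating). ΔPAS applies the same signed mean to a treatment-vs-control
differential expression signature e_i. Higher PAS means the network state
favors aggregation of the focal protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, ProteostasisNetwork
from .network import RelativeExpressionMatrix
from .stats import wilcoxon_ranksum

logger = logging.getLogger(__name__)


@dataclass
class ZMatrix:
    """Within-sample z-scores: each column standardized over its genes."""

    values: pd.DataFrame
    source_scale: str = "log2"


@dataclass(frozen=True)
class PASResult:
    sample: str
    pas: float
    K: int  # network genes used
    n_missing: int  # network genes absent from the matrix


def zscore_within_sample(matrix) -> ZMatrix:
    """Standardize every sample (column) over its genes, population sd.

    A constant column carries no relative information: it is set to all
    zeros with a warning.
    """
    if isinstance(matrix, (ExpressionMatrix, RelativeExpressionMatrix)):
        values = matrix.values
        scale = getattr(matrix, "scale", "log2")
    else:
        values = matrix
        scale = "unknown"
    if values.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 genes")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning("%d constant sample(s) z-scored to zero", int(zero_sd.sum()))
    sd = sd.replace(0.0, 1.0)
    z = values.sub(mean, axis=1).div(sd, axis=1)
    z.loc[:, zero_sd[zero_sd].index] = 0.0
    return ZMatrix(values=z, source_scale=scale)


def compute_pas(
    z: ZMatrix,
    network: ProteostasisNetwork,
    missing_policy: str = "renormalize",
) -> list[PASResult]:
    """Per-sample PAS over the network genes present in the z-matrix.

    missing_policy "renormalize" divides by the number of genes actually
    present; "error" requires full network coverage.
    """
    signs = network.signs
    present = [n.gene for n in network.nodes if n.gene in z.values.index]
    n_missing = network.K - len(present)
    if not present:
        raise ValueError("no network gene present in the matrix")
    if missing_policy == "error" and n_missing:
        missing = sorted(set(signs) - set(present))
        raise ValueError(f"network genes missing from matrix: {missing}")
    a = np.array([signs[g] for g in present], dtype=float)
    # fixed memory layout so the BLAS reduction order (and hence the last
    # bit of the result) does not depend on how the frame was assembled
    sub = np.ascontiguousarray(z.values.loc[present].to_numpy(dtype=float))
    pas = (a @ sub) / len(present)
    return [
        PASResult(sample=s, pas=float(v), K=len(present), n_missing=n_missing)
        for s, v in zip(z.values.columns, pas)
    ]


def compute_delta_pas(signature: pd.Series, network: ProteostasisNetwork) -> float:
    """ΔPAS = (1/K_used) * sum a_i * e_i over network genes in the signature.

    Linear in the signature by construction.
    """
    signs = network.signs
    genes = [g for g in signs if g in signature.index]
    if not genes:
        raise ValueError("signature has no overlap with the network")
    a = np.array([signs[g] for g in genes], dtype=float)
    e = signature.loc[genes].to_numpy(dtype=float)
    return float(a @ e / len(genes))


def compare_pas_groups(
    results: list[PASResult],
    sample_meta: pd.DataFrame,
    mode: str = "group",
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
    age_col: str = "age_at_death",
) -> dict:
    """Contrast PAS between two sample groups, or correlate with age.

    Group mode: two-sided Wilcoxon rank-sum p and the difference of group
    medians. Age mode: Spearman rho and p between PAS and age at death.
    """
    pas = pd.Series({r.sample: r.pas for r in results})
    meta = sample_meta.loc[pas.index]
    if mode == "group":
        labels = meta[group_col]
        if groups is None:
            uniq = sorted(labels.unique())
            if len(uniq) != 2:
                raise ValueError(f"expected exactly 2 groups, found {uniq}")
            groups = (uniq[0], uniq[1])
        x = pas[labels.to_numpy() == groups[0]].to_numpy()
        y = pas[labels.to_numpy() == groups[1]].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError("each group needs at least 2 samples")
        _, p = wilcoxon_ranksum(x, y)
        return {
            "mode": "group",
            "groups": groups,
            "median_diff": float(np.median(x) - np.median(y)),
            "p": float(p),
            "n": (len(x), len(y)),
        }
    if mode == "age":
        ages = meta[age_col].astype(float)
        ok = ages.notna()
        if ok.sum() < 4:
            raise ValueError("age mode needs at least 4 samples with ages")
        rho, p = sps.spearmanr(pas[ok], ages[ok])
        return {"mode": "age", "rho": float(rho), "p": float(p), "n": int(ok.sum())}
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class CellLineRecord:
    line: str
    pas: float
    pas_z: float
    p: float  # two-sided standard-normal tail of pas_z
    rank: int  # 1 = highest PAS


def rank_cell_lines(
    ntpm: pd.DataFrame,
    network: ProteostasisNetwork,
    reference: str | None = None,
    snca_min: float = 2.0,
    log2_ratio: bool = True,
) -> list[CellLineRecord]:
    """Rank cell lines by baseline network activity.

    ntpm: lines (rows) x genes (columns), linear nTPM units. Lines with
    reference nTPM <= snca_min are dropped (undetectable focal transcript).
    Per line: gene:reference ratios (log2 by default), z-scored within the
    line over all genes, PAS over network genes, then PAS z-scored across
    lines; p is the two-sided normal tail of that z; rank 1 is the highest
    PAS (most aggregation-promoting baseline).
    """
    reference = reference or network.focal
    if reference not in ntpm.columns:
        raise ValueError(f"reference column {reference!r} absent")
    kept = ntpm[ntpm[reference] > snca_min]
    if kept.empty:
        raise ValueError("all cell lines filtered out by the reference threshold")
    ratios = kept.div(kept[reference], axis=0)
    rel = np.log2(ratios) if log2_ratio else ratios
    # z within line over genes, then PAS per line
    z = zscore_within_sample(rel.T)  # genes x lines
    pas = {r.sample: r.pas for r in compute_pas(z, network)}
    pas_s = pd.Series(pas).loc[kept.index]
    mu, sd = pas_s.mean(), pas_s.std(ddof=0)
    pas_z = (pas_s - mu) / sd if sd > 0 else pas_s * 0.0
    pvals = 2.0 * sps.norm.sf(np.abs(pas_z))
    order = pas_s.sort_values(ascending=False, kind="mergesort").index
    ranks = {line: i + 1 for i, line in enumerate(order)}
    return [
        CellLineRecord(
            line=line,
            pas=float(pas_s[line]),
            pas_z=float(pas_z[line]),
            p=float(pv),
            rank=ranks[line],
        )
        for line, pv in zip(pas_s.index, pvals)
    ]
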