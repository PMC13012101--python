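"""Digital twin: a partial-correlation model of the network with in-silico
perturbation.

Single-cell expression is z-scored within each cell across genes (the
per-cell mean/sd are frozen for later reuse). Gene-gene dependencies are
estimated as partial correlations from an identity-target shrinkage
correlation matrix (analytic, data-driven shrinkage intensity). Edge
significance comes from an empirical-null mixture fitted to the observed
partial-correlation distribution; edges at q < 0.05 parameterize a linear
predictive model (OLS slope of target z on query z). A perturbation
multiplies a query gene's basal level in every cell, recomputes its z with
the frozen statistics, propagates one linear step to its significant
partners, and reads out the per-cell activity score with Cohen's d against
baseline.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .io import ExpressionMatrix, ProteostasisNetwork
from .pas import ZMatrix, compute_pas
from .stats import adjust_pvalues, cohens_d

logger = logging.getLogger(__name__)

KNOCKDOWN_FACTORS = (0.06, 0.12, 0.25, 0.5, 0.75)
OVEREXPRESSION_FACTORS = (1.25, 1.5, 1.75, 2.0, 4.0, 8.0)


# ---------------------------------------------------------------------------
# per-cell normalization with frozen statistics
# ---------------------------------------------------------------------------

def zscore_per_cell(cells: ExpressionMatrix | pd.DataFrame) -> tuple[ZMatrix, pd.DataFrame]:
    """Standardize each cell (column) over genes; freeze per-cell mean/sd.

    Returns (z-matrix, norm_stats) where norm_stats has one row per cell
    with columns mean and sd (population sd over genes). The frozen
    statistics let a later perturbation rescale a single gene without
    silently re-standardizing all others.
    """
    values = cells.values if isinstance(cells, ExpressionMatrix) else cells
    if values.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 genes")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant cell(s); cannot z-score")
    z = values.sub(mean, axis=1).div(sd, axis=1)
    stats = pd.DataFrame({"mean": mean, "sd": sd})
    return ZMatrix(values=z, source_scale="per-cell"), stats


def apply_norm_stats(values: pd.DataFrame, norm_stats: pd.DataFrame) -> pd.DataFrame:
    """Re-apply frozen per-cell statistics to (possibly perturbed) values."""
    return values.sub(norm_stats["mean"], axis=1).div(norm_stats["sd"], axis=1)


# ---------------------------------------------------------------------------
# Gaussian graphical model with shrinkage
# ---------------------------------------------------------------------------

@dataclass
class GGMFit:
    genes: list[str]
    pcor: pd.DataFrame  # symmetric, unit diagonal
    q: pd.DataFrame  # symmetric edge q-values
    norm_stats: pd.DataFrame
    shrinkage_lambda: float
    kappa: float = math.nan  # effective null degrees of freedom
    eta0: float = math.nan  # estimated null proportion
    qvalue_method: str = "mixture"

    def significant_edges(self, q_cut: float = 0.05) -> list[tuple[str, str]]:
        out = []
        for i, gi in enumerate(self.genes):
            for gj in self.genes[i + 1:]:
                if self.q.loc[gi, gj] < q_cut:
                    out.append((gi, gj))
        return out


def _shrinkage_correlation(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Identity-target shrinkage correlation with analytic intensity.

    x: observations (rows) x variables (columns). The intensity minimizes
    the estimated MSE: lambda* = sum Var(r_ij) / sum r_ij^2 over i != j,
    clipped to [0, 1].
    """
    n, p = x.shape
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = xs.T @ xs / (n - 1)
    w_bar = xs.T @ xs / n
    sq = (xs ** 2).T @ (xs ** 2)  # sum_k (x_ki x_kj)^2
    var_r = n / (n - 1) ** 3 * (sq - n * w_bar ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = (r[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    return r_shrunk, lam


def _pcor_from_correlation(r: np.ndarray) -> np.ndarray:
    omega = np.linalg.inv(r)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def _null_pvalues(pcor_off: np.ndarray, kappa: float) -> np.ndarray:
    """Two-sided tail Pr(|R| >= |r|) under the null density
    f0(r) = (1 - r^2)^((kappa-3)/2) / B(1/2, (kappa-1)/2)."""
    r2 = np.clip(pcor_off ** 2, 0.0, 1.0 - 1e-15)
    return 1.0 - special.betainc(0.5, (kappa - 1.0) / 2.0, r2)


def fit_ggm(
    z,
    norm_stats: pd.DataFrame | None = None,
    qvalue_method: str = "mixture",
) -> GGMFit:
    """Fit the partial-correlation model on within-cell z-scores.

    z: ZMatrix or DataFrame, genes (rows) x cells (columns), restricted to
    the network genes of interest.

    Edge q-values, method "mixture": the bulk of partial correlations is
    treated as draws from the null density of shrinkage partial
    correlations with kappa effective degrees of freedom; kappa is
    estimated robustly from the median |pcor| (normal-scale matching), the
    null proportion eta0 by Storey's estimator at lambda = 0.5, and
    q = eta0 * BH(p). Method "normal_bh" uses Fisher-z normal p-values and
    plain BH instead.
    """
    values = z.values if isinstance(z, ZMatrix) else z
    genes = list(values.index)
    n_cells = values.shape[1]
    if n_cells <= 3:
        raise ValueError("need more than 3 cells")
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    x = values.to_numpy(dtype=float).T  # cells x genes
    r_shrunk, lam = _shrinkage_correlation(x)
    # with lambda > 0 the shrunk matrix is positive-definite by construction
    eigmin = np.linalg.eigvalsh(r_shrunk).min()
    if eigmin <= 0:
        raise np.linalg.LinAlgError("shrunk correlation matrix not positive-definite")
    pcor = _pcor_from_correlation(r_shrunk)

    p_mat = np.ones_like(pcor)
    iu = np.triu_indices(len(genes), k=1)
    r_off = pcor[iu]
    if qvalue_method == "mixture":
        med = np.median(np.abs(r_off))
        kappa = max(5.0, (0.6745 / max(med, 1e-12)) ** 2)
        pvals = _null_pvalues(r_off, kappa)
        eta0 = float(min(1.0, np.mean(pvals > 0.5) / 0.5))
        qvals = np.minimum(1.0, eta0 * adjust_pvalues(pvals, method="BH"))
    elif qvalue_method == "normal_bh":
        kappa = float(n_cells - len(genes) - 1)
        se = 1.0 / math.sqrt(max(kappa - 3.0, 1.0))
        zfish = np.arctanh(np.clip(r_off, -1 + 1e-12, 1 - 1e-12)) / se
        pvals = 2.0 * special.ndtr(-np.abs(zfish))
        eta0 = math.nan
        qvals = adjust_pvalues(pvals, method="BH")
    else:
        raise ValueError(f"unknown qvalue_method {qvalue_method!r}")
    q_mat = np.ones_like(pcor)
    q_mat[iu] = qvals
    q_mat[(iu[1], iu[0])] = qvals

    if norm_stats is None:
        norm_stats = pd.DataFrame({"mean": 0.0, "sd": 1.0}, index=values.columns)
    return GGMFit(
        genes=genes,
        pcor=pd.DataFrame(pcor, index=genes, columns=genes),
        q=pd.DataFrame(q_mat, index=genes, columns=genes),
        norm_stats=norm_stats,
        shrinkage_lambda=lam,
        kappa=float(kappa),
        eta0=float(eta0) if not math.isnan(eta0) else math.nan,
        qvalue_method=qvalue_method,
    )


# ---------------------------------------------------------------------------
# linear twin and perturbation
# ---------------------------------------------------------------------------

@dataclass
class LinearTwin:
    """Sparse linear response model: z-unit slope per significant pair."""

    genes: list[str]
    slopes: dict[tuple[str, str], float]  # (target, query) -> slope
    q_cut: float = 0.05

    def slope(self, target: str, query: str) -> float:
        return self.slopes.get((target, query), 0.0)

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "q_cut": self.q_cut,
            "slopes": [
                {"target": t, "query": q, "slope": s}
                for (t, q), s in sorted(self.slopes.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "LinearTwin":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes=payload["genes"],
            slopes={(d["target"], d["query"]): d["slope"] for d in payload["slopes"]},
            q_cut=payload["q_cut"],
        )


def build_linear_twin(ggm: GGMFit, z, q_cut: float = 0.05) -> LinearTwin:
    """OLS slopes target~query across cells, for edges with q < q_cut only."""
    values = z.values if isinstance(z, ZMatrix) else z
    if list(values.index) != list(ggm.genes):
        values = values.loc[ggm.genes]
    x = values.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (x.shape[1] - 1)
    var = np.diag(cov)
    slopes: dict[tuple[str, str], float] = {}
    for gi, gj in ggm.significant_edges(q_cut):
        i, j = ggm.genes.index(gi), ggm.genes.index(gj)
        if var[j] > 0:
            slopes[(gi, gj)] = float(cov[i, j] / var[j])
        if var[i] > 0:
            slopes[(gj, gi)] = float(cov[i, j] / var[i])
    if not slopes:
        logger.warning("no significant edges at q < %.3g; twin is inert", q_cut)
    return LinearTwin(genes=list(ggm.genes), slopes=slopes, q_cut=q_cut)


@dataclass
class PerturbationOutcome:
    query: str
    factor: float
    pas_baseline: np.ndarray = field(repr=False)
    pas_perturbed: np.ndarray = field(repr=False)
    cohen_d: float = math.nan

    def __post_init__(self):
        if math.isnan(self.cohen_d):
            self.cohen_d = cohens_d(self.pas_perturbed, self.pas_baseline)


def simulate_perturbation(
    twin: LinearTwin,
    cells: ExpressionMatrix,
    norm_stats: pd.DataFrame,
    network: ProteostasisNetwork,
    query: str,
    factor: float,
) -> PerturbationOutcome:
    """Scale a query gene's basal level in every cell and read out PAS.

    The query's linear-scale value is multiplied by `factor` (on a log2
    matrix the equivalent additive shift log2(factor) is applied); its
    z-score is recomputed with the frozen per-cell statistics and each
    significant partner's z shifts by slope * delta-z (one linear step, no
    iteration). A factor of 1 is the exact identity.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if query not in twin.genes or query not in cells.values.index:
        raise ValueError(f"query gene {query!r} absent from the twin or the matrix")
    values = cells.values
    z = apply_norm_stats(values, norm_stats)
    if cells.scale == "linear":
        new_query = values.loc[query] * factor
    else:
        new_query = values.loc[query] + math.log2(factor)
    delta_z = (new_query - values.loc[query]) / norm_stats["sd"]
    z_pert = z.copy()
    z_pert.loc[query] = z.loc[query] + delta_z
    for target in twin.genes:
        if target == query:
            continue
        s = twin.slope(target, query)
        if s != 0.0 and target in z_pert.index:
            z_pert.loc[target] = z.loc[target] + s * delta_z
    pas_base = np.array([r.pas for r in compute_pas(ZMatrix(z), network)])
    pas_pert = np.array([r.pas for r in compute_pas(ZMatrix(z_pert), network)])
    return PerturbationOutcome(query=query, factor=factor,
                               pas_baseline=pas_base, pas_perturbed=pas_pert)


def perturbation_screen(
    twin: LinearTwin,
    cells: ExpressionMatrix,
    norm_stats: pd.DataFrame,
    network: ProteostasisNetwork,
    queries: list[str],
    knockdown=KNOCKDOWN_FACTORS,
    overexpression=OVEREXPRESSION_FACTORS,
) -> tuple[list[PerturbationOutcome], pd.DataFrame]:
    """Run the full factor ladder per query and rank targets by effect size.

    Returns (all outcomes, ranking table). The ranking orders queries by
    the maximum |Cohen's d| across factors; d at the display factors 0.12
    (knockdown) and 8 (overexpression) is reported alongside.
    """
    factors = list(knockdown) + list(overexpression)
    outcomes: list[PerturbationOutcome] = []
    rows = []
    for query in queries:
        ds = {}
        for f in factors:
            out = simulate_perturbation(twin, cells, norm_stats, network, query, f)
            outcomes.append(out)
            ds[f] = out.cohen_d
        rows.append({
            "query": query,
            "max_abs_d": max(abs(v) for v in ds.values()),
            "d_knockdown_0.12": ds.get(0.12, math.nan),
            "d_overexpression_8": ds.get(8.0, math.nan),
        })
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["max_abs_d", "query"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return outcomes, ranking
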