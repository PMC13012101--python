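"""Synthetic-data generators with planted ground truth.

Every pipeline input — functional-interaction edgelist, role annotations,
case/control expression sets, single-cell expression, cell-line baseline
tables, and dose-response treatment signatures — can be generated with a
known truth object, so each downstream stage's recovery can be scored
without external downloads. All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, InteractionEdge, ProteostasisNetwork
from .screen import SignatureRecord

FOCAL = "SNCA"


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# network inputs
# ---------------------------------------------------------------------------

def gen_edgelist(
    n_first_degree: int,
    n_background: int,
    n_upstream: int,
    seed: int,
    promoter_fraction: float = 0.6,
    n_nonmember_inward: int = 3,
    focal: str = FOCAL,
) -> tuple[list[InteractionEdge], dict[str, str], dict]:
    """Planted interaction structure around the focal gene.

    * first-degree genes: one directed edge into the focal gene each, plus
      sparse edges among themselves (they are the curated-list members);
    * upstream genes: 1-2 edges to first-degree genes, none to the focal;
    * background genes: edges only among themselves;
    * a few inward edges from genes outside the curated member list, to
      exercise the membership filter.

    Returns (edges, role annotations for the first-degree genes, truth).
    """
    if min(n_first_degree, n_background, n_upstream) < 1:
        raise ValueError("all counts must be >= 1")
    rng = _rng(seed)
    fd = [f"FD{i:03d}" for i in range(1, n_first_degree + 1)]
    up = [f"UP{i:03d}" for i in range(1, n_upstream + 1)]
    bg = [f"BG{i:03d}" for i in range(1, n_background + 1)]
    nonpn = [f"XX{i:03d}" for i in range(1, n_nonmember_inward + 1)]

    edges: list[InteractionEdge] = []
    for g in fd:
        edges.append(InteractionEdge(g, focal, directed=True))
    for g in nonpn:
        edges.append(InteractionEdge(g, focal, directed=True))
    # sparse first-degree interconnections give the influence graph texture
    for i, gi in enumerate(fd):
        for gj in fd[i + 1:]:
            if rng.random() < 0.3:
                edges.append(InteractionEdge(gi, gj, directed=bool(rng.random() < 0.5)))
    for g in up:
        partners = rng.choice(fd, size=rng.integers(1, 3), replace=False)
        for p in partners:
            if rng.random() < 0.5:
                edges.append(InteractionEdge(g, str(p), directed=True))
            else:
                edges.append(InteractionEdge(str(p), g, directed=True))
    # background genes only talk to each other
    for i, gi in enumerate(bg):
        gj = bg[(i + 1) % len(bg)]
        if gi != gj and rng.random() < 0.2:
            edges.append(InteractionEdge(gi, gj, directed=True))

    n_prom = int(round(promoter_fraction * n_first_degree))
    shuffled = list(fd)
    rng.shuffle(shuffled)
    roles = {g: ("promoter" if i < n_prom else "attenuator") for i, g in enumerate(shuffled)}
    pn_members = set(fd) | set(rng.choice(bg, size=min(20, len(bg)), replace=False).astype(str))
    truth = {
        "focal": focal,
        "first_degree": sorted(fd),
        "upstream": sorted(up),
        "background": sorted(bg),
        "non_member_inward": sorted(nonpn),
        "pn_members": sorted(pn_members),
        "roles": dict(sorted(roles.items())),
        "seed": seed,
    }
    return edges, roles, truth


def gen_case_control_sets(
    n_datasets: int,
    n_case: int,
    n_control: int,
    genes: list[str],
    planted: list[tuple[str, str, float]],
    noise_sd: float,
    n_consistent: int,
    seed: int,
    focal: str = FOCAL,
) -> tuple[list[ExpressionMatrix], dict]:
    """Case/control log2 expression sets with planted relative-expression shifts.

    planted: (gene, "up"/"down", effect in log2 units). Each planted gene's
    gene:focal log-ratio is shifted by +/-effect in the case samples of
    n_consistent randomly chosen datasets. The focal gene itself is never
    perturbed (it is the normalization reference).
    """
    if n_case < 5 or n_control < 5:
        raise ValueError("need at least 5 case and 5 control samples")
    if focal not in genes:
        raise ValueError(f"focal gene {focal!r} must be in the gene list")
    for gene, direction, effect in planted:
        if gene == focal:
            raise ValueError("cannot plant an effect on the reference gene")
        if gene not in genes:
            raise ValueError(f"planted gene {gene!r} not in gene list")
        if effect <= 0:
            raise ValueError("effect sizes must be positive")
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {direction!r}")
    rng = _rng(seed)
    baselines = pd.Series(rng.uniform(4.0, 10.0, size=len(genes)), index=genes)
    carriers = {
        gene: sorted(rng.choice(n_datasets, size=n_consistent, replace=False).tolist())
        for gene, _, _ in planted
    }
    datasets: list[ExpressionMatrix] = []
    majority = math.ceil(n_datasets / 2)
    for d in range(n_datasets):
        n = n_case + n_control
        values = baselines.to_numpy()[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n))
        samples = [f"DS{d + 1}_case{i + 1}" for i in range(n_case)] + [
            f"DS{d + 1}_ctrl{i + 1}" for i in range(n_control)
        ]
        df = pd.DataFrame(values, index=genes, columns=samples)
        for gene, direction, effect in planted:
            if d in carriers[gene]:
                shift = effect if direction == "up" else -effect
                df.loc[gene, samples[:n_case]] += shift
        meta = pd.DataFrame(
            {"group": ["case"] * n_case + ["control"] * n_control}, index=samples
        )
        datasets.append(ExpressionMatrix(values=df, scale="log2", sample_meta=meta))
    truth = {
        "planted": [
            {
                "gene": gene,
                "direction": +1 if direction == "up" else -1,
                "effect": effect,
                "datasets": carriers[gene],
                "meets_consensus": n_consistent >= majority,
            }
            for gene, direction, effect in planted
        ],
        "n_datasets": n_datasets,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return datasets, truth


# ---------------------------------------------------------------------------
# single-cell inputs
# ---------------------------------------------------------------------------

def make_planted_precision(
    n_genes: int,
    pcor: float = 0.3,
    structure: str = "chain",
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Precision matrix with planted partial correlations of known size.

    "chain": tridiagonal, every adjacent pair has partial correlation
    exactly `pcor` (positive-definite for |pcor| < 0.5). "pairs": disjoint
    2-blocks with the same property.
    """
    if genes is None:
        genes = [f"G{i:03d}" for i in range(1, n_genes + 1)]
    omega = np.eye(n_genes)
    edges: list[tuple[str, str]] = []
    if structure == "chain":
        if not abs(pcor) < 0.5:
            raise ValueError("chain precision needs |pcor| < 0.5 for positive-definiteness")
        for i in range(n_genes - 1):
            omega[i, i + 1] = omega[i + 1, i] = -pcor
            edges.append((genes[i], genes[i + 1]))
    elif structure == "pairs":
        for i in range(0, n_genes - 1, 2):
            omega[i, i + 1] = omega[i + 1, i] = -pcor
            edges.append((genes[i], genes[i + 1]))
    else:
        raise ValueError(f"unknown structure {structure!r}")
    if np.linalg.eigvalsh(omega).min() <= 0:
        raise ValueError("planted precision is not positive-definite")
    return pd.DataFrame(omega, index=genes, columns=genes), edges


def gen_single_cell(
    precision: pd.DataFrame,
    n_cells: int,
    seed: int,
    n_background: int = 200,
) -> tuple[ExpressionMatrix, dict]:
    """Cells drawn i.i.d. from the zero-mean Gaussian with the given precision.

    n_background independent unit-variance genes are appended so that the
    within-cell standardization (across all genes) leaves the network
    genes' joint distribution essentially untouched; without them the
    per-cell centering constraint would tie the few network genes together
    artifactually. Values are shifted to a nonnegative "expression" range;
    the shift is stored in the truth object.
    """
    omega = precision.to_numpy(dtype=float)
    genes = list(precision.index)
    eig = np.linalg.eigvalsh(omega)
    if eig.min() <= 0:
        raise ValueError("precision matrix must be positive-definite")
    rng = _rng(seed)
    cov = np.linalg.inv(omega)
    chol = np.linalg.cholesky(cov)
    raw = chol @ rng.standard_normal(size=(len(genes), n_cells))
    if n_background:
        bg = rng.standard_normal(size=(n_background, n_cells))
        raw = np.vstack([raw, bg])
        genes = genes + [f"BGC{i:03d}" for i in range(1, n_background + 1)]
    offset = float(max(10.0, 1.0 - raw.min()))
    values = pd.DataFrame(
        raw + offset, index=genes, columns=[f"cell{i + 1}" for i in range(n_cells)]
    )
    truth = {
        "precision": precision,
        "offset": offset,
        "genes": genes,
        "seed": seed,
    }
    return ExpressionMatrix(values=values, scale="linear"), truth


# ---------------------------------------------------------------------------
# drug-screen inputs
# ---------------------------------------------------------------------------

def gen_dose_signatures(
    drugs,
    concentrations,
    cell_lines: list[str],
    network: ProteostasisNetwork,
    slope_map: dict[str, float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    intercept_sd: float = 0.1,
    gene_jitter_sd: float = 0.2,
) -> tuple[list[SignatureRecord], dict]:
    """Treatment signatures whose ΔPAS follows a planted log-dose slope.

    Per drug x line x concentration, a target ΔPAS = slope * log10(conc) +
    intercept + N(0, noise_sd) is spread over the network genes as
    e_i = a_i * ΔPAS + jitter, with the jitter projected orthogonal to the
    sign vector so the ΔPAS identity holds exactly.
    """
    if network.K == 0:
        raise ValueError("empty network")
    concentrations = sorted(float(c) for c in concentrations)
    if len(concentrations) < 3:
        raise ValueError("need at least 3 concentrations")
    if isinstance(drugs, int):
        drugs = [f"DRUG{i:03d}" for i in range(1, drugs + 1)]
    rng = _rng(seed)
    if slope_map is None:
        levels = np.array([0.0, 0.2, 0.5, 1.0])
        slope_map = {
            d: float(rng.choice(levels) * rng.choice([-1.0, 1.0])) for d in drugs
        }
    bad = [d for d in drugs if not math.isfinite(slope_map[d])]
    if bad:
        raise ValueError(f"non-finite slopes for {bad}")
    genes = [n.gene for n in network.nodes]
    a = np.array([network.signs[g] for g in genes], dtype=float)
    records: list[SignatureRecord] = []
    intercepts: dict[tuple[str, str], float] = {}
    for drug in drugs:
        for line in cell_lines:
            intercept = float(rng.normal(0.0, intercept_sd))
            intercepts[(drug, line)] = intercept
            for conc in concentrations:
                target = slope_map[drug] * math.log10(conc) + intercept
                if noise_sd > 0:
                    target += float(rng.normal(0.0, noise_sd))
                jitter = rng.normal(0.0, gene_jitter_sd, size=len(genes))
                jitter -= a * (a @ jitter) / (a @ a)  # keep ΔPAS exact
                e = pd.Series(a * target + jitter, index=genes)
                records.append(
                    SignatureRecord(drug=drug, cell_line=line, concentration=conc, e=e)
                )
    truth = {
        "slopes": dict(slope_map),
        "intercepts": intercepts,
        "concentrations": concentrations,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return records, truth


# ---------------------------------------------------------------------------
# cell-line baseline table
# ---------------------------------------------------------------------------

def gen_cell_line_table(
    n_lines: int,
    snca_detectable_fraction: float,
    network: ProteostasisNetwork,
    activity_gradient: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.1,
    n_background: int = 200,
    base_amplitude: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Cell-line nTPM table with a planted baseline-activity gradient.

    Exactly round(fraction * n_lines) lines get a detectable focal
    transcript (nTPM > 2); the rest fall at or below the threshold.
    Detectable lines carry planted activities t evenly spaced in [0, 1];
    each network gene's log2 gene:focal ratio is a_i * c0 * (1 + g * t),
    with centered background-gene ratios shared across lines, which makes
    the within-line-z-scored PAS strictly increasing in t at zero noise.
    """
    if not (0.0 < snca_detectable_fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    rng = _rng(seed)
    lines = [f"CL{i:03d}" for i in range(1, n_lines + 1)]
    n_det = int(round(snca_detectable_fraction * n_lines))
    det_idx = sorted(rng.choice(n_lines, size=n_det, replace=False).tolist())
    detectable = [lines[i] for i in det_idx]
    net_genes = [n.gene for n in network.nodes]
    signs = np.array([network.signs[g] for g in net_genes], dtype=float)
    bg_genes = [f"BGL{i:03d}" for i in range(1, n_background + 1)]
    beta = rng.normal(0.0, 1.0, size=n_background)
    beta -= beta.mean()  # centered so line PAS is strictly monotone in t

    activities = {}
    if n_det == 1:
        activities[detectable[0]] = 1.0
    else:
        ts = np.linspace(0.0, 1.0, n_det)
        order = rng.permutation(n_det)
        for line, t in zip(detectable, ts[order]):
            activities[line] = float(t)

    rows = {}
    for line in lines:
        if line in activities:
            snca = float(rng.uniform(5.0, 50.0))
            t = activities[line]
        else:
            snca = float(rng.uniform(0.1, 2.0))
            t = float(rng.uniform(0.0, 1.0))
        net_ratio = signs * base_amplitude * (1.0 + activity_gradient * t)
        if noise_sd > 0:
            net_ratio = net_ratio + rng.normal(0.0, noise_sd, size=len(net_genes))
            bg_ratio = beta + rng.normal(0.0, noise_sd, size=n_background)
        else:
            bg_ratio = beta
        row = {network.focal: snca}
        for g, lr in zip(net_genes, net_ratio):
            row[g] = snca * 2.0 ** lr
        for g, lr in zip(bg_genes, bg_ratio):
            row[g] = snca * 2.0 ** lr
        rows[line] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    expected_rank = {
        line: rank + 1
        for rank, line in enumerate(
            sorted(activities, key=lambda ln: (-activities[ln], ln))
        )
    }
    truth = {
        "planted_activity": activities,
        "detectable": sorted(activities),
        "expected_rank": expected_rank,
        "seed": seed,
    }
    return table, truth
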