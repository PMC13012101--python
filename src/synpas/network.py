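"""Assembly of the focal-protein proteostasis network.

The network is built in three steps: (1) first-degree interactors — curated
proteostasis genes with a functional interaction directed into the focal
gene; (2) consensus genes — genes whose expression relative to the focal
gene is consistently perturbed (same direction, significant, |effect| above
a cutoff) in at least half of the case/control datasets; (3) upstream
integration — consensus genes touching the first-degree set are added as a
second tier. Node signs: literature role annotations take precedence
(promoter +1, attenuator -1); unannotated upstream genes inherit the sign of
their disease direction (up-in-disease relative to the focal gene -> +1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    ROLE_SIGN,
    ExpressionMatrix,
    InteractionEdge,
    PNNode,
    ProteostasisNetwork,
)
from .stats import adjust_pvalues, wilcoxon_ranksum

logger = logging.getLogger(__name__)


@dataclass
class RelativeExpressionMatrix:
    """log2(gene) - log2(reference) per sample; the reference row is 0."""

    values: pd.DataFrame
    reference: str
    sample_meta: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class DifferentialResult:
    gene: str
    fc: float  # case - control mean difference of relative expression (log2)
    p: float
    q: float
    direction: int  # sign(fc)
    dataset_id: str


@dataclass(frozen=True)
class ConsensusGene:
    gene: str
    direction: int
    n_support: int
    n_datasets: int


def first_degree_interactors(edges, pn_members, focal: str) -> set[str]:
    """Curated proteostasis genes with an inward interaction to the focal gene.

    Directed edges count when they point into the focal gene; undirected
    edges count as inward by convention. Membership in the curated list is
    required; the result excludes the focal gene itself.
    """
    pn_members = set(pn_members)
    out: set[str] = set()
    for e in edges:
        if e.directed:
            if e.target == focal and e.source in pn_members:
                out.add(e.source)
        else:
            if e.target == focal and e.source in pn_members:
                out.add(e.source)
            elif e.source == focal and e.target in pn_members:
                out.add(e.target)
    out.discard(focal)
    return out


def relative_expression(matrix: ExpressionMatrix, reference: str) -> RelativeExpressionMatrix:
    """Per-sample log2 ratio of every gene to the reference gene."""
    if matrix.scale != "log2":
        raise ValueError("relative_expression requires a log2-scale matrix; call to_log2 first")
    if reference not in matrix.values.index:
        raise ValueError(f"reference gene {reference!r} absent from matrix")
    ref_row = matrix.values.loc[reference]
    rel = matrix.values.sub(ref_row, axis=1)
    return RelativeExpressionMatrix(values=rel, reference=reference, sample_meta=matrix.sample_meta)


def differential_relative_expression(
    rel: RelativeExpressionMatrix,
    case_label: str,
    control_label: str,
    adjust: str = "BH",
    group_col: str = "group",
    dataset_id: str = "dataset",
    fc_stat: str = "mean",
) -> list[DifferentialResult]:
    """Per-gene case-vs-control test of relative expression.

    fc is the case - control difference of group means (log2-ratio units;
    medians behind fc_stat="median"); p from the two-sided Wilcoxon
    rank-sum test; q adjusted across genes within the dataset.
    """
    groups = rel.sample_meta[group_col]
    case_cols = rel.values.columns[groups.to_numpy() == case_label]
    ctrl_cols = rel.values.columns[groups.to_numpy() == control_label]
    if len(case_cols) == 0 or len(ctrl_cols) == 0:
        raise ValueError(f"missing group label: {case_label!r} or {control_label!r}")
    if min(len(case_cols), len(ctrl_cols)) < 2:
        raise ValueError("each group needs at least 2 samples")
    if min(len(case_cols), len(ctrl_cols)) < 5:
        logger.warning("group below 5 samples; test power is limited")

    center = np.mean if fc_stat == "mean" else np.median
    genes, fcs, ps = [], [], []
    for gene in rel.values.index:
        x = rel.values.loc[gene, case_cols].to_numpy(dtype=float)
        y = rel.values.loc[gene, ctrl_cols].to_numpy(dtype=float)
        fcs.append(float(center(x) - center(y)))
        ps.append(wilcoxon_ranksum(x, y)[1])
        genes.append(gene)
    qs = adjust_pvalues(ps, method=adjust)
    return [
        DifferentialResult(
            gene=g,
            fc=fc,
            p=float(p),
            q=float(q),
            direction=int(np.sign(fc)),
            dataset_id=dataset_id,
        )
        for g, fc, p, q in zip(genes, fcs, ps, qs)
    ]


def consensus_genes(
    results_by_dataset: list[list[DifferentialResult]],
    fc_cut: float = 0.3,
    q_cut: float = 0.05,
    min_fraction: float = 0.5,
    reference: str | None = None,
) -> list[ConsensusGene]:
    """Genes consistently perturbed across datasets.

    A gene qualifies when the number of datasets in which it is significant
    (q < q_cut), has |fc| > fc_cut, and shares a common direction reaches
    ceil(min_fraction * n_datasets). The reference gene is never included
    (its relative expression is identically zero).
    """
    if len(results_by_dataset) < 2:
        raise ValueError("consensus requires at least 2 datasets")
    n_datasets = len(results_by_dataset)
    need = math.ceil(min_fraction * n_datasets)
    support: dict[str, dict[int, int]] = {}
    for results in results_by_dataset:
        for r in results:
            if r.q < q_cut and abs(r.fc) > fc_cut and r.direction != 0:
                support.setdefault(r.gene, {1: 0, -1: 0})[r.direction] += 1
    out: list[ConsensusGene] = []
    for gene in sorted(support):
        if reference is not None and gene == reference:
            continue
        counts = support[gene]
        direction = max((1, -1), key=lambda d: (counts[d], d))
        if counts[direction] >= need:
            out.append(
                ConsensusGene(
                    gene=gene,
                    direction=direction,
                    n_support=counts[direction],
                    n_datasets=n_datasets,
                )
            )
    return out


def integrate_upstream(
    consensus: list[ConsensusGene],
    edges: list[InteractionEdge],
    first_degree: set[str],
    focal: str,
) -> tuple[set[str], set[str]]:
    """Consensus genes adjacent to the first-degree set, either direction.

    Returns (upstream genes, focal-only genes); the latter are consensus
    genes whose only interaction is with the focal gene itself — reported
    separately, not integrated.
    """
    if not first_degree:
        raise ValueError("first-degree set is empty")
    cons_set = {c.gene for c in consensus}
    neighbors: dict[str, set[str]] = {g: set() for g in cons_set}
    for e in edges:
        if e.source in cons_set:
            neighbors[e.source].add(e.target)
        if e.target in cons_set:
            neighbors[e.target].add(e.source)
    upstream = {g for g, nb in neighbors.items() if nb & first_degree}
    focal_only = {g for g, nb in neighbors.items() if nb and nb <= {focal}}
    return upstream, focal_only


def assemble_network(
    first_degree: set[str],
    upstream: set[str],
    roles: dict[str, str],
    consensus: list[ConsensusGene],
    edges: list[InteractionEdge],
    focal: str,
) -> ProteostasisNetwork:
    """Final network with pathway activation signs and restricted edges.

    Sign precedence: literature role annotation wins; otherwise an upstream
    gene up-regulated in disease relative to the focal gene gets +1 and a
    down-regulated one -1.
    """
    missing = sorted(g for g in first_degree if g not in roles)
    if missing:
        raise ValueError(f"first-degree genes without role annotation: {missing}")
    directions = {c.gene: c.direction for c in consensus}
    nodes: list[PNNode] = []
    for gene in sorted(first_degree):
        role = roles[gene]
        nodes.append(PNNode(gene=gene, role=role, sign=ROLE_SIGN[role], tier="first_degree"))
    for gene in sorted(upstream - first_degree):
        role = roles.get(gene)
        if role is not None:
            sign = ROLE_SIGN[role]
        elif gene in directions:
            sign = directions[gene]
        else:
            raise ValueError(f"upstream gene {gene} has neither role nor consensus direction")
        nodes.append(PNNode(gene=gene, role=role, sign=sign, tier="upstream"))
    node_set = {n.gene for n in nodes} | {focal}
    kept = [e for e in edges if e.source in node_set and e.target in node_set]
    return ProteostasisNetwork(focal=focal, nodes=nodes, edges=kept)
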