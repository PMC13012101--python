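"""Dose-response drug screen on the network activity score.

Each treatment signature (drug x cell line x concentration) is reduced to a
single ΔPAS. Per drug and line, the Pearson correlation r of ΔPAS with
log10(concentration) summarizes the dose response; |r| > 0.5 and p < 0.05
classify the drug as an inhibitor (r < 0, shifts the network toward
clearance) or promoter (r > 0). Cross-line calls require a concordant sign
of r in every line, |r| above the cutoff in every line, and p < 0.05 in at
least one line; candidates are ranked by the mean |r| across lines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ProteostasisNetwork
from .pas import compute_delta_pas

logger = logging.getLogger(__name__)


@dataclass
class SignatureRecord:
    drug: str
    cell_line: str
    concentration: float  # µM
    e: pd.Series  # per-gene differential relative expression, log2 units
    duration: float = 24.0  # hours, metadata

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass(frozen=True)
class DoseResponse:
    drug: str
    cell_line: str
    r: float
    p: float
    n_doses: int
    valid: bool = True  # False when < 3 distinct concentrations


@dataclass
class DrugCall:
    drug: str
    klass: str  # inhibitor / promoter / none
    r_by_line: dict[str, float] = field(default_factory=dict)
    mean_abs_r: float = math.nan
    rank: int | None = None


def signatures_to_frame(records: list[SignatureRecord]) -> pd.DataFrame:
    """Long-format view of signature records (one row per gene measurement)."""
    rows = []
    for rec in records:
        for gene, e in rec.e.items():
            rows.append({"drug": rec.drug, "cell_line": rec.cell_line,
                         "concentration_um": rec.concentration, "gene": gene, "e": e})
    return pd.DataFrame(rows)


def signatures_from_frame(df: pd.DataFrame) -> list[SignatureRecord]:
    """Inverse of signatures_to_frame."""
    records = []
    for (drug, line, conc), grp in df.groupby(
            ["drug", "cell_line", "concentration_um"], sort=True):
        e = pd.Series(grp["e"].to_numpy(dtype=float), index=grp["gene"].tolist())
        records.append(SignatureRecord(drug=drug, cell_line=line,
                                       concentration=float(conc), e=e))
    return records


def signature_delta_pas(
    records: list[SignatureRecord],
    network: ProteostasisNetwork,
) -> pd.DataFrame:
    """ΔPAS per signature record; records with no network overlap are skipped."""
    rows = []
    n_skipped = 0
    signs = set(network.signs)
    for rec in records:
        overlap = len(signs & set(rec.e.index))
        if overlap == 0:
            n_skipped += 1
            continue
        rows.append({
            "drug": rec.drug,
            "cell_line": rec.cell_line,
            "concentration": rec.concentration,
            "delta_pas": compute_delta_pas(rec.e, network),
            "n_overlap": overlap,
        })
    if n_skipped:
        logger.info("signature_delta_pas: skipped %d records with no network overlap", n_skipped)
    return pd.DataFrame(rows)


def _pearson_dose(conc: np.ndarray, dpas: np.ndarray) -> tuple[float, float]:
    if np.std(dpas) == 0.0 or np.std(conc) == 0.0:
        return 0.0, 1.0  # constant response carries no trend information
    r, p = sps.pearsonr(np.log10(conc), dpas)
    return float(r), float(p)


def dose_response(deltas: pd.DataFrame, method: str = "pearson") -> list[DoseResponse]:
    """Correlation of ΔPAS with log10(concentration) per drug x cell line.

    Replicates at the same concentration are averaged first. Fewer than 3
    distinct concentrations yields an invalid record that is excluded from
    classification downstream.
    """
    out: list[DoseResponse] = []
    grouped = deltas.groupby(["drug", "cell_line"], sort=True)
    for (drug, line), grp in grouped:
        per_dose = grp.groupby("concentration", sort=True)["delta_pas"].mean()
        n = len(per_dose)
        if n < 3:
            out.append(DoseResponse(drug, line, math.nan, math.nan, n, valid=False))
            continue
        conc = per_dose.index.to_numpy(dtype=float)
        dpas = per_dose.to_numpy(dtype=float)
        if method == "pearson":
            r, p = _pearson_dose(conc, dpas)
        elif method == "spearman":
            if np.std(dpas) == 0.0:
                r, p = 0.0, 1.0
            else:
                r, p = (float(v) for v in sps.spearmanr(np.log10(conc), dpas))
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append(DoseResponse(drug, line, r, p, n))
    return out


def classify_drug(dr: DoseResponse, r_cut: float = 0.5, p_cut: float = 0.05) -> str:
    """Single-line call: inhibitor (r < 0) / promoter (r > 0) / none."""
    if not dr.valid or math.isnan(dr.r):
        raise ValueError("dose response has no defined correlation")
    if abs(dr.r) > r_cut and dr.p < p_cut:
        return "inhibitor" if dr.r < 0 else "promoter"
    return "none"


def cross_line_concordance(
    responses: list[DoseResponse],
    r_cut: float = 0.5,
    p_cut: float = 0.05,
    require_all_lines_significant: bool = False,
) -> tuple[list[DrugCall], list[str]]:
    """Combine per-line dose responses into cross-line drug calls.

    Only drugs with a valid response in every cell line present in the
    input are called (intersection); single-line drugs are returned
    separately and never ranked. A class is assigned when the sign of r is
    concordant across lines, |r| > r_cut in every line, and p < p_cut in at
    least one line (or in every line if require_all_lines_significant).
    """
    lines = sorted({dr.cell_line for dr in responses})
    by_drug: dict[str, dict[str, DoseResponse]] = {}
    for dr in responses:
        if dr.valid:
            by_drug.setdefault(dr.drug, {})[dr.cell_line] = dr
    calls: list[DrugCall] = []
    single_line: list[str] = []
    for drug in sorted(by_drug):
        per_line = by_drug[drug]
        if set(per_line) != set(lines):
            single_line.append(drug)
            continue
        rs = {line: per_line[line].r for line in lines}
        ps = [per_line[line].p for line in lines]
        signs = {np.sign(r) for r in rs.values()}
        concordant = len(signs) == 1 and 0.0 not in signs
        strong = all(abs(r) > r_cut for r in rs.values())
        if require_all_lines_significant:
            significant = all(p < p_cut for p in ps)
        else:
            significant = any(p < p_cut for p in ps)
        if concordant and strong and significant:
            klass = "inhibitor" if next(iter(signs)) < 0 else "promoter"
        else:
            klass = "none"
        calls.append(DrugCall(
            drug=drug,
            klass=klass,
            r_by_line=rs,
            mean_abs_r=float(np.mean([abs(r) for r in rs.values()])),
        ))
    return calls, single_line


def prioritize(calls: list[DrugCall], wanted_class: str = "inhibitor") -> list[DrugCall]:
    """Rank calls of one class by descending mean |r| (ties: drug id)."""
    selected = [c for c in calls if c.klass == wanted_class]
    if not selected:
        logger.warning("no %s calls to rank", wanted_class)
        return []
    selected.sort(key=lambda c: (-c.mean_abs_r, c.drug))
    for i, c in enumerate(selected, start=1):
        c.rank = i
    return selected
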