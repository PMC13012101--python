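"""End-to-end pipeline on synthetic inputs.

One seeded run chains every stage: simulate inputs -> assemble the network
(first-degree + consensus + upstream) -> PAS scoring and group comparison ->
influence scores -> digital-twin fit and perturbation screen -> cell-line
ranking -> dose-response drug screen. All outputs are deterministic TSV/JSON
under the chosen output directory; two runs with the same config and seed
are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, network as net, pas, influence, twin as tw, screen as scr, simulate as sim

DEFAULT_CONFIG: dict = {
    "focal": "SNCA",
    "edgelist": {"n_first_degree": 12, "n_background": 300, "n_upstream": 6,
                 "promoter_fraction": 0.6},
    "case_control": {"n_datasets": 6, "n_case": 10, "n_control": 10,
                     "effect": 1.0, "noise_sd": 0.2, "n_consistent": 4,
                     "n_extra_planted": 4},
    "consensus": {"fc_cut": 0.3, "q_cut": 0.05, "min_fraction": 0.5, "adjust": "BH"},
    "influence": {"t": 0.1, "damping": 0.85},
    "single_cell": {"n_cells": 800, "pcor": 0.3, "structure": "chain"},
    "twin": {"q_cut": 0.05, "n_queries": 4},
    "cell_lines": {"n_lines": 40, "fraction": 0.6, "gradient": 1.0, "noise_sd": 0.1},
    "drugs": {"n_drugs": 50, "cell_lines": ["LINE_A", "LINE_B"],
              "concentrations": [0.04, 0.12, 0.37, 1.11, 3.33, 10.0],
              "noise_sd": 0.05, "r_cut": 0.5, "p_cut": 0.05},
}


def _merge(base: dict, override: dict | None) -> dict:
    if not override:
        return {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            out[k] = {**v, **override.get(k, {})}
        else:
            out[k] = override.get(k, v)
    return out


def run_pipeline(seed: int, outdir, config: dict | None = None) -> dict:
    """Run every stage from synthetic inputs; returns a summary dict."""
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    focal = cfg["focal"]

    # --- simulate interaction structure and roles
    ecfg = cfg["edgelist"]
    edges, roles, net_truth = sim.gen_edgelist(
        ecfg["n_first_degree"], ecfg["n_background"], ecfg["n_upstream"],
        seed=seeds[0], promoter_fraction=ecfg["promoter_fraction"], focal=focal)
    io.write_table(
        [{"source": e.source, "target": e.target,
          "direction": "->" if e.directed else "-"} for e in edges],
        outdir / "edgelist.tsv")
    io.write_table([{"gene": g, "role": r} for g, r in sorted(roles.items())],
                   outdir / "roles.tsv")

    # --- simulate case/control expression and derive the consensus
    ccfg = cfg["case_control"]
    genes = [focal] + net_truth["first_degree"] + net_truth["upstream"] + net_truth["background"]
    rng = np.random.default_rng(seeds[1])
    extra = [g for g in net_truth["background"][: ccfg["n_extra_planted"]]]
    planted = [
        (g, "up" if rng.random() < 0.7 else "down", ccfg["effect"])
        for g in net_truth["upstream"] + extra
    ]
    datasets, cc_truth = sim.gen_case_control_sets(
        ccfg["n_datasets"], ccfg["n_case"], ccfg["n_control"], genes, planted,
        ccfg["noise_sd"], ccfg["n_consistent"], seed=seeds[1], focal=focal)

    kcfg = cfg["consensus"]
    results_by_dataset = []
    for d, mat in enumerate(datasets):
        rel = net.relative_expression(mat, focal)
        res = net.differential_relative_expression(
            rel, "case", "control", adjust=kcfg["adjust"], dataset_id=f"DS{d + 1}")
        results_by_dataset.append(res)
        io.write_table(
            [{"gene": r.gene, "fc": r.fc, "p": r.p, "q": r.q,
              "direction": r.direction} for r in res],
            outdir / f"differential_DS{d + 1}.tsv", sort_by=["gene"])
    consensus = net.consensus_genes(
        results_by_dataset, fc_cut=kcfg["fc_cut"], q_cut=kcfg["q_cut"],
        min_fraction=kcfg["min_fraction"], reference=focal)
    io.write_table(
        [{"gene": c.gene, "direction": c.direction, "n_support": c.n_support,
          "n_datasets": c.n_datasets} for c in consensus],
        outdir / "consensus.tsv", sort_by=["gene"], allow_empty=True)

    # --- assemble the network
    first_degree = net.first_degree_interactors(edges, set(net_truth["pn_members"]), focal)
    upstream, focal_only = net.integrate_upstream(consensus, edges, first_degree, focal)
    pn = net.assemble_network(first_degree, upstream, roles, consensus, edges, focal)
    pn.to_json(outdir / "network.json")

    # --- PAS per dataset and group contrast
    pas_rows, contrasts = [], []
    for d, mat in enumerate(datasets):
        z = pas.zscore_within_sample(mat)
        res = pas.compute_pas(z, pn)
        pas_rows += [{"dataset": f"DS{d + 1}", "sample": r.sample, "pas": r.pas,
                      "K_used": r.K, "n_missing": r.n_missing} for r in res]
        cmp = pas.compare_pas_groups(res, mat.sample_meta, mode="group",
                                     groups=("case", "control"))
        contrasts.append({"dataset": f"DS{d + 1}", "median_diff": cmp["median_diff"],
                          "p": cmp["p"]})
    io.write_table(pas_rows, outdir / "pas.tsv", sort_by=["dataset", "sample"])
    io.write_table(contrasts, outdir / "pas_group_contrasts.tsv", sort_by=["dataset"])

    # --- influence
    icfg = cfg["influence"]
    inf = influence.influence_table(pn, t=icfg["t"], damping=icfg["damping"])
    io.write_table(inf.to_dict(orient="records"), outdir / "influence.tsv", sort_by=["gene"])

    # --- digital twin on synthetic single cells over the network genes
    sccfg = cfg["single_cell"]
    net_genes = sorted(n.gene for n in pn.nodes)
    precision, planted_edges = sim.make_planted_precision(
        len(net_genes), pcor=sccfg["pcor"], structure=sccfg["structure"], genes=net_genes)
    cells, sc_truth = sim.gen_single_cell(precision, sccfg["n_cells"], seed=seeds[2])
    z_cells, norm_stats = tw.zscore_per_cell(cells)
    z_net = z_cells.values.loc[net_genes]
    ggm = tw.fit_ggm(z_net, norm_stats=norm_stats)
    twin = tw.build_linear_twin(ggm, z_net, q_cut=cfg["twin"]["q_cut"])
    twin.to_json(outdir / "twin.json")
    queries = net_genes[: cfg["twin"]["n_queries"]]
    outcomes, ranking = tw.perturbation_screen(twin, cells, norm_stats, pn, queries)
    io.write_table(
        [{"query": o.query, "factor": o.factor, "cohen_d": o.cohen_d} for o in outcomes],
        outdir / "perturbation_outcomes.tsv", sort_by=["query", "factor"])
    io.write_table(ranking.to_dict(orient="records"),
                   outdir / "perturbation_ranking.tsv", sort_by=["rank"])

    # --- cell-line ranking
    clcfg = cfg["cell_lines"]
    ntpm, cl_truth = sim.gen_cell_line_table(
        clcfg["n_lines"], clcfg["fraction"], pn, activity_gradient=clcfg["gradient"],
        seed=seeds[3], noise_sd=clcfg["noise_sd"])
    lines = pas.rank_cell_lines(ntpm, pn)
    io.write_table(
        [{"line": r.line, "pas": r.pas, "pas_z": r.pas_z, "p": r.p, "rank": r.rank}
         for r in lines],
        outdir / "cell_line_ranking.tsv", sort_by=["rank"])

    # --- drug screen
    dcfg = cfg["drugs"]
    records, drug_truth = sim.gen_dose_signatures(
        dcfg["n_drugs"], dcfg["concentrations"], dcfg["cell_lines"], pn,
        noise_sd=dcfg["noise_sd"], seed=seeds[4])
    deltas = scr.signature_delta_pas(records, pn)
    responses = scr.dose_response(deltas)
    io.write_table(
        [{"drug": r.drug, "cell_line": r.cell_line, "r": r.r, "p": r.p,
          "n_doses": r.n_doses} for r in responses],
        outdir / "dose_response.tsv", sort_by=["drug", "cell_line"])
    calls, single_line = scr.cross_line_concordance(
        responses, r_cut=dcfg["r_cut"], p_cut=dcfg["p_cut"])
    inhibitors = scr.prioritize(calls, "inhibitor")
    io.write_table(
        [{"drug": c.drug, "class": c.klass, "mean_abs_r": c.mean_abs_r}
         for c in calls],
        outdir / "drug_calls.tsv", sort_by=["drug"])
    io.write_table(
        [{"rank": c.rank, "drug": c.drug, "mean_abs_r": c.mean_abs_r}
         for c in inhibitors],
        outdir / "inhibitor_ranking.tsv", sort_by=["rank"], allow_empty=True)

    summary = {
        "seed": seed,
        "n_first_degree": len(first_degree),
        "n_consensus": len(consensus),
        "n_upstream": len(upstream),
        "n_focal_only": len(focal_only),
        "network_K": pn.K,
        "n_significant_twin_edges": len(ggm.significant_edges(cfg["twin"]["q_cut"])),
        "n_cell_lines_ranked": len(lines),
        "n_drugs_called": len(calls),
        "n_inhibitors": len(inhibitors),
        "truth": {
            "planted_consensus": sorted(p["gene"] for p in cc_truth["planted"]),
            "planted_upstream": net_truth["upstream"],
            "planted_twin_edges": [list(e) for e in planted_edges],
            "inhibitor_slopes": {d: s for d, s in drug_truth["slopes"].items() if s < 0},
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
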