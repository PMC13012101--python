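#!/usr/bin/env python
"""Stage 1: generate all synthetic inputs with planted ground truth.

Writes the interaction edgelist, role annotations, curated member list and
six case/control expression datasets (plus truth JSONs) under results/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import yaml

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from synpas import io, simulate as sim


def main() -> None:
    out = common.outdir()
    edges, roles, net_truth = sim.gen_edgelist(
        common.N_FIRST_DEGREE, common.N_BACKGROUND, common.N_UPSTREAM,
        seed=common.child_seed(0), focal=common.FOCAL)
    io.write_table([{"source": e.source, "target": e.target,
                     "direction": "->" if e.directed else "-"} for e in edges],
                   out / "edgelist.tsv")
    io.write_table([{"gene": g, "role": r} for g, r in sorted(roles.items())],
                   out / "roles.tsv")
    (out / "pn_members.txt").write_text("\n".join(net_truth["pn_members"]) + "\n")
    (out / "edgelist_truth.json").write_text(
        json.dumps(net_truth, indent=1, sort_keys=True) + "\n")

    # plant consensus effects on the upstream genes plus a few background genes
    genes = ([common.FOCAL] + net_truth["first_degree"]
             + net_truth["upstream"] + net_truth["background"])
    cc_seed = common.child_seed(1)
    rng = np.random.default_rng(cc_seed)
    planted = [(g, "up" if rng.random() < 0.7 else "down", common.EFFECT)
               for g in net_truth["upstream"] + net_truth["background"][:4]]
    datasets, cc_truth = sim.gen_case_control_sets(
        common.N_DATASETS, common.N_CASE, common.N_CONTROL, genes, planted,
        common.NOISE_SD, common.N_CONSISTENT, seed=cc_seed, focal=common.FOCAL)
    specs = []
    for d, mat in enumerate(datasets, start=1):
        io.write_expression_table(mat, out / f"dataset{d}.tsv")
        mat.sample_meta.to_csv(out / f"dataset{d}_meta.tsv", sep="\t")
        specs.append({"expression": str(out / f"dataset{d}.tsv"),
                      "meta": str(out / f"dataset{d}_meta.tsv")})
    (out / "datasets.yaml").write_text(yaml.safe_dump(specs, sort_keys=True))
    (out / "case_control_truth.json").write_text(
        json.dumps(cc_truth, indent=1, sort_keys=True) + "\n")
    print(f"wrote {len(edges)} edges, {len(datasets)} datasets, "
          f"{len(planted)} planted consensus genes -> {out}")


if __name__ == "__main__":
    main()
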