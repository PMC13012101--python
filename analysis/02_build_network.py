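#!/usr/bin/env python
"""Stage 2: differential relative expression, consensus, network assembly.

Reads stage-1 files from disk (exercising the file formats, not in-memory
objects) and writes per-dataset differential tables, the consensus list and
the assembled network JSON.
"""

import json
import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from synpas import io, network as net


def main() -> None:
    out = common.outdir()
    edges = io.read_edgelist(out / "edgelist.tsv")
    roles = io.read_roles(out / "roles.tsv")
    members = set((out / "pn_members.txt").read_text().split())

    results = []
    for i, spec in enumerate(yaml.safe_load((out / "datasets.yaml").read_text()), 1):
        mat = io.read_expression_table(spec["expression"], scale_hint="log2",
                                       meta_path=spec["meta"])
        rel = net.relative_expression(mat, common.FOCAL)
        res = net.differential_relative_expression(
            rel, "case", "control", dataset_id=f"DS{i}")
        results.append(res)
        io.write_table([{"gene": r.gene, "fc": r.fc, "p": r.p, "q": r.q,
                         "direction": r.direction} for r in res],
                       out / f"differential_DS{i}.tsv", sort_by=["gene"])

    consensus = net.consensus_genes(results, reference=common.FOCAL)
    io.write_table([{"gene": c.gene, "direction": c.direction,
                     "n_support": c.n_support, "n_datasets": c.n_datasets}
                    for c in consensus], out / "consensus.tsv",
                   sort_by=["gene"], allow_empty=True)

    fd = net.first_degree_interactors(edges, members, common.FOCAL)
    upstream, focal_only = net.integrate_upstream(consensus, edges, fd, common.FOCAL)
    pn = net.assemble_network(fd, upstream, roles, consensus, edges, common.FOCAL)
    pn.to_json(out / "network.json")

    truth = json.loads((out / "case_control_truth.json").read_text())
    planted = {p["gene"] for p in truth["planted"]}
    called = {c.gene for c in consensus}
    print(f"consensus: {len(called)} genes "
          f"({len(called & planted)}/{len(planted)} planted recovered, "
          f"{len(called - planted)} background)")
    print(f"network: K={pn.K} ({len(fd)} first-degree, {len(upstream)} upstream, "
          f"{len(focal_only)} consensus genes touching only the focal)")


if __name__ == "__main__":
    main()
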