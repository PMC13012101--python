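#!/usr/bin/env python
"""Stage 3: PAS per sample and case-vs-control contrasts per dataset."""

import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from synpas import io, pas


def main() -> None:
    out = common.outdir()
    pn = io.ProteostasisNetwork.from_json(out / "network.json")
    rows, contrasts = [], []
    for i, spec in enumerate(yaml.safe_load((out / "datasets.yaml").read_text()), 1):
        mat = io.read_expression_table(spec["expression"], scale_hint="log2",
                                       meta_path=spec["meta"])
        z = pas.zscore_within_sample(mat)
        res = pas.compute_pas(z, pn)
        rows += [{"dataset": f"DS{i}", "sample": r.sample, "pas": r.pas,
                  "K_used": r.K, "n_missing": r.n_missing} for r in res]
        cmp = pas.compare_pas_groups(res, mat.sample_meta, mode="group",
                                     groups=("case", "control"))
        contrasts.append({"dataset": f"DS{i}", "median_diff": cmp["median_diff"],
                          "p": cmp["p"]})
    io.write_table(rows, out / "pas.tsv", sort_by=["dataset", "sample"])
    io.write_table(contrasts, out / "pas_group_contrasts.tsv", sort_by=["dataset"])
    for c in contrasts:
        print(f"{c['dataset']}: case-control PAS median diff "
              f"{c['median_diff']:+.4f} (p={c['p']:.3g})")


if __name__ == "__main__":
    main()
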