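#!/usr/bin/env python
"""Stage 4: heat-diffusion / PPR influence scores and quadrant categories."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from synpas import influence as infl
from synpas import io


def main() -> None:
    out = common.outdir()
    pn = io.ProteostasisNetwork.from_json(out / "network.json")
    df = infl.influence_table(pn)
    io.write_table(df.to_dict(orient="records"), out / "influence.tsv",
                   sort_by=["gene"])
    counts = df["category"].value_counts().to_dict()
    print("quadrants:", {k: counts.get(k, 0) for k in infl.CATEGORIES})
    top = df.sort_values(["heat", "gene"], ascending=[False, True]).head(3)
    for _, row in top.iterrows():
        print(f"top heat influence: {row['gene']} "
              f"(heat={row['heat']:.4f}, ppr={row['ppr']:.4f}, "
              f"{row['category']})")


if __name__ == "__main__":
    main()
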