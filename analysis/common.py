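"""Shared configuration for the numbered analysis scripts.

All scripts write into RESULTS and read each other's outputs from there, so
they must be run in order (01 .. 07). SEED controls every generator; child
seeds are spawned per stage so stages stay independently reproducible.
"""

from pathlib import Path

import numpy as np

SEED = 1
FOCAL = "SNCA"
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

# study conditions (mirroring the library defaults)
N_FIRST_DEGREE = 12
N_BACKGROUND = 300
N_UPSTREAM = 6
N_DATASETS = 6
N_CASE = N_CONTROL = 10
EFFECT = 1.0
NOISE_SD = 0.2
N_CONSISTENT = 4
N_CELLS = 800
PCOR = 0.3
N_LINES = 40
DETECTABLE_FRACTION = 0.6
N_DRUGS = 50
CELL_LINES = ["LINE_A", "LINE_B"]
CONCENTRATIONS = [0.04, 0.12, 0.37, 1.11, 3.33, 10.0]


def child_seed(stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence(SEED)
    return int(ss.spawn(stage + 1)[stage].generate_state(1)[0] % (2**31))


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
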