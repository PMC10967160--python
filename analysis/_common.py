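"""Shared plumbing for the numbered analysis scripts.

Each script is a thin narrative driver over the ``nssinet`` library.  The
cohort is fully determined by the seed, so later scripts regenerate it
deterministically instead of depending on earlier scripts' files."""

from __future__ import annotations

import argparse
from pathlib import Path

from nssinet import SimConfig, TrueGGM, make_true_network, sample_likert


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1, help="root seed for the cohort")
    ap.add_argument(
        "--out", type=Path, default=Path("results/analysis"), help="output directory"
    )
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    return args


def cohort(seed: int, n: int = 412):
    """The default 21-node simulated cohort (19 function items + PHQ-9 and
    GAD-7 total-score nodes), deterministic in the seed."""
    cfg = SimConfig(n=n, seed=seed)
    truth = make_true_network(cfg)
    table = sample_likert(truth, cfg)
    return cfg, truth, table
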