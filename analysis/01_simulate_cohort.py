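#!/usr/bin/env python
"""Simulate the default synthetic cohort and write the raw data files.

Generates 23 children + 30 adolescents, each performing the full
incentivized dot-comparison session, and writes per-subject trial logs,
pupil sample streams and event tables plus a checksummed manifest under
``data/``.  The block count is scaled down from the task's 32 blocks to
keep the raw pupil streams small; pass ``--full`` for the complete session.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

import argparse
from pathlib import Path

from incentive_ans.cli import _simulate_to_dir
from incentive_ans.io import RunConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("data"))
    ap.add_argument("--full", action="store_true", help="all 32 blocks")
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed, n_blocks=32 if args.full else 8)
    _simulate_to_dir(cfg, args.out)
    cfg.to_yaml(args.out / "config.yaml")
    n = cfg.n_children + cfg.n_adolescents
    print(
        f"simulated {n} subjects ({cfg.n_children} children, "
        f"{cfg.n_adolescents} adolescents), {cfg.n_blocks} blocks of "
        f"{cfg.trials_per_block} trials each -> {args.out}/"
    )


if __name__ == "__main__":
    main()
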