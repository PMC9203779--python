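#!/usr/bin/env python
"""Behavioural summaries and EZ-diffusion decomposition.

Reads the simulated trial logs from ``data/``, applies the 250-1500 ms RT
window, summarizes each subject x condition into (Pc, MRT, VRT) and
inverts the summaries into drift rate, boundary separation and
non-decision time.  Writes ``results/ez_table.csv`` and prints the
condition means — expect higher drift under reward in both age groups,
and faster/more efficient processing in adolescents.

Run after 01_simulate_cohort.py:  python analysis/02_fit_ez.py
"""

import argparse
from pathlib import Path

from incentive_ans.cli import _subject_records
from incentive_ans.pipeline import ez_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("data"))
    ap.add_argument("--out", type=Path, default=Path("results/ez_table.csv"))
    args = ap.parse_args()
    records = _subject_records(args.data, with_pupil=False)
    df = ez_table(records)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    means = df[df["valid"]].groupby(["age_group", "incentive"])[
        ["Pc", "MRT_s", "v", "a", "t_ER"]
    ].mean()
    print(f"EZ table ({len(df)} subject x condition rows) -> {args.out}")
    print(means.round(3).to_string())


if __name__ == "__main__":
    main()
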