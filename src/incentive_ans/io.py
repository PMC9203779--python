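"""File formats, run configuration and provenance manifest.

All tables are UTF-8 CSV/TSV with a header row and '.' decimal separator:
trial logs and events as comma-separated CSV, pupil sample streams as
tab-separated TSV (one sample per row).  Times are milliseconds, diameters
millimetres; floats are written at full precision so a write/read cycle is
bit-exact.  A manifest (JSON) records every file a simulation run produced
together with its SHA-256 checksum and the config that generated it, so
every downstream number is traceable to inputs + seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from incentive_ans.cohort import PupilStream
from incentive_ans.design import TrialSpec
from incentive_ans.ez import TrialResult

__all__ = [
    "RunConfig",
    "write_session",
    "read_session",
    "write_trials",
    "read_trials",
    "write_stream",
    "read_stream",
    "write_manifest",
    "verify_manifest",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: parameters + seeds only."""

    seed: int = 1
    n_children: int = 23
    n_adolescents: int = 30
    effect_scale: float = 1.0
    n_blocks: int = 32
    trials_per_block: int = 24
    ratios: list[str] = field(default_factory=lambda: ["4:3", "5:4", "8:7", "10:9"])
    dot_range: list[int] = field(default_factory=lambda: [12, 32])
    sampling_rate_hz: float = 60.0
    rt_window_ms: list[float] = field(default_factory=lambda: [250.0, 1500.0])
    max_blink_ms: float = 500.0
    max_missing_frac: float = 0.25
    guard_ms: float = 40.0
    min_trials: int = 10
    gaze_area_deg: float = 10.0
    n_perm: int = 5000
    alpha: float = 0.05
    ratio_factor: bool = False

    def ratio_fractions(self) -> list[Fraction]:
        return [Fraction(*(int(x) for x in r.split(":"))) for r in self.ratios]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


# ---------------------------------------------------------------------------
# session / trial tables

def write_session(session: Sequence[TrialSpec], path: str | Path) -> None:
    rows = [
        {
            "block_index": t.block_index,
            "trial_index": t.trial_index,
            "incentive": t.incentive,
            "ratio": f"{t.ratio.numerator}:{t.ratio.denominator}",
            "larger_side": t.larger_side,
            "n_dots_left": t.n_dots_left,
            "n_dots_right": t.n_dots_right,
            "cue_color": t.cue_color,
        }
        for t in session
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_session(path: str | Path) -> list[TrialSpec]:
    df = pd.read_csv(path)
    return [
        TrialSpec(
            block_index=int(r.block_index),
            trial_index=int(r.trial_index),
            incentive=r.incentive,
            ratio=Fraction(*(int(x) for x in r.ratio.split(":"))),
            larger_side=r.larger_side,
            n_dots_left=int(r.n_dots_left),
            n_dots_right=int(r.n_dots_right),
            cue_color=r.cue_color,
        )
        for r in df.itertuples()
    ]


def write_trials(
    results: Sequence[TrialResult],
    path: str | Path,
    subject_id: str = "",
    age_group: str = "",
) -> None:
    rows = [
        {
            "subject_id": subject_id,
            "age_group": age_group,
            "block_index": t.block_index,
            "trial_index": t.trial_index,
            "incentive": t.incentive,
            "rt_ms": t.rt_ms if t.rt_ms is not None else np.nan,
            "correct": int(t.correct),
            "points_delta": t.points_delta,
        }
        for t in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials(path: str | Path) -> tuple[list[TrialResult], str, str]:
    df = pd.read_csv(path)
    results = [
        TrialResult(
            block_index=int(r.block_index),
            trial_index=int(r.trial_index),
            incentive=r.incentive,
            rt_ms=None if pd.isna(r.rt_ms) else float(r.rt_ms),
            correct=bool(r.correct),
            points_delta=int(r.points_delta),
        )
        for r in df.itertuples()
    ]
    sid = str(df["subject_id"].iloc[0]) if len(df) else ""
    grp = str(df["age_group"].iloc[0]) if len(df) else ""
    return results, sid, grp


# ---------------------------------------------------------------------------
# pupil streams

def write_stream(stream: PupilStream, samples_path: str | Path, events_path: str | Path) -> None:
    """Samples as TSV (one row per sample), trial events as CSV."""
    stream.samples.to_csv(samples_path, sep="\t", index=False)
    stream.trial_events.to_csv(events_path, index=False)


def read_stream(
    samples_path: str | Path,
    events_path: str | Path,
    sampling_rate_hz: float | None = None,
) -> PupilStream:
    """Thin adapter: any export with the documented columns loads here."""
    samples = pd.read_csv(samples_path, sep="\t")
    events = pd.read_csv(events_path)
    required = {"t_ms", "left_mm", "right_mm", "gaze_x_deg", "gaze_y_deg", "event_label"}
    if not required.issubset(samples.columns):
        raise ValueError(f"sample stream missing columns {sorted(required - set(samples.columns))}")
    if sampling_rate_hz is None:
        dt = np.diff(samples["t_ms"].to_numpy()[:100])
        sampling_rate_hz = float(round(1000.0 / np.median(dt), 3))
    return PupilStream(
        sampling_rate_hz=sampling_rate_hz,
        samples=samples,
        trial_events=events,
        blink_schedule=[],
    )


# ---------------------------------------------------------------------------
# provenance manifest

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, files: Sequence[str | Path], config: RunConfig
) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "config": dataclasses.asdict(config),
        "files": {
            str(Path(f).relative_to(out_dir)): _sha256(Path(f)) for f in files
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def verify_manifest(out_dir: str | Path) -> dict[str, bool]:
    """Re-hash every manifest entry; True where the checksum still matches."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return {
        rel: (out_dir / rel).exists() and _sha256(out_dir / rel) == digest
        for rel, digest in manifest["files"].items()
    }
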