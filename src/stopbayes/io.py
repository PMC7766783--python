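"""Events-file I/O, coordinate labeling and run configuration.

Events are tab-separated with BIDS-style column names (``onset``,
``duration``, ``trial_type``, ``ssd_ms``, ``responded``, ``rt_ms``), one
row per trial, preceded by a format-version comment line.  Missing values
(SSD on go trials, RT without a response) are written as ``n/a``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .sst import TrialRecord

__all__ = [
    "FORMAT_VERSION",
    "EventsFormatError",
    "read_events",
    "write_events",
    "events_to_frame",
    "label_anterior_posterior",
    "RunConfig",
    "load_config",
]

FORMAT_VERSION = "stopbayes-events v1"
_COLUMNS = ["onset", "duration", "trial_type", "ssd_ms", "responded", "rt_ms"]

#: Longitudinal-axis split of the hippocampus in MNI space (mm).  The
#: boundary plane y = -22 is labeled anterior (closed on the anterior
#: side); strictly smaller y is posterior.
AP_BOUNDARY_Y_MM = -22.0


class EventsFormatError(ValueError):
    pass


def events_to_frame(records: Sequence[TrialRecord], extra: Optional[dict] = None) -> pd.DataFrame:
    """Trial records as a BIDS-events-style DataFrame (durations are 0:
    events are modeled as impulses)."""
    frame = pd.DataFrame(
        {
            "onset": [r.onset_s for r in records],
            "duration": [0.0] * len(records),
            "trial_type": [r.category for r in records],
            "ssd_ms": [r.ssd_ms for r in records],
            "responded": [int(r.responded) for r in records],
            "rt_ms": [r.rt_ms for r in records],
        }
    )
    for k, v in (extra or {}).items():
        frame[k] = v
    return frame


def write_events(records: Sequence[TrialRecord], path, extra: Optional[dict] = None) -> None:
    """Write trial records as TSV with a format-version header line."""
    frame = events_to_frame(records, extra=extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        # shortest round-trip float repr: write∘read is the identity
        frame.to_csv(fh, sep="\t", index=False, na_rep="n/a")


def _outcome(trial_type: str, responded: bool) -> str:
    if trial_type == "go":
        return "GS" if responded else "GE"
    return "SE" if responded else "SS"


def read_events(path) -> list[TrialRecord]:
    """Read an events TSV back into validated trial records.

    Rejects unknown format versions, missing columns, negative or
    non-monotone onsets, and rows violating the trial invariants (for
    example a go trial carrying an SSD), reporting offending line numbers.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise EventsFormatError(f"{path}: missing format-version header line")
        version = first.lstrip("# ").strip()
        if version != FORMAT_VERSION:
            raise EventsFormatError(f"{path}: unknown format version {version!r}")
        frame = pd.read_csv(fh, sep="\t", na_values=["n/a"], float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise EventsFormatError(f"{path}: missing required column(s) {', '.join(missing)}")

    problems: list[str] = []
    records: list[TrialRecord] = []
    prev_onset = -np.inf
    for i, row in frame.iterrows():
        line = i + 3  # header comment + column row are lines 1-2
        onset = float(row["onset"])
        if onset < 0:
            problems.append(f"line {line}: negative onset {onset}")
            continue
        if onset <= prev_onset:
            problems.append(f"line {line}: non-monotone onset {onset}")
            continue
        prev_onset = onset
        trial_type = str(row["trial_type"])
        ssd = None if pd.isna(row["ssd_ms"]) else float(row["ssd_ms"])
        rt = None if pd.isna(row["rt_ms"]) else float(row["rt_ms"])
        responded = bool(int(row["responded"]))
        try:
            records.append(
                TrialRecord(
                    index=len(records) + 1,
                    onset_s=onset,
                    category=trial_type,
                    ssd_ms=ssd,
                    responded=responded,
                    rt_ms=rt,
                    outcome=_outcome(trial_type, responded),
                )
            )
        except ValueError as err:
            problems.append(f"line {line}: {err}")
    if problems:
        raise EventsFormatError(f"{path}: " + "; ".join(problems))
    return records


def label_anterior_posterior(coordinates: Sequence[Sequence[float]]) -> list[str]:
    """Label MNI (x, y, z) mm coordinates as hippocampal ``anterior``
    (y >= -22, boundary included) or ``posterior`` (y < -22)."""
    labels = []
    for x, y, z in coordinates:
        if not all(np.isfinite([x, y, z])):
            raise ValueError(f"non-finite coordinate ({x}, {y}, {z})")
        labels.append("anterior" if y >= AP_BOUNDARY_Y_MM else "posterior")
    return labels


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters for a full pipeline run (defaults are the
    study-standard values: observer alpha 0.8 / pm 0.25 / scale 10,
    staircase 200/67 ms, TR 2 s, 128 s high-pass, 10,000 bootstrap
    draws)."""

    seed: int = 0
    out_dir: str = "stopbayes_out"
    log_level: str = "INFO"
    n_subjects: int = 149
    n_sessions: int = 4
    trials_per_session: int = 100
    stop_fraction: float = 0.25
    ssd_start_ms: float = 200.0
    ssd_step_ms: float = 67.0
    alpha: float = 0.8
    pm: float = 0.25
    scale: float = 10.0
    grid_size: int = 1000
    ssrt_method: str = "critical_ssd"
    tr_s: float = 2.0
    hp_cutoff_s: float = 128.0
    n_boot: int = 10000
    mediation_mode: str = "none"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected loudly."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**data)
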