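"""Read EMR-style CSV tables into per-stay episodes and apply cohort rules.

The dialect is a pre-mapped, de-identified variant of the MIMIC-III tables:
measurements already carry canonical feature names (no ITEMID mapping), and
all times are fractional hours from ICU admission.  Four files make up a
cohort directory::

    chartevents.csv   STAY_ID, FEATURE, CHARTTIME_H, VALUENUM
    noteevents.csv    STAY_ID, CHARTTIME_H, CATEGORY, TEXT
    diagnoses.csv     STAY_ID, ICD9_CODE
    labels.csv        STAY_ID, MORTALITY, AGE   (optional at predict time)

Cohort rules applied downstream of reading: adults only (age >= 16) and
stays covering at least 48 h of measurements.  Chronic status is decided by
ICD-9 membership in a configurable chronic-condition list, and chronic
patients additionally contribute their pre-window "history" notes to the
text branch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .resources import feature_names, gcs_lookup, load_chronic_codes

logger = logging.getLogger(__name__)

CHART_FILE = "chartevents.csv"
NOTE_FILE = "noteevents.csv"
DIAG_FILE = "diagnoses.csv"
LABEL_FILE = "labels.csv"

_REQUIRED_COLUMNS = {
    CHART_FILE: ["STAY_ID", "FEATURE", "CHARTTIME_H", "VALUENUM"],
    NOTE_FILE: ["STAY_ID", "CHARTTIME_H", "CATEGORY", "TEXT"],
    DIAG_FILE: ["STAY_ID", "ICD9_CODE"],
    LABEL_FILE: ["STAY_ID", "MORTALITY", "AGE"],
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class RawEvent:
    stay_id: str
    feature_name: str
    time: float          # hours from ICU admission
    value: float


@dataclass(frozen=True)
class RawNote:
    stay_id: str
    chart_time: float    # hours from ICU admission; negative = pre-admission
    category: str
    text: str


@dataclass
class PatientEpisode:
    stay_id: str
    age: float
    chronic: bool
    events: list[RawEvent]
    notes: list[RawNote]
    label: int | None = None

    @property
    def max_event_time(self) -> float:
        return max((e.time for e in self.events), default=float("-inf"))


@dataclass
class NoteBundle:
    """Notes feeding the text branch: in-window notes always, plus the K
    pre/post-window history notes when the patient is chronic."""

    stay_id: str
    window_notes: list[RawNote] = field(default_factory=list)
    history_notes: list[RawNote] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.history_notes)

    @property
    def is_empty(self) -> bool:
        return not self.window_notes and not self.history_notes


def normalize_icd9(code: str) -> str:
    return str(code).strip().replace(".", "").upper()


def classify_chronic(icd9_codes: Iterable[str], chronic_list: frozenset[str] | set[str]) -> bool:
    """True iff any (decimal-stripped) code belongs to the chronic list."""
    normalized = {normalize_icd9(c) for c in chronic_list}
    return any(normalize_icd9(c) in normalized for c in icd9_codes)


def _check_columns(df: pd.DataFrame, fname: str) -> None:
    for col in _REQUIRED_COLUMNS[fname]:
        if col not in df.columns:
            raise SchemaError(f"{fname}: missing required column {col!r}")


def _parse_value(raw, lookup: Mapping[str, float]) -> float | None:
    """Numeric value, or the GCS ordinal score for a categorical response."""
    try:
        v = float(raw)
        return v if math.isfinite(v) else None
    except (TypeError, ValueError):
        key = str(raw).strip().lower()
        return lookup.get(key)


def read_tables(
    data_dir: str | Path,
    chronic_codes: frozenset[str] | None = None,
    stats: dict | None = None,
) -> list[PatientEpisode]:
    """Assemble one :class:`PatientEpisode` per stay id from a cohort directory.

    Rows for features outside the canonical 17-feature list are dropped (count
    logged and recorded in ``stats``), as are rows whose value parses neither
    as a number nor as a Glasgow-Coma-Scale response.  A feature reported by
    several source tables upstream arrives here as one stream; duplicate
    measurements at identical timestamps are averaged at the hourly-binning
    stage.
    """
    data_dir = Path(data_dir)
    chart_path = data_dir / CHART_FILE
    if not chart_path.exists():
        raise FileNotFoundError(f"events table not found: {chart_path}")

    # keep_default_na=False: "None" is a valid Glasgow-Coma-Scale response,
    # not a missing value
    chart = pd.read_csv(chart_path, dtype={"STAY_ID": str, "FEATURE": str},
                        keep_default_na=False)
    _check_columns(chart, CHART_FILE)

    known = set(feature_names())
    unknown_mask = ~chart["FEATURE"].isin(known)
    n_unknown = int(unknown_mask.sum())
    if n_unknown:
        logger.info("dropping %d event rows with unknown features", n_unknown)
    chart = chart[~unknown_mask]

    lookup = gcs_lookup()
    values = chart["VALUENUM"].map(lambda r: _parse_value(r, lookup))
    n_bad = int(values.isna().sum())
    if n_bad:
        logger.info("skipping %d event rows with unparseable values", n_bad)
    chart = chart.assign(PARSED_VALUE=values).dropna(subset=["PARSED_VALUE"])

    notes = pd.DataFrame(columns=_REQUIRED_COLUMNS[NOTE_FILE])
    note_path = data_dir / NOTE_FILE
    if note_path.exists():
        notes = pd.read_csv(note_path, dtype={"STAY_ID": str}, keep_default_na=False)
        _check_columns(notes, NOTE_FILE)

    diag: dict[str, list[str]] = {}
    diag_path = data_dir / DIAG_FILE
    if diag_path.exists():
        ddf = pd.read_csv(diag_path, dtype=str)
        _check_columns(ddf, DIAG_FILE)
        for sid, grp in ddf.groupby("STAY_ID"):
            diag[sid] = list(grp["ICD9_CODE"])

    labels: dict[str, int] = {}
    ages: dict[str, float] = {}
    label_path = data_dir / LABEL_FILE
    if label_path.exists():
        ldf = pd.read_csv(label_path, dtype={"STAY_ID": str})
        _check_columns(ldf, LABEL_FILE)
        labels = dict(zip(ldf["STAY_ID"], ldf["MORTALITY"].astype(int)))
        ages = dict(zip(ldf["STAY_ID"], ldf["AGE"].astype(float)))

    chronic_set = chronic_codes if chronic_codes is not None else load_chronic_codes()

    episodes: list[PatientEpisode] = []
    note_groups = {sid: grp for sid, grp in notes.groupby("STAY_ID")} if len(notes) else {}
    for sid, grp in chart.groupby("STAY_ID", sort=True):
        events = [
            RawEvent(sid, r.FEATURE, float(r.CHARTTIME_H), float(r.PARSED_VALUE))
            for r in grp.itertuples()
        ]
        ep_notes: list[RawNote] = []
        if sid in note_groups:
            for r in note_groups[sid].itertuples():
                text = str(r.TEXT)
                if text.strip():
                    ep_notes.append(RawNote(sid, float(r.CHARTTIME_H), str(r.CATEGORY), text))
        episodes.append(
            PatientEpisode(
                stay_id=sid,
                age=ages.get(sid, float("nan")),
                chronic=classify_chronic(diag.get(sid, []), chronic_set),
                events=events,
                notes=sorted(ep_notes, key=lambda n: n.chart_time),
                label=labels.get(sid),
            )
        )
    if stats is not None:
        stats.update(
            n_unknown_feature_rows=n_unknown,
            n_unparseable_rows=n_bad,
            n_episodes=len(episodes),
        )
    logger.info("assembled %d episodes", len(episodes))
    return episodes


def filter_cohort(
    episodes: list[PatientEpisode],
    min_age: float = 16.0,
    min_stay_h: float = 48.0,
) -> list[PatientEpisode]:
    """Keep adult stays (age >= 16, inclusive) spanning at least 48 h of
    measurements; order preserved, idempotent."""
    kept = [
        ep for ep in episodes
        if ep.age >= min_age and ep.max_event_time >= min_stay_h
    ]
    logger.info("cohort filter: %d -> %d episodes", len(episodes), len(kept))
    return kept


def select_notes(
    episode: PatientEpisode,
    window_h: float = 48.0,
    chronic: bool | None = None,
) -> NoteBundle:
    """Split an episode's notes into the observation-window set and, for
    chronic patients only, the K out-of-window history notes.

    Non-chronic patients contribute only notes charted inside the observation
    window [0, window_h]; chronic patients additionally contribute every note
    charted outside it (their pre-admission hospital record), ordered by
    chart time.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    if chronic is None:
        chronic = episode.chronic
    bundle = NoteBundle(stay_id=episode.stay_id)
    for note in sorted(episode.notes, key=lambda n: n.chart_time):
        if 0.0 <= note.chart_time <= window_h:
            bundle.window_notes.append(note)
        elif chronic:
            bundle.history_notes.append(note)
    return bundle
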