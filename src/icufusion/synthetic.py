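"""Reproducible synthetic ICU cohorts with the statistical structure the
multimodal mortality model assumes.

Restricted-access critical-care databases cannot ship with a package, so
every pipeline stage here is exercised on generated stays that emulate the
relevant structure of real EMR data: irregular hourly measurements of the 17
acute-physiology features over at least 48 h, free-text notes organized
under the standard history section headers, ICD-9 code lists that mark a
configurable fraction of patients as chronic, and an imbalanced binary
mortality label.

Signal is *planted*, and therefore recoverable by construction: positive
stays get a mean shift in a configurable subset of temporal features and
label-informative tokens inserted into a designated note section, so tests
can ask whether each model branch finds exactly the signal that was put in.
Temporal features are Gaussian random walks around clinically plausible
baselines; missingness is missing-completely-at-random.  Neither choice
claims physiological realism — see docs/methods.md for what that does and
does not validate.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ingest import CHART_FILE, DIAG_FILE, LABEL_FILE, NOTE_FILE
from .resources import canonical_sections, default_chronic_codes, feature_names, normal_values

DEFAULT_SIGNAL_TOKENS = ("sepsis", "hypotension", "vasopressors", "intubated", "oliguria")
DEFAULT_EFFECT_FEATURES = ("heart_rate", "respiratory_rate", "systolic_blood_pressure")
DEFAULT_SIGNAL_SECTION = "HISTORY OF PRESENT ILLNESS"

# categorical Glasgow-Coma-Scale responses emitted as free text, to exercise
# the ordinal lookup on ingest
_GCS_EYE = ("Spontaneously", "To Speech", "To Pain", "None")
_GCS_MOTOR = ("Obeys Commands", "Localizes Pain", "Flex-withdraws", "Abnormal Flexion",
              "Abnormal extension", "No response")
_GCS_VERBAL = ("Oriented", "Confused", "Inappropriate Words", "Incomprehensible sounds",
               "No Response")
_CATEGORICAL = {
    "gcs_eye_opening": _GCS_EYE,
    "gcs_motor_response": _GCS_MOTOR,
    "gcs_verbal_response": _GCS_VERBAL,
}

# (sd around baseline, plausible clip range)
_FEATURE_SPREAD: dict[str, tuple[float, tuple[float, float]]] = {
    "capillary_refill_rate": (0.3, (0.0, 1.0)),
    "diastolic_blood_pressure": (10.0, (20.0, 140.0)),
    "fraction_inspired_oxygen": (0.1, (0.21, 1.0)),
    "gcs_total": (2.0, (3.0, 15.0)),
    "glucose": (30.0, (40.0, 500.0)),
    "heart_rate": (12.0, (30.0, 200.0)),
    "height": (10.0, (140.0, 210.0)),
    "mean_blood_pressure": (11.0, (30.0, 160.0)),
    "oxygen_saturation": (2.5, (60.0, 100.0)),
    "respiratory_rate": (4.0, (5.0, 60.0)),
    "systolic_blood_pressure": (15.0, (50.0, 220.0)),
    "temperature": (0.7, (33.0, 42.0)),
    "weight": (12.0, (35.0, 200.0)),
    "ph": (0.07, (6.8, 7.8)),
}

_FILLER = (
    "patient", "stable", "admitted", "transferred", "monitor", "continue", "plan",
    "noted", "denies", "reports", "exam", "unremarkable", "tolerating", "diet",
    "ambulating", "review", "labs", "pending", "followup", "daily", "assessment",
    "afebrile", "alert", "responsive", "medications", "administered", "improved",
    "unchanged", "mild", "moderate", "chest", "abdomen", "extremities", "bilateral",
)

_ACUTE_CODES = ("486", "0389", "5849", "41071", "431", "5070", "9959", "4589")

_NOTE_CATEGORIES = ("Nursing", "Physician", "Radiology")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one generated cohort."""

    n_patients: int = 100
    prevalence: float = 0.13          # mortality rate; real cohorts are imbalanced
    chronic_fraction: float = 0.7     # chronic patients dominate real ICU cohorts
    signal_tokens: tuple[str, ...] = DEFAULT_SIGNAL_TOKENS
    signal_strength: float = 0.8      # P(signal token planted | positive note section)
    noise_vocab_size: int = 300
    missing_rate: float = 0.3         # MCAR per feature-hour cell
    seed: int = 0
    # where the planted signal lives
    temporal_effect: float = 1.0      # mean shift for positives, in baseline-sd units
    effect_features: tuple[str, ...] = DEFAULT_EFFECT_FEATURES
    signal_section: str = DEFAULT_SIGNAL_SECTION
    signal_location: str = "both"     # "window" | "history" | "both"

    def validate(self) -> None:
        if not (isinstance(self.n_patients, int) and self.n_patients >= 0):
            raise ValueError("n_patients must be a non-negative integer")
        for name in ("prevalence", "chronic_fraction", "signal_strength", "missing_rate"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")
        if not math.isfinite(self.temporal_effect):
            raise ValueError("temporal_effect must be finite")
        if self.noise_vocab_size < 1:
            raise ValueError("noise_vocab_size must be positive")
        if self.signal_location not in ("window", "history", "both"):
            raise ValueError("signal_location must be 'window', 'history' or 'both'")


@dataclass
class SyntheticPatient:
    stay_id: str
    age: int
    icd9_codes: list[str]
    label: int
    chronic: bool
    events: list[tuple[str, float, str]] = field(default_factory=list)   # (feature, hours, value-as-written)
    notes: list[tuple[float, str, str]] = field(default_factory=list)    # (hours, category, text)


def _noise_vocab(size: int) -> list[str]:
    vocab = list(_FILLER[: min(len(_FILLER), size)])
    i = 0
    while len(vocab) < size:
        vocab.append(f"obs{i:03d}")
        i += 1
    return vocab


def _walk(rng: np.random.Generator, n: int, base: float, sd: float, lo: float, hi: float) -> np.ndarray:
    steps = rng.normal(0.0, sd * 0.25, size=n)
    path = base + rng.normal(0.0, sd) + np.cumsum(steps)
    return np.clip(path, lo, hi)


def _section_text(rng: np.random.Generator, vocab: list[str], plant: list[str]) -> str:
    n_words = int(rng.integers(6, 16))
    words = list(rng.choice(vocab, size=n_words))
    for tok in plant:
        pos = int(rng.integers(0, len(words) + 1))
        words.insert(pos, tok)
    return " ".join(words)


def _make_note(
    rng: np.random.Generator,
    spec: CohortSpec,
    vocab: list[str],
    sections_pool: tuple[str, ...],
    plant_signal: bool,
) -> str:
    n_sections = int(rng.integers(2, 5))
    others = [s for s in sections_pool if s != spec.signal_section]
    chosen = list(rng.choice(others, size=min(n_sections, len(others)), replace=False))
    # the designated signal section is always present so planting has a target
    chosen.insert(int(rng.integers(0, len(chosen) + 1)), spec.signal_section)
    parts = []
    for name in chosen:
        plant: list[str] = []
        if plant_signal and name == spec.signal_section and rng.random() < spec.signal_strength:
            k = int(rng.integers(1, 4))
            plant = list(rng.choice(spec.signal_tokens, size=k))
        parts.append(f"{name}: {_section_text(rng, vocab, plant)}.")
    return "\n".join(parts)


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Draw ``spec.n_patients`` synthetic ICU stays; fixed seed, fixed output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vocab = _noise_vocab(spec.noise_vocab_size)
    chronic_pool = sorted(default_chronic_codes())
    sections_pool = tuple(s for s in canonical_sections() if s != "SERVICE")
    normals = normal_values()

    patients: list[SyntheticPatient] = []
    for i in range(spec.n_patients):
        label = int(rng.random() < spec.prevalence)
        chronic = bool(rng.random() < spec.chronic_fraction)
        age = int(rng.integers(18, 91))
        stay_h = float(rng.uniform(49.0, 72.0))

        codes = list(rng.choice(chronic_pool, size=int(rng.integers(1, 4)), replace=False)) \
            if chronic else list(rng.choice(_ACUTE_CODES, size=int(rng.integers(1, 3)), replace=False))

        events: list[tuple[str, float, str]] = []
        n_hours = int(math.floor(stay_h)) + 1
        for feat in feature_names():
            if feat in _CATEGORICAL:
                choices = _CATEGORICAL[feat]
                probs = np.ones(len(choices)) / len(choices)
                for t in range(n_hours):
                    if rng.random() < spec.missing_rate:
                        continue
                    val = str(rng.choice(choices, p=probs))
                    events.append((feat, t + float(rng.uniform(0, 1)), val))
                continue
            sd, (lo, hi) = _FEATURE_SPREAD[feat]
            shift = spec.temporal_effect * sd if (label == 1 and feat in spec.effect_features) else 0.0
            path = _walk(rng, n_hours, normals[feat] + shift, sd, lo, hi)
            for t in range(n_hours):
                if rng.random() < spec.missing_rate:
                    continue
                events.append((feat, t + float(rng.uniform(0, 1)), f"{path[t]:.4f}"))
        # guarantee the stay registers as >= 48 h of measurements
        events.append(("heart_rate", max(stay_h, 48.0),
                       f"{_walk(rng, 1, normals['heart_rate'], 12.0, 30.0, 200.0)[0]:.4f}"))

        plant_window = label == 1 and spec.signal_location in ("window", "both")
        plant_history = label == 1 and spec.signal_location in ("history", "both")

        notes: list[tuple[float, str, str]] = []
        for _ in range(int(rng.integers(1, 4))):
            t = float(rng.uniform(1.0, 47.0))
            cat = str(rng.choice(_NOTE_CATEGORIES))
            notes.append((t, cat, _make_note(rng, spec, vocab, sections_pool, plant_window)))
        if chronic:
            for _ in range(int(rng.integers(1, 3))):
                t = float(rng.uniform(-300.0, -10.0))
                notes.append((t, "History", _make_note(rng, spec, vocab, sections_pool, plant_history)))
        notes.sort(key=lambda n: n[0])

        patients.append(
            SyntheticPatient(
                stay_id=f"stay{i:05d}",
                age=age,
                icd9_codes=[str(c) for c in codes],
                label=label,
                chronic=chronic,
                events=events,
                notes=notes,
            )
        )
    return patients


def write_cohort(patients: list[SyntheticPatient], out_dir: str | Path) -> dict[str, Path]:
    """Emit the four-CSV cohort directory the ingest module reads."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {name: out_dir / name for name in (CHART_FILE, NOTE_FILE, DIAG_FILE, LABEL_FILE)}
        with open(paths[CHART_FILE], "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["STAY_ID", "FEATURE", "CHARTTIME_H", "VALUENUM"])
            for p in patients:
                for feat, t, val in p.events:
                    w.writerow([p.stay_id, feat, f"{t:.4f}", val])
        with open(paths[NOTE_FILE], "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["STAY_ID", "CHARTTIME_H", "CATEGORY", "TEXT"])
            for p in patients:
                for t, cat, text in p.notes:
                    w.writerow([p.stay_id, f"{t:.4f}", cat, text])
        with open(paths[DIAG_FILE], "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["STAY_ID", "ICD9_CODE"])
            for p in patients:
                for code in p.icd9_codes:
                    w.writerow([p.stay_id, code])
        with open(paths[LABEL_FILE], "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["STAY_ID", "MORTALITY", "AGE"])
            for p in patients:
                w.writerow([p.stay_id, p.label, p.age])
    except OSError as exc:
        raise OSError(f"failed writing cohort under {out_dir}: {exc}") from exc
    return paths
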