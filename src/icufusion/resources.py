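"""Loaders for the small plain-text/JSON tables shipped with the package:
the 17-feature list, clinical normal values, the Glasgow-Coma-Scale text
lookup, the note section-header lexicon, the stop-word list and the default
chronic ICD-9 code list."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path


def _data_path(name: str) -> Path:
    return Path(str(resources.files("icufusion").joinpath("data", name)))


@lru_cache(maxsize=None)
def feature_names() -> tuple[str, ...]:
    """The 17 acute-physiology features, in canonical column order."""
    payload = json.loads(_data_path("features.json").read_text())
    return tuple(payload["features"])


@lru_cache(maxsize=None)
def normal_values() -> dict[str, float]:
    return {k: float(v) for k, v in json.loads(_data_path("normal_values.json").read_text()).items()}


@lru_cache(maxsize=None)
def gcs_lookup() -> dict[str, float]:
    """Ordinal scores for categorical Glasgow-Coma-Scale responses (lowercased keys)."""
    return {k: float(v) for k, v in json.loads(_data_path("gcs_lookup.json").read_text()).items()}


@lru_cache(maxsize=None)
def section_lexicon() -> dict[str, str]:
    """Map every surface header form (lowercased, no colon) to its canonical name."""
    lex: dict[str, str] = {}
    for line in _data_path("section_headers.txt").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("|")]
        canonical = parts[0].upper()
        for surface in parts:
            lex[surface.lower()] = canonical
    return lex


@lru_cache(maxsize=None)
def canonical_sections() -> tuple[str, ...]:
    seen: list[str] = []
    for canon in section_lexicon().values():
        if canon not in seen:
            seen.append(canon)
    return tuple(seen)


def _read_list(path: Path) -> frozenset[str]:
    out = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


@lru_cache(maxsize=None)
def stop_words() -> frozenset[str]:
    return _read_list(_data_path("stopwords.txt"))


@lru_cache(maxsize=None)
def default_chronic_codes() -> frozenset[str]:
    return _read_list(_data_path("chronic_icd9_codes.txt"))


def load_chronic_codes(path: str | Path | None = None) -> frozenset[str]:
    """Chronic ICD-9 code set: the shipped default or a one-code-per-line file."""
    if path is None:
        return default_chronic_codes()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"chronic code list not found: {path}")
    return _read_list(path)
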