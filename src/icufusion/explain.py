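"""Interpretability: section-importance scores and token heatmaps.

A section's importance is the sum of the attention weights of its
non-stop-word tokens, normalized by the total attention on non-stop-word
content — so a patient's section scores sum to one and are invariant to any
rescaling of the attention vector.  Stop words carry no importance by
definition.  Heatmaps render each token with a blue background whose
intensity is the max-normalized attention weight, and each section header
shaded by its section score.
"""

from __future__ import annotations

import html
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .text_prep import NoteSection, TokenSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SectionScore:
    section_name: str
    score: float


def section_importance(
    alpha: np.ndarray,
    sections: list[NoteSection],
    stopword_mask: np.ndarray,
) -> list[SectionScore]:
    """One score per section *name* (spans of the same section accumulate).

    Returns an empty list (with a warning) when no non-stop-word content
    carries attention, e.g. an all-stop-word note.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    keep = ~np.asarray(stopword_mask, dtype=bool)
    weights = alpha * keep[: alpha.shape[0]]
    totals: dict[str, float] = {}
    for s in sections:
        totals[s.name] = totals.get(s.name, 0.0) + float(weights[s.start: s.end].sum())
    denom = sum(totals.values())
    if denom <= 0.0:
        logger.warning("section importance undefined: no attended non-stop-word content")
        return []
    return [SectionScore(name, tot / denom) for name, tot in totals.items()]


def aggregate_section_scores(
    per_patient: "list[list[SectionScore]]", reduce: str = "median",
) -> dict[str, float]:
    """Cohort-level summary of per-patient section scores (absent sections
    do not contribute zeros)."""
    pools: dict[str, list[float]] = {}
    for scores in per_patient:
        for s in scores:
            pools.setdefault(s.section_name, []).append(s.score)
    fn = np.median if reduce == "median" else np.mean
    return {name: float(fn(vals)) for name, vals in pools.items()}


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Attention heatmap</title>
<style>
body {{ font-family: sans-serif; max-width: 60em; margin: 2em auto; line-height: 1.9; }}
.tok {{ padding: 1px 2px; border-radius: 3px; }}
.hdr {{ font-weight: bold; display: block; margin-top: 0.8em; padding: 2px 4px; }}
</style></head><body>
<h1>Token attention and section importance</h1>
{body}
</body></html>
"""


def export_heatmap(
    seq: TokenSequence,
    alpha: np.ndarray,
    section_scores: list[SectionScore],
    out_path: str | Path,
) -> Path:
    """Write a standalone HTML heatmap; returns the output path.

    Token shading is proportional to alpha (max-normalized over non-stop-word
    content); stop words are unshaded.  Machine-readable ``data-alpha`` /
    ``data-score`` attributes support downstream parsing.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    n = seq.content_length
    keep = ~seq.stopword_mask[:n]
    amax = float((alpha[:n] * keep).max()) if n else 0.0
    score_by_name = {s.section_name: s.score for s in section_scores}

    chunks: list[str] = []
    for sec in seq.sections:
        score = score_by_name.get(sec.name, 0.0)
        chunks.append(
            f'<span class="hdr" data-score="{score:.6f}" '
            f'style="background: rgba(30, 64, 255, {0.8 * score:.6f})">'
            f"{html.escape(sec.name)} (score {score:.3f})</span>"
        )
        for i in range(sec.start, min(sec.end, n)):
            tok = html.escape(seq.tokens[i])
            if seq.stopword_mask[i]:
                chunks.append(f'<span class="tok">{tok}</span>')
                continue
            a = float(alpha[i])
            intensity = a / amax if amax > 0 else 0.0
            chunks.append(
                f'<span class="tok" data-alpha="{a:.8f}" '
                f'style="background: rgba(30, 64, 255, {intensity:.6f})">{tok}</span>'
            )
    out_path = Path(out_path)
    try:
        out_path.write_text(_PAGE.format(body="\n".join(chunks)))
    except OSError as exc:
        raise OSError(f"failed writing heatmap to {out_path}: {exc}") from exc
    return out_path
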