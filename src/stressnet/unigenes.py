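"""Unigene selection from assembled transcripts.

A de-novo assembly groups transcripts into components (putative genes)
with several isoforms each. One representative transcript — the unigene —
is chosen per component by maximising the score ``length x isoform
percent``, after dropping transcripts below a minimum length (300 bp by
default, the assembler's minimum contig length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript with its component and expression share."""

    transcript_id: str
    component_id: str
    length: int
    isoform_pct: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0 <= self.isoform_pct <= 100:
            raise ValueError("isoform_pct must be in [0, 100]")


def select_unigenes(
    transcripts: Iterable[TranscriptRecord], min_length: int = 300
) -> list[str]:
    """Pick one transcript per component by ``length * isoform_pct``.

    Transcripts shorter than ``min_length`` are excluded before scoring.
    Ties go to the longer transcript, then the lexicographically smaller
    id. Components left with no transcript yield no unigene (logged).
    Returns selected ids ordered by component id.
    """
    by_component: dict[str, list[TranscriptRecord]] = {}
    empty_components: set[str] = set()
    for rec in transcripts:
        if rec.length < min_length:
            empty_components.add(rec.component_id)
            continue
        by_component.setdefault(rec.component_id, []).append(rec)
    for comp in sorted(empty_components - set(by_component)):
        logger.warning("component %s: all transcripts below %d bp", comp,
                       min_length)
    selected = []
    for comp in sorted(by_component):
        best = max(
            by_component[comp],
            key=lambda r: (
                r.length * r.isoform_pct, r.length,
                _neg_lex(r.transcript_id),
            ),
        )
        selected.append(best.transcript_id)
    return selected


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def read_transcript_table(path) -> list[TranscriptRecord]:
    """TSV columns: transcript_id, component_id, length, isoform_pct."""
    df = pd.read_csv(path, sep="\t", dtype={
        "transcript_id": str, "component_id": str,
    })
    return [
        TranscriptRecord(
            r.transcript_id, r.component_id, int(r.length),
            float(r.isoform_pct),
        )
        for r in df.itertuples()
    ]
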