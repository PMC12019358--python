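"""Note-level extraction of (stopped, started, reason) triples.

The extractor contract is the pluggable seam of the pipeline: anything with
an ``extract(note_id, text) -> ExtractionResult`` method can stand behind
it (an LLM adapter, for instance). The shipped reference implementation is
a deterministic cue-phrase scanner: it looks for stop cues ("stopped",
"discontinu...", "removal of", "came off") and start cues ("started",
"starting", "switching to", "begin", "placed") adjacent to a drug or
modality mention, and takes the clause after a causal cue ("because",
"due to", "reports") as the reason. Extracted drug text is normalised to
the six modalities through the same pattern table the cohort stage uses;
deidentification placeholders therefore normalise to none, mirroring the
failure mode redaction induces in real notes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol

import pandas as pd

from .cohort import SwitchEvent
from .patterns import Modality, PatternTable, load_default_table

__all__ = [
    "ExtractionResult",
    "SilverLabel",
    "Extractor",
    "RuleBasedExtractor",
    "normalize_to_modality",
    "derive_silver_labels",
    "extract_all",
    "results_frame",
    "silver_frame",
]

STOP_CUES = ("stopped", "discontinu", "removal of", "came off")
START_CUES = ("started", "starting", "switching to", "begin", "placed")
REASON_CUES = ("because of", "because", "due to", "reports")


@dataclass(frozen=True)
class ExtractionResult:
    note_id: str
    stopped: Modality | None
    started: Modality | None
    reason: str | None
    raw_output: str = ""


@dataclass(frozen=True)
class SilverLabel:
    """Weak started/stopped label derived purely from structured orders."""

    note_id: str
    stopped: Modality | None
    started: Modality | None


class Extractor(Protocol):
    def extract(self, note_id: str, text: str) -> ExtractionResult: ...


def normalize_to_modality(text: str, table: PatternTable | None = None) -> Modality | None:
    """Map extracted drug text to a modality; unmatched text gives None."""
    if not text or not text.strip():
        return None
    table = table or load_default_table()
    result = table.map(text)
    return result if isinstance(result, Modality) else None


class RuleBasedExtractor:
    """Deterministic cue-phrase reference extractor.

    ``window`` is how many characters after a cue are scanned for a drug
    mention. When several cues of the same kind resolve to a modality, the
    last mention wins (``take_last=True``, the default) — clinical notes
    typically state the final plan at the end.
    """

    def __init__(
        self,
        table: PatternTable | None = None,
        *,
        window: int = 60,
        take_last: bool = True,
    ):
        self.table = table or load_default_table()
        self.window = window
        self.take_last = take_last
        self._stop_re = re.compile("|".join(re.escape(c) for c in STOP_CUES), re.IGNORECASE)
        self._start_re = re.compile("|".join(re.escape(c) for c in START_CUES), re.IGNORECASE)
        self._reason_re = re.compile(
            r"(?:%s)\s+([^.;\n]+)" % "|".join(re.escape(c) for c in REASON_CUES), re.IGNORECASE
        )

    def _scan(self, text: str, cue_re: re.Pattern) -> Modality | None:
        hits = []
        for m in cue_re.finditer(text):
            # nearest mention after the cue wins; if nothing follows within
            # the window, fall back to the text just before the cue
            # ("Mirena placed today").
            found = self.table.find_first(text[m.end() : m.end() + self.window])
            if found is None or not isinstance(found[1], Modality):
                back = text[max(0, m.start() - self.window) : m.start()]
                found = self.table.find_last(back)
            if found is not None and isinstance(found[1], Modality):
                hits.append(found[1])
        if not hits:
            return None
        return hits[-1] if self.take_last else hits[0]

    def extract(self, note_id: str, text: str) -> ExtractionResult:
        if not text:
            raise ValueError("note text must be non-empty")
        stopped = self._scan(text, self._stop_re)
        started = self._scan(text, self._start_re)
        reason = None
        m = self._reason_re.search(text)
        if m:
            reason = m.group(1).strip()
        return ExtractionResult(
            note_id=note_id,
            stopped=stopped,
            started=started,
            reason=reason,
            raw_output=f"stopped={stopped}; started={started}; reason={reason}",
        )


def extract_all(
    notes: pd.DataFrame, extractor: Extractor | None = None, note_ids=None
) -> list[ExtractionResult]:
    """Run an extractor over a note table (optionally restricted to ids)."""
    extractor = extractor or RuleBasedExtractor()
    df = notes if note_ids is None else notes[notes["note_id"].isin(set(note_ids))]
    return [extractor.extract(row.note_id, row.text) for row in df.itertuples(index=False)]


def derive_silver_labels(
    timeline, event: SwitchEvent, *, tie_break: str = "alphabetical"
) -> SilverLabel:
    """Silver label for one switch event from its structured set differences.

    When a set difference holds more than one modality the alphabetically
    first modality name is taken (documented tie-break).
    """
    entries = {e.encounter_date for e in timeline}
    if event.prev_encounter_date not in entries or event.new_encounter_date not in entries:
        raise ValueError(
            f"event encounters ({event.prev_encounter_date}, {event.new_encounter_date}) "
            "not found in timeline"
        )

    def pick(mods: frozenset) -> Modality | None:
        if not mods:
            return None
        return sorted(mods, key=lambda m: m.value)[0]

    return SilverLabel(note_id=event.note_id or "", stopped=pick(event.stopped), started=pick(event.started))


def results_frame(results: list[ExtractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "note_id": r.note_id,
                "stopped": r.stopped.value if r.stopped else "",
                "started": r.started.value if r.started else "",
                "reason": r.reason or "",
            }
            for r in results
        ],
        columns=["note_id", "stopped", "started", "reason"],
    )


def silver_frame(labels: list[SilverLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "note_id": s.note_id,
                "stopped": s.stopped.value if s.stopped else "",
                "started": s.started.value if s.started else "",
            }
            for s in labels
        ],
        columns=["note_id", "stopped", "started"],
    )
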