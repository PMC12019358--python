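"""Cohort construction and contraceptive-switch detection.

Mirrors a study-flow (attrition) pipeline over structured medication
orders: select contraceptive orders by therapeutic class, map each product
to one of six modalities, then apply a fixed filter sequence — exclusion
patterns, missing start dates, six-month follow-up, missing/short notes,
per-encounter deduplication — while recording exactly what each step
removed. A switch is a difference between the modality *sets* of a
patient's consecutive encounters, ordered by prescription start date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .patterns import EXCLUDED, UNMAPPED, Modality, PatternTable, load_default_table

__all__ = [
    "SwitchEvent",
    "TimelineEntry",
    "AttritionReport",
    "map_to_modality",
    "apply_filters",
    "build_timelines",
    "detect_switches",
    "find_switches",
    "switch_matrix",
    "demographic_comparison",
    "FOLLOWUP_DAYS",
]

log = logging.getLogger(__name__)

FOLLOWUP_DAYS = 183  # "6 months" as a fixed day count

ORDER_COLUMNS = ["patient_id", "encounter_date", "start_date", "drug_name", "therapeutic_class"]
NOTE_COLUMNS = ["note_id", "patient_id", "encounter_date", "text"]


@dataclass(frozen=True)
class SwitchEvent:
    """A modality change between two consecutive encounters of one patient."""

    patient_id: str
    prev_encounter_date: int
    new_encounter_date: int
    stopped: frozenset  # of Modality
    started: frozenset  # of Modality
    note_id: str | None

    def __post_init__(self):
        if self.stopped & self.started:
            raise ValueError("stopped and started modality sets must be disjoint")
        if not (self.prev_encounter_date < self.new_encounter_date):
            raise ValueError("prev_encounter_date must precede new_encounter_date")


@dataclass(frozen=True)
class TimelineEntry:
    start_date: float
    encounter_date: int
    modalities: frozenset
    note_id: str | None = None


@dataclass
class AttritionReport:
    """Ordered (filter, removed, remaining records, remaining patients) rows."""

    rows: list = field(default_factory=list)

    def add(self, name: str, removed: int, remaining: int, patients: int) -> None:
        if self.rows and remaining != self.rows[-1][2] - removed:
            raise ValueError("attrition conservation violated")
        self.rows.append((name, int(removed), int(remaining), int(patients)))

    def removed(self) -> dict:
        return {name: rem for name, rem, _, _ in self.rows if name != "initial"}

    def to_records(self) -> list[dict]:
        return [
            {"filter": n, "removed": r, "records_remaining": q, "patients_remaining": p}
            for n, r, q, p in self.rows
        ]


def map_to_modality(drug_name: str, therapeutic_class: str = "", table: PatternTable | None = None):
    """Map one order to a :class:`Modality`, ``EXCLUDED`` or ``UNMAPPED``."""
    table = table or load_default_table()
    return table.map(drug_name)


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing column(s): {', '.join(missing)}")


def _link_notes(notes: pd.DataFrame, token_threshold: int) -> pd.DataFrame:
    """Qualifying note (longest with > threshold tokens) per (patient, encounter)."""
    nt = notes.copy()
    nt["_tokens"] = nt["text"].str.split().str.len()
    nt = nt[nt["_tokens"] > token_threshold]
    nt = nt.sort_values(["patient_id", "encounter_date", "_tokens", "note_id"], kind="stable")
    best = nt.groupby(["patient_id", "encounter_date"], as_index=False).last()
    return best[["patient_id", "encounter_date", "note_id"]]


def apply_filters(
    orders: pd.DataFrame,
    notes: pd.DataFrame,
    encounters: pd.DataFrame | None = None,
    *,
    table: PatternTable | None = None,
    followup_anchor: str = "last",
    followup_days: int = FOLLOWUP_DAYS,
    token_threshold: int = 50,
) -> tuple[pd.DataFrame, AttritionReport]:
    """Run the attrition pipeline; return surviving orders and the report.

    Surviving orders carry a resolved ``modality`` and linked ``note_id``.
    ``encounters`` (patient_id, encounter_date) supplies follow-up evidence
    beyond the order and note tables; by default note encounter dates are
    used. ``followup_anchor`` picks whether the six-month window is anchored
    at the patient's last (default) or first contraceptive order.
    """
    _require_columns(orders, ORDER_COLUMNS, "orders")
    _require_columns(notes, NOTE_COLUMNS, "notes")
    if followup_anchor not in ("first", "last"):
        raise ValueError("followup_anchor must be 'first' or 'last'")
    table = table or load_default_table()

    df = orders.copy().reset_index(drop=True)
    report = AttritionReport()
    report.add("initial", 0, len(df), df["patient_id"].nunique())

    # 1. therapeutic-class selection
    is_contra = df["therapeutic_class"].str.contains("contracept", case=False, na=False)
    df = df[is_contra]
    report.add("non_contraceptive_class", int((~is_contra).sum()), len(df), df["patient_id"].nunique())

    # 2. pattern mapping: exclusions (non-drug/emergency) and unmapped names
    mapped = df["drug_name"].map(table.map)
    n_unmapped = int((mapped == UNMAPPED).sum())
    if n_unmapped:
        log.warning("dropping %d orders with unmapped drug names", n_unmapped)
    keep = mapped.apply(lambda m: isinstance(m, Modality))
    df = df[keep].assign(modality=mapped[keep])
    report.add("excluded_or_unmapped", int((~keep).sum()), len(df), df["patient_id"].nunique())

    # 3. missing start date
    has_start = df["start_date"].notna()
    df = df[has_start]
    report.add("missing_start_date", int((~has_start).sum()), len(df), df["patient_id"].nunique())

    # 4. six-month follow-up
    enc = pd.concat(
        [
            df[["patient_id", "encounter_date"]],
            notes[["patient_id", "encounter_date"]],
        ]
        + ([encounters[["patient_id", "encounter_date"]]] if encounters is not None else [])
    )
    last_enc = enc.groupby("patient_id")["encounter_date"].max()
    agg = "max" if followup_anchor == "last" else "min"
    anchor = df.groupby("patient_id")["encounter_date"].agg(agg)
    ok_patients = anchor.index[last_enc.reindex(anchor.index) >= anchor + followup_days]
    in_followup = df["patient_id"].isin(ok_patients)
    df = df[in_followup]
    report.add("no_followup", int((~in_followup).sum()), len(df), df["patient_id"].nunique())

    # 5. missing or short associated note
    linked = _link_notes(notes, token_threshold)
    df = df.merge(linked, on=["patient_id", "encounter_date"], how="left")
    has_note = df["note_id"].notna()
    df = df[has_note]
    report.add("missing_or_short_note", int((~has_note).sum()), len(df), df["patient_id"].nunique())

    # 6. duplicate orders per encounter date
    dup = df.duplicated(subset=["patient_id", "encounter_date", "modality"], keep="first")
    df = df[~dup]
    report.add("duplicate", int(dup.sum()), len(df), df["patient_id"].nunique())

    return df.reset_index(drop=True), report


def build_timelines(filtered_orders: pd.DataFrame) -> dict[str, list[TimelineEntry]]:
    """Group surviving orders into per-patient encounter timelines.

    Encounters are ordered by documented start date (ties broken by
    encounter date then modality name, stably); each entry carries the
    modality set prescribed at that encounter and its linked note.
    """
    timelines: dict[str, list[TimelineEntry]] = {}
    df = filtered_orders.sort_values(
        ["patient_id", "start_date", "encounter_date", "modality"],
        kind="stable",
        key=lambda s: s.map(lambda v: v.value) if s.name == "modality" else s,
    )
    for pid, grp in df.groupby("patient_id", sort=True):
        entries = []
        for enc_date, sub in grp.groupby("encounter_date", sort=True):
            entries.append(
                TimelineEntry(
                    start_date=float(sub["start_date"].min()),
                    encounter_date=int(enc_date),
                    modalities=frozenset(sub["modality"]),
                    note_id=sub["note_id"].iloc[0],
                )
            )
        entries.sort(key=lambda e: (e.start_date, e.encounter_date))
        timelines[pid] = entries
    return timelines


def detect_switches(timeline: list[TimelineEntry], patient_id: str = "") -> list[SwitchEvent]:
    """Emit a SwitchEvent for every consecutive encounter pair whose
    modality sets differ; stopped = previous - current, started =
    current - previous. Input must be sorted by start date ascending."""
    starts = [e.start_date for e in timeline]
    if starts != sorted(starts):
        raise ValueError("timeline must be sorted by start date ascending")
    if any(not e.modalities for e in timeline):
        raise ValueError("timeline entries must have non-empty modality sets")
    events = []
    for prev, cur in zip(timeline, timeline[1:]):
        if prev.modalities != cur.modalities:
            events.append(
                SwitchEvent(
                    patient_id=patient_id,
                    prev_encounter_date=prev.encounter_date,
                    new_encounter_date=cur.encounter_date,
                    stopped=frozenset(prev.modalities - cur.modalities),
                    started=frozenset(cur.modalities - prev.modalities),
                    note_id=cur.note_id,
                )
            )
    return events


def find_switches(filtered_orders: pd.DataFrame) -> list[SwitchEvent]:
    """Convenience: timelines + detection over a filtered order table."""
    events: list[SwitchEvent] = []
    for pid, timeline in build_timelines(filtered_orders).items():
        events.extend(detect_switches(timeline, patient_id=pid))
    return events


def switch_matrix(events: list[SwitchEvent]) -> pd.DataFrame:
    """Stopped-modality x started-modality counts over single-modality moves.

    Multi-modality set differences contribute one count per (stopped,
    started) pair in their cross product.
    """
    names = [m.value for m in Modality]
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for ev in events:
        for s in ev.stopped:
            for t in ev.started:
                mat.loc[s.value, t.value] += 1
    mat.index.name = "stopped"
    mat.columns.name = "started"
    return mat


def events_frame(events: list[SwitchEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": ev.patient_id,
                "prev_encounter_date": ev.prev_encounter_date,
                "new_encounter_date": ev.new_encounter_date,
                "stopped": "|".join(sorted(m.value for m in ev.stopped)),
                "started": "|".join(sorted(m.value for m in ev.started)),
                "note_id": ev.note_id or "",
            }
            for ev in events
        ],
        columns=[
            "patient_id",
            "prev_encounter_date",
            "new_encounter_date",
            "stopped",
            "started",
            "note_id",
        ],
    )


def demographic_comparison(
    switch_demo: pd.DataFrame,
    noswitch_demo: pd.DataFrame,
    *,
    continuous: tuple = ("age_first_rx",),
    categorical: tuple = ("race_ethnicity", "preferred_language"),
) -> dict:
    """Table-1-style comparison of switch vs no-switch cohorts.

    Continuous variables: mean (SD) per group with a two-sided t test.
    Categorical variables: counts and percentages among non-missing with a
    chi-square test of homogeneity (no continuity correction, so the
    statistic equals the textbook sum of (O-E)^2/E). A variable taking a
    single value in both groups is marked not applicable.
    """
    if switch_demo.empty or noswitch_demo.empty:
        raise ValueError("both cohorts must be non-empty")
    out: dict = {"n_switch": len(switch_demo), "n_noswitch": len(noswitch_demo)}
    for var in continuous:
        a = switch_demo[var].dropna().to_numpy(float)
        b = noswitch_demo[var].dropna().to_numpy(float)
        t, p = stats.ttest_ind(a, b)
        out[var] = {
            "switch_mean": float(np.mean(a)),
            "switch_sd": float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"),
            "noswitch_mean": float(np.mean(b)),
            "noswitch_sd": float(np.std(b, ddof=1)) if len(b) > 1 else float("nan"),
            "t_statistic": float(t),
            "p_value": float(p),
            "test": "two-sided t",
        }
    for var in categorical:
        a = switch_demo[var].dropna()
        b = noswitch_demo[var].dropna()
        labels = sorted(set(a) | set(b))
        counts = pd.DataFrame(
            {
                "switch": a.value_counts().reindex(labels, fill_value=0),
                "noswitch": b.value_counts().reindex(labels, fill_value=0),
            }
        )
        pct = counts / counts.sum() * 100.0
        entry = {
            "labels": labels,
            "switch_counts": counts["switch"].tolist(),
            "noswitch_counts": counts["noswitch"].tolist(),
            "switch_pct": [round(v, 1) for v in pct["switch"]],
            "noswitch_pct": [round(v, 1) for v in pct["noswitch"]],
            "n_missing_switch": int(switch_demo[var].isna().sum()),
            "n_missing_noswitch": int(noswitch_demo[var].isna().sum()),
        }
        if len(labels) < 2:
            entry.update({"chi2": None, "p_value": None, "test": "not applicable"})
        else:
            chi2, p, dof, _ = stats.chi2_contingency(counts.T.to_numpy(), correction=False)
            entry.update({"chi2": float(chi2), "p_value": float(p), "dof": int(dof), "test": "chi-square"})
        out[var] = entry
    return out
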