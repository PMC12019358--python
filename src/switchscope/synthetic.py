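"""Synthetic EHR generator with planted contraceptive-switch dynamics.

Emits the three tables the analysis pipeline consumes — medication orders,
demographics, and clinical notes — together with note-level gold labels and
an exact bookkeeping summary of everything that was planted: how many
switches exist, how many records each cohort filter should remove, and how
many switch notes fall in each (reason topic, patient subgroup) cell.

The generator writes documentation noise deliberately: orders with missing
start dates, duplicate orders at an encounter date, orders without an
associated note, notes at or below the short-note token threshold, patients
lost to follow-up, emergency-contraceptive and non-contraceptive distractor
rows, and deidentification-style redaction of brand names that resemble
person names (e.g. "Camila", "Heather"). Each noise record is constructed
so that exactly one downstream filter removes it, which makes the planted
summary an exact oracle for the attrition report.

Dates are integer day offsets from a synthetic epoch; six months is fixed
at 183 days.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import age_bin
from .patterns import Modality

__all__ = [
    "Product",
    "ReasonTopic",
    "NoiseRates",
    "EnrichmentPlanItem",
    "SimConfig",
    "GoldRecord",
    "SyntheticCohort",
    "generate_cohort",
    "generate_note",
    "simulate_topic_subgroups",
    "DEFAULT_TOPICS",
    "PRODUCTS",
]

FOLLOWUP_DAYS = 183  # "6 months"
REDACTION_PLACEHOLDER = "***"


@dataclass(frozen=True)
class Product:
    """A prescribable contraceptive product.

    ``order_name`` is the structured-order product string; ``mention`` is how
    clinicians refer to it in note text. ``person_like`` marks brand names
    that collide with common first names and are targets of deidentification
    redaction.
    """

    order_name: str
    mention: str
    modality: Modality
    person_like: bool = False


PRODUCTS: dict[Modality, list[Product]] = {
    Modality.ORAL: [
        Product("norethindrone 0.35 mg oral tablet (Camila)", "Camila", Modality.ORAL, True),
        Product("norethindrone 0.35 mg oral tablet (Heather)", "Heather", Modality.ORAL, True),
        Product("norgestimate-ethinyl estradiol oral tablet (Sprintec)", "Sprintec", Modality.ORAL),
        Product("drospirenone-ethinyl estradiol 3-0.02 mg oral tablet (Yaz)", "Yaz", Modality.ORAL),
    ],
    Modality.IMPLANT: [
        Product("etonogestrel 68 mg subdermal implant (Nexplanon)", "Nexplanon", Modality.IMPLANT),
    ],
    Modality.IUD: [
        Product("levonorgestrel 52 mg intrauterine device (Mirena)", "Mirena", Modality.IUD),
        Product("copper T 380A intrauterine device (Paragard)", "Paragard", Modality.IUD),
    ],
    Modality.INJECTABLE: [
        Product(
            "medroxyprogesterone acetate 150 mg/mL intramuscular injection (Depo-Provera)",
            "Depo-Provera",
            Modality.INJECTABLE,
        ),
    ],
    Modality.TRANSDERMAL: [
        Product("norelgestromin-ethinyl estradiol transdermal patch (Xulane)", "Xulane", Modality.TRANSDERMAL),
    ],
    Modality.INTRAVAGINAL: [
        Product("etonogestrel-ethinyl estradiol vaginal ring (NuvaRing)", "NuvaRing", Modality.INTRAVAGINAL),
    ],
}

EMERGENCY_PRODUCT = "levonorgestrel 1.5 mg oral tablet (emergency contraception)"
DISTRACTOR_PRODUCTS = [
    ("acetaminophen 500 mg oral tablet", "Analgesics"),
    ("sertraline 50 mg oral tablet", "Antidepressants"),
    ("loratadine 10 mg oral tablet", "Antihistamines"),
]
CONTRACEPTIVE_CLASS = "CONTRACEPTIVES"


# Shared low-salience modifier vocabulary. Sampled phrases interleave a
# topic's core wording with a random handful of these, which gives the
# reason corpus the continuous within-topic variation real free text has
# (no two extracted rationales are written identically) while the topic's
# core tokens stay fixed.
MODIFIER_POOL: tuple[str, ...] = (
    "mild", "recurrent", "frequent", "ongoing", "persistent", "intermittent",
    "noticeable", "significant", "troublesome", "worsening", "episodic",
    "bothersome", "chronic", "occasional", "severe", "moderate", "constant",
    "fluctuating", "disruptive", "recent", "gradual", "marked", "notably",
    "increasingly", "newly", "steadily", "distinctly", "progressively",
    "somewhat", "clearly",
)


@dataclass(frozen=True)
class ReasonTopic:
    """A switching-rationale topic with its core phrase pool.

    ``phrases`` are core wordings sharing the topic's vocabulary;
    :meth:`sample` perturbs one with modifiers from the shared pool.
    ``applies_to`` restricts the topic to switches stopping one of the
    given modalities (device-removal reasons make no sense for pills);
    ``None`` means any modality.
    """

    name: str
    phrases: tuple[str, ...]
    adverse_event: bool
    applies_to: frozenset | None = None

    def sample(self, rng: np.random.Generator) -> str:
        words = self.phrases[int(rng.integers(len(self.phrases)))].split()
        k = int(rng.integers(2, 8))
        for m in rng.choice(MODIFIER_POOL, size=k, replace=False):
            words.insert(int(rng.integers(0, len(words) + 1)), str(m))
        return " ".join(words)


def _topic(name, phrases, ae, applies=None):
    return ReasonTopic(name, tuple(phrases), ae, frozenset(applies) if applies else None)


# Core wordings within a topic are bag-of-words permutations of each other,
# and topic vocabularies are pairwise (near-)disjoint.
DEFAULT_TOPICS: tuple[ReasonTopic, ...] = (
    _topic(
        "irregular_bleeding",
        [
            "spotting and irregular breakthrough bleeding between periods",
            "irregular bleeding and breakthrough spotting between periods",
        ],
        True,
    ),
    _topic(
        "patient_preference",
        [
            "personal preference for a different contraceptive option or method",
            "preference for a different personal contraceptive method or option",
        ],
        False,
    ),
    _topic(
        "missed_pills",
        [
            "difficulty remembering to take the daily pill dose",
            "trouble remembering the daily pill dose to take",
        ],
        False,
        [Modality.ORAL],
    ),
    _topic(
        "skin_irritation",
        [
            "skin irritation and itchy rash at the application site",
            "itchy skin rash and irritation at the application site",
        ],
        True,
        [Modality.TRANSDERMAL],
    ),
    _topic(
        "iud_malposition",
        [
            "malpositioned device displacement seen on pelvic ultrasound",
            "pelvic ultrasound showed malpositioned device displacement",
        ],
        True,
        [Modality.IUD],
    ),
    _topic(
        "weight_mood",
        [
            "unwanted weight gain with low mood and mood swings",
            "low mood and mood swings with unwanted weight gain",
        ],
        True,
    ),
    _topic(
        "menstrual_pain",
        [
            "painful cramping and pelvic pain during her menses",
            "pelvic pain and painful cramping during her menses",
        ],
        True,
    ),
    _topic(
        "insurance_coverage",
        [
            "insurance plan coverage denied for the prescribed refill",
            "coverage denied by the insurance plan for the prescribed refill",
        ],
        False,
    ),
    _topic(
        "implant_removal",
        [
            "requests elective arm device explant at the three year mark",
            "elective explant of the arm device requests at the three year mark",
        ],
        True,
        [Modality.IMPLANT],
    ),
)

# First-prescribed modality shares pooled over the switch and no-switch
# columns of the study's demographic table.
DEFAULT_MODALITY_START = {
    Modality.ORAL: 0.6404,
    Modality.INTRAVAGINAL: 0.1251,
    Modality.IUD: 0.0763,
    Modality.INJECTABLE: 0.0604,
    Modality.IMPLANT: 0.0550,
    Modality.TRANSDERMAL: 0.0428,
}

DEFAULT_RACE = {
    "White": 0.4406,
    "Asian": 0.1996,
    "Latinx": 0.1549,
    "Black or African American": 0.0919,
    "Other": 0.0808,
    "Multi-Race/Ethnicity": 0.0322,
}

DEFAULT_LANGUAGE = {"English": 0.9690, "Spanish": 0.0170, "Other": 0.0140}


@dataclass(frozen=True)
class NoiseRates:
    """Documentation-noise rates, each a fraction of the clean record count."""

    missing_start_date: float = 0.10
    missing_note: float = 0.12
    duplicate_order: float = 0.50
    short_note: float = 0.05
    lost_to_followup: float = 0.15
    excluded_order: float = 0.05
    distractor_order: float = 0.10
    redacted_brand: float = 0.02
    # Fraction of switch notes that never mention the drug being stopped:
    # the structured orders still record the stop, so silver labels disagree
    # with what a reader of the note (the gold label) can know.
    undocumented_stop: float = 0.10

    def all_zero(self) -> "NoiseRates":
        return NoiseRates(**{f.name: 0.0 for f in dataclasses.fields(self)})

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"noise rate {f.name}={v} outside [0, 1]")


@dataclass(frozen=True)
class EnrichmentPlanItem:
    """Multiply a topic's sampling weight by ``factor`` inside one subgroup."""

    topic: str
    subgroup: str
    factor: float
    axis: str = "race"  # "race" or "age"


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the real study's reported marginals at desk scale: a
    7.6% per-patient switch rate, the pooled first-prescribed modality
    distribution, the pooled race/ethnicity and language distributions, and
    ages drawn from the reported per-group normals (switchers 25.9 +/- 7.7
    years, non-switchers 29.1 +/- 8.4).
    """

    n_patients: int = 2000
    switch_probability: float = 0.076
    modality_start_distribution: dict = field(default_factory=lambda: dict(DEFAULT_MODALITY_START))
    reason_topic_catalog: tuple = DEFAULT_TOPICS
    subgroup_enrichment_plan: tuple = ()
    noise_rates: NoiseRates = field(default_factory=NoiseRates)
    seed: int = 0

    race_distribution: dict = field(default_factory=lambda: dict(DEFAULT_RACE))
    language_distribution: dict = field(default_factory=lambda: dict(DEFAULT_LANGUAGE))
    age_mean_switch: float = 25.9
    age_sd_switch: float = 7.7
    age_mean_noswitch: float = 29.1
    age_sd_noswitch: float = 8.4
    # Mean time from one encounter to the next switch encounter; the study
    # reports mean time-to-first-switch of 39.1 months (~1190 days) but at
    # desk scale the absolute gap only has to order encounters, so a shorter
    # exponential keeps day offsets compact. Configurable by design.
    switch_gap_mean_days: float = 400.0
    extra_switch_probability: float = 0.25  # chance of each additional switch
    refill_encounter_mean: float = 1.0
    note_token_threshold: int = 50

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.switch_probability <= 1.0:
            raise ValueError("switch_probability outside [0, 1]")
        total = sum(self.modality_start_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"modality_start_distribution sums to {total}, not 1")
        if any(p < 0 for p in self.modality_start_distribution.values()):
            raise ValueError("modality_start_distribution has negative entries")
        for t in self.reason_topic_catalog:
            if not t.phrases:
                raise ValueError(f"topic {t.name} has an empty phrase pool")
        for item in self.subgroup_enrichment_plan:
            if item.factor < 0:
                raise ValueError("enrichment factors must be >= 0")
        self.noise_rates.validate()


@dataclass(frozen=True)
class GoldRecord:
    """Ground-truth annotation for one note (all-none for non-switch notes)."""

    note_id: str
    true_stopped: Modality | None
    true_started: Modality | None
    true_reason_topic: str | None
    true_reason_text: str | None


@dataclass
class SyntheticCohort:
    orders: pd.DataFrame
    demographics: pd.DataFrame
    notes: pd.DataFrame
    gold: list[GoldRecord]
    truth: dict

    def gold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "note_id": g.note_id,
                    "true_stopped": g.true_stopped.value if g.true_stopped else "",
                    "true_started": g.true_started.value if g.true_started else "",
                    "true_reason_topic": g.true_reason_topic or "",
                    "true_reason_text": g.true_reason_text or "",
                }
                for g in self.gold
            ]
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.orders.to_csv(outdir / "orders.csv", index=False)
        self.demographics.to_csv(outdir / "demographics.csv", index=False)
        with open(outdir / "notes.jsonl", "w") as fh:
            for row in self.notes.itertuples(index=False):
                fh.write(
                    json.dumps(
                        {
                            "note_id": row.note_id,
                            "patient_id": row.patient_id,
                            "encounter_date": int(row.encounter_date),
                            "text": row.text,
                        }
                    )
                    + "\n"
                )
        self.gold_frame().to_csv(outdir / "gold.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


_FILLER = [
    "Patient presents today for routine follow up of her contraceptive management plan.",
    "Vital signs were reviewed and remain within normal limits for age.",
    "She denies fevers, chills, chest pain, shortness of breath, or urinary symptoms.",
    "Review of systems is otherwise negative in detail as documented in the chart.",
    "Past medical history was reviewed and remains unchanged since the prior visit.",
    "Counseling provided regarding routine preventive care and age appropriate screening.",
    "All questions were answered and the patient verbalized understanding of the plan.",
    "Return precautions were discussed and follow up will be arranged as needed.",
]


def _token_count(text: str) -> int:
    return len(text.split())


def generate_note(
    stopped_mention: str | None = None,
    started_mention: str | None = None,
    reason_phrase: str | None = None,
    *,
    rng: np.random.Generator,
    short: bool = False,
    redact: bool = False,
    min_tokens: int = 51,
) -> str:
    """Render one clinical note.

    Switch notes embed the cue sentences the rule-based extractor targets
    ("stopped <drug>", "starting <drug>", "because of <reason>"). Unless
    ``short`` is set, filler sentences pad the note above ``min_tokens``
    whitespace tokens. With ``redact``, drug mentions are replaced by the
    deidentification placeholder.
    """
    if short:
        return "Brief telephone encounter, no issues reported."
    parts = [_FILLER[int(rng.integers(len(_FILLER)))]]
    if stopped_mention or started_mention:
        a = REDACTION_PLACEHOLDER if redact else stopped_mention
        b = REDACTION_PLACEHOLDER if redact else started_mention
        if stopped_mention and reason_phrase:
            parts.append(f"She has stopped {a} because of {reason_phrase}.")
        elif stopped_mention:
            parts.append(f"She has stopped {a}.")
        elif reason_phrase:
            parts.append(f"She is interested in a change because of {reason_phrase}.")
        if started_mention:
            parts.append(f"Plan today: starting {b} after counseling on options.")
    else:
        parts.append("Current contraceptive method reviewed; no change made at this visit.")
    i = 0
    while _token_count(" ".join(parts)) < min_tokens:
        parts.append(_FILLER[(i + 3) % len(_FILLER)])
        i += 1
    return " ".join(parts)


def _choice(rng: np.random.Generator, items: list, probs=None):
    idx = rng.choice(len(items), p=probs)
    return items[int(idx)]


def _sample_topic(rng, catalog, stopped: Modality, subgroups: dict, plan) -> ReasonTopic:
    eligible = [t for t in catalog if t.applies_to is None or stopped in t.applies_to]
    weights = np.ones(len(eligible))
    for item in plan:
        member = subgroups.get(item.axis) == item.subgroup
        if member:
            for i, t in enumerate(eligible):
                if t.name == item.topic:
                    weights[i] *= item.factor
    if weights.sum() == 0:
        weights = np.ones(len(eligible))
    return eligible[int(rng.choice(len(eligible), p=weights / weights.sum()))]


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mods = list(config.modality_start_distribution)
    mod_p = np.array([config.modality_start_distribution[m] for m in mods], float)
    races = list(config.race_distribution)
    race_p = np.array(list(config.race_distribution.values()), float)
    race_p = race_p / race_p.sum()
    langs = list(config.language_distribution)
    lang_p = np.array(list(config.language_distribution.values()), float)
    lang_p = lang_p / lang_p.sum()

    nr = config.noise_rates
    n_ltfu = int(round(nr.lost_to_followup * config.n_patients))

    orders, notes, demo_rows, gold = [], [], [], []
    note_seq = [0]
    topic_race_counts: dict[str, int] = {}
    topic_age_counts: dict[str, int] = {}
    n_switch_patients = 0
    n_switches = 0
    n_undocumented = 0
    ltfu_order_count = 0
    switch_note_ids: list[tuple[str, Product, Product]] = []
    min_tok = config.note_token_threshold + 1

    def add_note(pid, day, text):
        note_seq[0] += 1
        nid = f"N{note_seq[0]:06d}"
        notes.append({"note_id": nid, "patient_id": pid, "encounter_date": day, "text": text})
        return nid

    def add_order(pid, day, product: Product, start=None):
        orders.append(
            {
                "patient_id": pid,
                "encounter_date": day,
                "start_date": day if start is None else start,
                "drug_name": product.order_name,
                "therapeutic_class": CONTRACEPTIVE_CLASS,
            }
        )
        return orders[-1]

    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        ltfu = i < n_ltfu  # first block of patients is lost to follow-up
        switcher = (not ltfu) and rng.random() < config.switch_probability
        race = _choice(rng, races, race_p)
        lang = _choice(rng, langs, lang_p)
        if switcher:
            age = rng.normal(config.age_mean_switch, config.age_sd_switch)
        else:
            age = rng.normal(config.age_mean_noswitch, config.age_sd_noswitch)
        age = float(np.clip(age, 15.0, 55.0))
        demo_rows.append(
            {
                "patient_id": pid,
                "race_ethnicity": race,
                "preferred_language": lang,
                "age_first_rx": round(age, 1),
            }
        )
        subgroups = {"race": race, "age": age_bin(age)}

        day = int(rng.integers(0, 1000))
        modality = _choice(rng, mods, mod_p)
        product = _choice(rng, PRODUCTS[modality])
        add_order(pid, day, product)
        add_note(pid, day, generate_note(rng=rng, min_tokens=min_tok))
        if ltfu:
            ltfu_order_count += 1
            continue

        if switcher:
            n_switch_patients += 1
            n_sw = 1
            while rng.random() < config.extra_switch_probability:
                n_sw += 1
            for _ in range(n_sw):
                day += max(30, int(rng.exponential(config.switch_gap_mean_days)))
                new_mod = _choice(rng, [m for m in mods if m != modality])
                new_product = _choice(rng, PRODUCTS[new_mod])
                topic = _sample_topic(
                    rng, config.reason_topic_catalog, modality, subgroups, config.subgroup_enrichment_plan
                )
                phrase = topic.sample(rng)
                undocumented = rng.random() < nr.undocumented_stop
                text = generate_note(
                    None if undocumented else product.mention,
                    new_product.mention,
                    phrase,
                    rng=rng,
                    min_tokens=min_tok,
                )
                add_order(pid, day, new_product)
                nid = add_note(pid, day, text)
                n_undocumented += undocumented
                gold.append(
                    GoldRecord(nid, None if undocumented else modality, new_mod, topic.name, phrase)
                )
                switch_note_ids.append((nid, product, new_product))
                key_r = f"{topic.name}|{race}"
                key_a = f"{topic.name}|{subgroups['age']}"
                topic_race_counts[key_r] = topic_race_counts.get(key_r, 0) + 1
                topic_age_counts[key_a] = topic_age_counts.get(key_a, 0) + 1
                n_switches += 1
                modality, product = new_mod, new_product
        else:
            n_refill = int(rng.poisson(config.refill_encounter_mean))
            for _ in range(n_refill):
                day += max(30, int(rng.exponential(200.0)))
                add_order(pid, day, product)
                add_note(pid, day, generate_note(rng=rng, min_tokens=min_tok))

        # Follow-up encounter (note only) ensures retention at the 6-month filter.
        fu_day = day + FOLLOWUP_DAYS + int(rng.integers(0, 180))
        add_note(pid, fu_day, generate_note(rng=rng, min_tokens=min_tok))

    # Gold records for routine (non-switch) notes.
    switch_ids = {nid for nid, _, _ in switch_note_ids}
    for n in notes:
        if n["note_id"] not in switch_ids:
            gold.append(GoldRecord(n["note_id"], None, None, None, None))

    n_clean = len(orders)
    clean_orders = list(orders)
    surviving = [o for o in clean_orders if int(o["patient_id"][1:]) > n_ltfu]

    def planted(k_rate):
        return int(round(k_rate * n_clean))

    # --- noise rows, each removed by exactly one downstream filter ---
    n_distractor = planted(nr.distractor_order)
    for _ in range(n_distractor):
        base = _choice(rng, clean_orders)
        name, cls = _choice(rng, DISTRACTOR_PRODUCTS)
        orders.append(
            {
                "patient_id": base["patient_id"],
                "encounter_date": base["encounter_date"],
                "start_date": base["encounter_date"],
                "drug_name": name,
                "therapeutic_class": cls,
            }
        )

    n_excl = planted(nr.excluded_order)
    for _ in range(n_excl):
        base = _choice(rng, clean_orders)
        orders.append(
            {
                "patient_id": base["patient_id"],
                "encounter_date": base["encounter_date"],
                "start_date": base["encounter_date"],
                "drug_name": EMERGENCY_PRODUCT,
                "therapeutic_class": CONTRACEPTIVE_CLASS,
            }
        )

    n_nostart = planted(nr.missing_start_date)
    for _ in range(n_nostart):
        base = _choice(rng, clean_orders)
        row = dict(base)
        row["start_date"] = np.nan
        orders.append(row)

    # Orders at fresh encounter dates with no note / a too-short note, on
    # patients that survive the follow-up filter. Dates are back-filled a
    # few days *before* an existing encounter (inter-encounter gaps are
    # >= 30 days) so these rows never extend a patient's timeline past the
    # follow-up anchor and never collide with a real encounter date.
    n_nonote = planted(nr.missing_note) if surviving else 0
    for _ in range(n_nonote):
        base = _choice(rng, surviving)
        row = dict(base)
        row["encounter_date"] = row["start_date"] = base["encounter_date"] - int(rng.integers(2, 22))
        orders.append(row)

    n_short = planted(nr.short_note) if surviving else 0
    for _ in range(n_short):
        base = _choice(rng, surviving)
        row = dict(base)
        row["encounter_date"] = row["start_date"] = base["encounter_date"] - int(rng.integers(22, 30))
        orders.append(row)
        nid = add_note(
            row["patient_id"], row["encounter_date"], generate_note(rng=rng, short=True)
        )
        gold.append(GoldRecord(nid, None, None, None, None))

    # Duplicates copy orders of patients that survive follow-up, so the
    # dedup step (and no earlier filter) is what removes them.
    n_dup = planted(nr.duplicate_order) if surviving else 0
    for _ in range(n_dup):
        orders.append(dict(_choice(rng, surviving)))

    # Redaction: person-like brand mentions scrubbed from a fraction of
    # switch notes. Gold labels are untouched — this is the planted failure
    # mode for note-level extraction.
    n_redact = int(round(nr.redacted_brand * len(switch_note_ids)))
    redactable = [
        (nid, a, b) for nid, a, b in switch_note_ids if a.person_like or b.person_like
    ]
    n_redact = min(n_redact, len(redactable))
    note_by_id = {n["note_id"]: n for n in notes}
    for nid, a, b in redactable[:n_redact]:
        text = note_by_id[nid]["text"]
        for prod in (a, b):
            if prod.person_like:
                text = text.replace(prod.mention, REDACTION_PLACEHOLDER)
        note_by_id[nid]["text"] = text

    orders_df = pd.DataFrame(
        orders, columns=["patient_id", "encounter_date", "start_date", "drug_name", "therapeutic_class"]
    )
    notes_df = pd.DataFrame(notes, columns=["note_id", "patient_id", "encounter_date", "text"])
    demo_df = pd.DataFrame(demo_rows, columns=["patient_id", "race_ethnicity", "preferred_language", "age_first_rx"])

    truth = {
        "n_patients": config.n_patients,
        "n_clean_orders": n_clean,
        "n_orders_total": len(orders),
        "n_switch_patients": n_switch_patients,
        "n_switches": n_switches,
        "n_notes": len(notes),
        "n_switch_notes": len(switch_note_ids),
        "n_redacted_notes": n_redact,
        "n_undocumented_stops": int(n_undocumented),
        "removable": {
            "non_contraceptive_class": n_distractor,
            "excluded_or_unmapped": n_excl,
            "missing_start_date": n_nostart,
            "no_followup": ltfu_order_count,
            "missing_or_short_note": n_nonote + n_short,
            "duplicate": n_dup,
        },
        "n_lost_to_followup_patients": n_ltfu,
        "topic_race_counts": topic_race_counts,
        "topic_age_counts": topic_age_counts,
    }
    return SyntheticCohort(orders_df, demo_df, notes_df, gold, truth)


def simulate_topic_subgroups(
    n_notes: int,
    n_topics: int,
    subgroup_probs: dict[str, float],
    plan: tuple[EnrichmentPlanItem, ...] = (),
    *,
    seed: int = 0,
    soft: bool = False,
    concentration: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Draw (q, y) directly at the note level, honouring an enrichment plan.

    A light-weight companion to :func:`generate_cohort` for Monte-Carlo work
    on the enrichment statistic itself: each note gets one subgroup, then a
    topic drawn from uniform weights multiplied by the plan's factors inside
    the planted subgroup. With ``soft``, q rows are Dirichlet-perturbed
    toward the sampled topic; otherwise they are one-hot.

    Returns ``(q, y_frame, topic_index)`` where ``y_frame`` is the
    notes x subgroups indicator as a DataFrame.
    """
    rng = np.random.default_rng(seed)
    groups = list(subgroup_probs)
    gp = np.array(list(subgroup_probs.values()), float)
    gp = gp / gp.sum()
    g_idx = rng.choice(len(groups), size=n_notes, p=gp)
    base = np.ones(n_topics)
    topic_idx = np.empty(n_notes, dtype=int)
    weights_by_group = {}
    for gi, g in enumerate(groups):
        w = base.copy()
        for item in plan:
            if item.subgroup == g:
                w[int(item.topic)] *= item.factor
        weights_by_group[gi] = w / w.sum()
    for gi in range(len(groups)):
        mask = g_idx == gi
        topic_idx[mask] = rng.choice(n_topics, size=int(mask.sum()), p=weights_by_group[gi])
    if soft:
        q = rng.dirichlet(np.full(n_topics, concentration), size=n_notes)
        q = 0.2 * q
        q[np.arange(n_notes), topic_idx] += 0.8
        q = q / q.sum(axis=1, keepdims=True)
    else:
        q = np.zeros((n_notes, n_topics))
        q[np.arange(n_notes), topic_idx] = 1.0
    y = pd.DataFrame(0, index=range(n_notes), columns=groups, dtype=int)
    for gi, g in enumerate(groups):
        y.loc[g_idx == gi, g] = 1
    return q, y, topic_idx
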