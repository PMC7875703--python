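"""Emergency-department visit records: cleansing, deduplication, history
selection, outcome labeling, imputation, and dataset splitting.

A visit couples 15 structural fields (demographics, vital signs, pain score
and Glasgow coma scale components) with free-text chief complaint and past
medical-history entries, plus ICU-admission / death outcome timestamps.
Cleansing discards records whose chief complaint is absent or whose present
vitals are physiologically unreasonable; records with merely missing vitals
are retained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "VITAL_FIELDS",
    "StructuredVitals",
    "Visit",
    "CohortStats",
    "SplitSizes",
    "RejectReason",
    "cleanse_visits",
    "deduplicate_revisits",
    "select_history",
    "label_critical_outcome",
    "impute_and_perturb",
    "split_sizes",
    "assign_splits",
    "nhamcs_preprocess",
    "visits_to_jsonl",
    "visits_from_jsonl",
]

# Canonical slot order of the 15-element structural vector S.
VITAL_FIELDS = (
    "age", "gender", "sbp", "dbp", "hr", "spo2", "rr", "bt",
    "height", "weight", "pain", "gcs_total", "eye", "verbal", "motor",
)

GENDER_CODE = {"male": 1.0, "female": 0.0}


@dataclass
class StructuredVitals:
    """The 15 structural fields of one visit; ``None`` marks a missing value.

    Units: age in years, blood pressures in mmHg, heart rate in beats/min,
    SpO2 in %, respiratory rate in breaths/min, body temperature in °C,
    height in cm, weight in kg, pain on a 0–10 scale, Glasgow coma scale
    total 3–15 with eye 1–4 / verbal 1–5 / motor 1–6 components.
    """

    age: float | None = None
    gender: str | None = None  # "male" | "female"
    sbp: float | None = None
    dbp: float | None = None
    hr: float | None = None
    spo2: float | None = None
    rr: float | None = None
    bt: float | None = None
    height: float | None = None
    weight: float | None = None
    pain: float | None = None
    gcs_total: float | None = None
    eye: float | None = None
    verbal: float | None = None
    motor: float | None = None

    def numeric(self, name: str) -> float | None:
        """Value of a field on the numeric scale used by the model
        (gender coded male=1.0, female=0.0)."""
        v = getattr(self, name)
        if name == "gender":
            return None if v is None else GENDER_CODE[v]
        return v

    def present_mask(self) -> np.ndarray:
        return np.array([getattr(self, f) is not None for f in VITAL_FIELDS], dtype=bool)


@dataclass
class Visit:
    """One emergency-department encounter."""

    visit_id: str
    patient_id: str
    account_id: str
    revisit_flag: int
    triage_time: datetime
    chief_complaint: str
    vitals: StructuredVitals = field(default_factory=StructuredVitals)
    history_texts: list[tuple[datetime, str]] = field(default_factory=list)
    icu_time: datetime | None = None
    death_time: datetime | None = None


class RejectReason:
    """Closed enum of cleansing rejection codes."""

    MISSING_CC = "MISSING_CC"
    SBP_GT_300 = "SBP_GT_300"
    DBP_GT_SBP = "DBP_GT_SBP"
    HR_GT_250 = "HR_GT_250"
    RR_GT_100 = "RR_GT_100"
    BT_OUT_OF_RANGE = "BT_OUT_OF_RANGE"
    WT_GT_400 = "WT_GT_400"
    HT_GT_250 = "HT_GT_250"

    ALL = (MISSING_CC, SBP_GT_300, DBP_GT_SBP, HR_GT_250, RR_GT_100,
           BT_OUT_OF_RANGE, WT_GT_400, HT_GT_250)


def _violations(v: StructuredVitals) -> list[str]:
    out = []
    if v.sbp is not None and v.sbp > 300:
        out.append(RejectReason.SBP_GT_300)
    if v.sbp is not None and v.dbp is not None and v.dbp > v.sbp:
        out.append(RejectReason.DBP_GT_SBP)
    if v.hr is not None and v.hr > 250:
        out.append(RejectReason.HR_GT_250)
    if v.rr is not None and v.rr > 100:
        out.append(RejectReason.RR_GT_100)
    if v.bt is not None and not (20.0 <= v.bt <= 48.0):
        out.append(RejectReason.BT_OUT_OF_RANGE)
    if v.weight is not None and v.weight > 400:
        out.append(RejectReason.WT_GT_400)
    if v.height is not None and v.height > 250:
        out.append(RejectReason.HT_GT_250)
    return out


def cleanse_visits(visits: list[Visit]) -> tuple[list[Visit], list[tuple[Visit, str]]]:
    """Discard visits with an empty chief complaint or an unreasonable
    present vital; visits whose vitals are merely missing are kept.

    Returns (kept, rejected) with input order preserved; each rejected visit
    carries the first matching :class:`RejectReason` code.
    """
    kept: list[Visit] = []
    rejected: list[tuple[Visit, str]] = []
    for visit in visits:
        if not visit.chief_complaint or not visit.chief_complaint.strip():
            rejected.append((visit, RejectReason.MISSING_CC))
            continue
        bad = _violations(visit.vitals)
        if bad:
            rejected.append((visit, bad[0]))
        else:
            kept.append(visit)
    return kept, rejected


def deduplicate_revisits(visits: list[Visit]) -> list[Visit]:
    """Keep, per account, only the visit with the maximal revisit flag
    (the last account record), preserving the order of the survivors."""
    best: dict[str, Visit] = {}
    for visit in visits:
        prev = best.get(visit.account_id)
        if prev is not None and prev.revisit_flag == visit.revisit_flag:
            raise ValueError(
                f"DUPLICATE_KEY: account {visit.account_id} has two visits "
                f"with revisit_flag {visit.revisit_flag}"
            )
        if prev is None or visit.revisit_flag > prev.revisit_flag:
            best[visit.account_id] = visit
    winners = {id(v) for v in best.values()}
    return [v for v in visits if id(v) in winners]


def select_history(patient_records: list[tuple[datetime, str]],
                   triage_time: datetime) -> list[str]:
    """Texts of records strictly before triage time, chronological order.
    Future records must never leak into a visit's history."""
    past = [(t, txt) for t, txt in patient_records if t < triage_time]
    past.sort(key=lambda pair: pair[0])
    return [txt for _, txt in past]


def label_critical_outcome(visit: Visit, window_days: float = 3.0,
                           mode: str = "window") -> int:
    """Binary critical-care outcome: ICU admission or death.

    ``mode="window"`` (hospital-database definition): 1 iff an ICU or death
    record exists within ``window_days`` (inclusive, continuous 24 h days)
    after triage.  ``mode="nhamcs"`` (survey definition): 1 iff a direct-ICU
    or in-hospital-death record exists at all, with no time window.
    """
    if mode == "nhamcs":
        return int(visit.icu_time is not None or visit.death_time is not None)
    if mode != "window":
        raise ValueError(f"unknown outcome mode: {mode!r}")
    window = timedelta(days=window_days)
    for t in (visit.icu_time, visit.death_time):
        if t is not None and timedelta(0) <= t - visit.triage_time <= window:
            return 1
    return 0


@dataclass
class CohortStats:
    """Per-field mean and SD over PRESENT values (missing data discarded
    before counting). Gender enters on its numeric 0/1 coding."""

    means: dict[str, float]
    sds: dict[str, float]

    @classmethod
    def from_visits(cls, visits: list[Visit]) -> "CohortStats":
        cols: dict[str, list[float]] = {f: [] for f in VITAL_FIELDS}
        for visit in visits:
            for f in VITAL_FIELDS:
                x = visit.vitals.numeric(f)
                if x is not None:
                    cols[f].append(float(x))
        means, sds = {}, {}
        for f, values in cols.items():
            if not values:
                raise ValueError(f"INCOMPLETE_STATS: no present values for field {f!r}")
            arr = np.asarray(values)
            means[f] = float(arr.mean())
            sds[f] = float(arr.std())
        return cls(means=means, sds=sds)

    def mean_vector(self) -> np.ndarray:
        return np.array([self.means[f] for f in VITAL_FIELDS])

    def sd_vector(self) -> np.ndarray:
        return np.array([self.sds[f] for f in VITAL_FIELDS])


def impute_and_perturb(vitals: StructuredVitals, stats: CohortStats,
                       noise_fraction: float = 0.0,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Numeric 15-vector: missing fields filled with the training mean, then
    (optionally) additive zero-mean Gaussian noise with per-field scale
    ``noise_fraction`` × training SD.

    Gender is coded numerically (male=1, female=0) and is never perturbed:
    noise must not move a categorical field across its category boundary.
    """
    missing = set(VITAL_FIELDS) - set(stats.means) | set(VITAL_FIELDS) - set(stats.sds)
    if missing:
        raise ValueError(f"INCOMPLETE_STATS: stats lack fields {sorted(missing)}")
    x = np.empty(len(VITAL_FIELDS))
    for i, f in enumerate(VITAL_FIELDS):
        v = vitals.numeric(f)
        x[i] = stats.means[f] if v is None else float(v)
    if noise_fraction > 0:
        if rng is None:
            raise ValueError("noise_fraction > 0 requires a seeded rng")
        noise = rng.normal(0.0, 1.0, size=x.shape) * noise_fraction * stats.sd_vector()
        noise[VITAL_FIELDS.index("gender")] = 0.0
        x = x + noise
    return x


@dataclass(frozen=True)
class SplitSizes:
    n_train: int
    n_val: int
    n_test: int

    def __iter__(self):
        return iter((self.n_train, self.n_val, self.n_test))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_sizes(n_total: int, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)) -> SplitSizes:
    """Train/validation/test sizes for an n-visit sample.

    train = round-half-up(r_train·n), test = round-half-up(r_test·n),
    validation = remainder — the rounding rule that reproduces the published
    80/10/10 splits of both the hospital-database and survey cohorts.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    n_train = _round_half_up(ratios[0] * n_total)
    n_test = _round_half_up(ratios[2] * n_total)
    n_val = n_total - n_train - n_test
    return SplitSizes(n_train=n_train, n_val=n_val, n_test=n_test)


def assign_splits(visit_ids: list[str], seed: int,
                  ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)) -> dict[str, str]:
    """Seeded random partition of visit ids into train/val/test with sizes
    from :func:`split_sizes`."""
    sizes = split_sizes(len(visit_ids), ratios)
    order = np.random.default_rng(seed).permutation(len(visit_ids))
    labels = ["train"] * sizes.n_train + ["val"] * sizes.n_val + ["test"] * sizes.n_test
    return {visit_ids[j]: labels[i] for i, j in enumerate(order)}


# ---------------------------------------------------------------------------
# Survey-style (NHAMCS-like) tabular conversion

_EXCLUDED_DISPOSITIONS = {"doa", "left_before_seen", "ama"}
_KNOWN_DISPOSITIONS = _EXCLUDED_DISPOSITIONS | {
    "treated", "admitted", "transferred", "observation", "icu",
}


def _default_phrase_table() -> dict[str, str]:
    import importlib.resources

    import yaml

    ref = importlib.resources.files("edembed") / "resources" / "comorbidity_phrases.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def nhamcs_preprocess(records: pd.DataFrame,
                      phrase_table: dict[str, str] | None = None) -> list[Visit]:
    """Convert survey-style tabular rows into :class:`Visit` objects.

    Expected columns: ``visit_id``, ``patient_id``, ``triage_time`` (ISO),
    ``cc_desc_1..3`` (coded chief-complaint descriptions, joined into one
    string), ``disposition``, ``direct_icu`` / ``hospital_death`` (0/1),
    and one 0/1 column per comorbidity key of the phrase table; vitals
    columns share names with :data:`VITAL_FIELDS` where the survey carries
    them (no height/weight or coma-scale components).

    Excludes dead-on-arrival, left-before-seen and against-medical-advice
    rows; positive comorbidity flags become one past-history text each via
    the phrase table. Cleansing thresholds are applied afterwards through
    :func:`cleanse_visits`.
    """
    phrase_table = phrase_table or _default_phrase_table()
    visits: list[Visit] = []
    for _, row in records.iterrows():
        disposition = str(row.get("disposition", "")).strip().lower()
        if disposition in _EXCLUDED_DISPOSITIONS:
            continue
        if disposition and disposition not in _KNOWN_DISPOSITIONS:
            warnings.warn(f"unknown disposition code {disposition!r}; record kept",
                          stacklevel=2)
        triage = _parse_ts(row["triage_time"])
        cc = " ".join(
            str(row[c]).strip() for c in ("cc_desc_1", "cc_desc_2", "cc_desc_3")
            if c in row.index and not _isna(row[c]) and str(row[c]).strip()
        )
        history = [
            (triage - timedelta(days=365), phrase_table[key])
            for key in phrase_table
            if key in row.index and not _isna(row[key]) and int(row[key]) == 1
        ]
        vital_kwargs = {}
        for f in VITAL_FIELDS:
            if f in row.index and not _isna(row[f]):
                vital_kwargs[f] = str(row[f]) if f == "gender" else float(row[f])
        visit = Visit(
            visit_id=str(row["visit_id"]),
            patient_id=str(row.get("patient_id", row["visit_id"])),
            account_id=str(row.get("account_id", row["visit_id"])),
            revisit_flag=int(row.get("revisit_flag", 0)),
            triage_time=triage,
            chief_complaint=cc,
            vitals=StructuredVitals(**vital_kwargs),
            history_texts=history,
            icu_time=triage if int(row.get("direct_icu", 0) or 0) == 1 else None,
            death_time=triage if int(row.get("hospital_death", 0) or 0) == 1 else None,
        )
        visits.append(visit)
    kept, _ = cleanse_visits(visits)
    return kept


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or (isinstance(x, str) and not x.strip())


def _parse_ts(x) -> datetime:
    if isinstance(x, datetime):
        return x
    return datetime.fromisoformat(str(x))


# ---------------------------------------------------------------------------
# JSONL serialization (one visit per line; timestamps as ISO-8601 strings)

def _visit_to_dict(v: Visit) -> dict:
    return {
        "visit_id": v.visit_id,
        "patient_id": v.patient_id,
        "account_id": v.account_id,
        "revisit_flag": v.revisit_flag,
        "triage_time": v.triage_time.isoformat(),
        "chief_complaint": v.chief_complaint,
        "vitals": {f: getattr(v.vitals, f) for f in VITAL_FIELDS},
        "history_texts": [[t.isoformat(), txt] for t, txt in v.history_texts],
        "icu_time": v.icu_time.isoformat() if v.icu_time else None,
        "death_time": v.death_time.isoformat() if v.death_time else None,
    }


def _visit_from_dict(d: dict) -> Visit:
    return Visit(
        visit_id=d["visit_id"],
        patient_id=d["patient_id"],
        account_id=d["account_id"],
        revisit_flag=int(d["revisit_flag"]),
        triage_time=datetime.fromisoformat(d["triage_time"]),
        chief_complaint=d["chief_complaint"],
        vitals=StructuredVitals(**d["vitals"]),
        history_texts=[(datetime.fromisoformat(t), txt) for t, txt in d["history_texts"]],
        icu_time=datetime.fromisoformat(d["icu_time"]) if d.get("icu_time") else None,
        death_time=datetime.fromisoformat(d["death_time"]) if d.get("death_time") else None,
    )


def visits_to_jsonl(visits: list[Visit], path) -> None:
    with open(path, "w") as fh:
        for v in visits:
            fh.write(json.dumps(_visit_to_dict(v)) + "\n")


def visits_from_jsonl(path) -> list[Visit]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(_visit_from_dict(json.loads(line)))
    return out


def visits_to_csv(visits: list[Visit], path) -> None:
    """Flat CSV dialect: one row per visit, one column per vital field,
    ISO-8601 timestamps, history entries JSON-encoded in ``history_texts``;
    missing values are empty cells."""
    rows = []
    for v in visits:
        row = {
            "visit_id": v.visit_id, "patient_id": v.patient_id,
            "account_id": v.account_id, "revisit_flag": v.revisit_flag,
            "triage_time": v.triage_time.isoformat(),
            "chief_complaint": v.chief_complaint,
            "history_texts": json.dumps([[t.isoformat(), txt]
                                         for t, txt in v.history_texts]),
            "icu_time": v.icu_time.isoformat() if v.icu_time else None,
            "death_time": v.death_time.isoformat() if v.death_time else None,
        }
        row.update({f: getattr(v.vitals, f) for f in VITAL_FIELDS})
        rows.append(row)
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def visits_from_csv(path) -> list[Visit]:
    frame = pd.read_csv(path, dtype={"visit_id": str, "patient_id": str,
                                     "account_id": str},
                        float_precision="round_trip")
    out = []
    for _, row in frame.iterrows():
        vitals = {}
        for f in VITAL_FIELDS:
            if not _isna(row[f]):
                vitals[f] = str(row[f]) if f == "gender" else float(row[f])
        out.append(Visit(
            visit_id=row["visit_id"], patient_id=row["patient_id"],
            account_id=row["account_id"], revisit_flag=int(row["revisit_flag"]),
            triage_time=datetime.fromisoformat(row["triage_time"]),
            chief_complaint="" if _isna(row["chief_complaint"]) else str(row["chief_complaint"]),
            vitals=StructuredVitals(**vitals),
            history_texts=[(datetime.fromisoformat(t), txt)
                           for t, txt in json.loads(row["history_texts"])],
            icu_time=None if _isna(row["icu_time"]) else datetime.fromisoformat(row["icu_time"]),
            death_time=None if _isna(row["death_time"]) else datetime.fromisoformat(row["death_time"]),
        ))
    return out
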