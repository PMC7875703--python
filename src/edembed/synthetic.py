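"""Seeded generator of emergency-department-like cohorts with known latent
structure.

Each synthetic visit belongs to a hidden cluster ("disease pattern"). The
cluster shifts a subset of the vital-sign means by a configurable number of
standard deviations, selects the symptom vocabulary the chief complaint and
history texts are sampled from, and shifts the log-odds of the rare
critical-care outcome. Marginal vital-sign means and SDs are anchored to
published emergency-department cohort statistics (e.g. systolic blood
pressure 135.4 (27.3) mmHg, heart rate 95.8 (25.6) beats/min, outcome
prevalence 0.6–1.6%). A configurable fraction of records is deliberately
corrupted with threshold violations so the cleansing stage sees dirty data,
and per-field missingness exercises imputation.

The latent cluster labels are returned separately and never leak into the
visit fields; they are the oracle every downstream evaluation (retrieval
precision, ARI, finetuning AUROC) is scored against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .ehr import (RejectReason, StructuredVitals, Visit, VITAL_FIELDS,
                  visits_from_jsonl, visits_to_jsonl)

__all__ = ["SyntheticConfig", "SyntheticCohort", "generate_cohort",
           "cohort_to_files", "cohort_from_files"]

# Anchor marginal means/SDs for the continuous vitals (emergency-department
# cohort scale).
FIELD_MEANS = {
    "age": 43.7, "sbp": 135.4, "dbp": 78.3, "hr": 95.8, "spo2": 97.2,
    "rr": 19.5, "bt": 37.1, "height": 152.8, "weight": 52.5, "pain": 2.7,
}
FIELD_SDS = {
    "age": 26.9, "sbp": 27.3, "dbp": 15.8, "hr": 25.6, "spo2": 3.64,
    "rr": 3.4, "bt": 1.0, "height": 26.6, "weight": 22.8, "pain": 3.2,
}
# Plausible clipping ranges (cleansing thresholds stay strictly outside).
FIELD_BOUNDS = {
    "age": (0.0, 105.0), "sbp": (50.0, 295.0), "dbp": (20.0, 200.0),
    "hr": (20.0, 245.0), "spo2": (40.0, 100.0), "rr": (4.0, 95.0),
    "bt": (30.0, 45.0), "height": (40.0, 245.0), "weight": (1.0, 350.0),
    "pain": (0.0, 10.0),
}
MALE_FRACTION = 0.505
# Fields eligible for cluster mean shifts.
CLUSTER_FIELDS = ("sbp", "dbp", "hr", "spo2", "rr", "bt", "pain")

# Disjoint per-cluster symptom vocabularies for the default 4 clusters.
DEFAULT_VOCABULARIES = [
    ["chest", "tightness", "palpitation", "dyspnea", "orthopnea", "sweating",
     "exertion", "radiating", "arm", "pressure"],
    ["abdominal", "epigastric", "vomiting", "diarrhea", "nausea", "bloating",
     "tarry", "stool", "flank", "cramp"],
    ["fever", "cough", "sputum", "chills", "sore", "throat", "rhinorrhea",
     "myalgia", "malaise", "headcold"],
    ["dizziness", "vertigo", "headache", "weakness", "numbness", "slurred",
     "speech", "unsteady", "gait", "syncope"],
]


@dataclass
class SyntheticConfig:
    """Generating parameters of a synthetic cohort.

    ``cluster_separation`` is the per-field mean shift in SD units applied
    to the fields a cluster perturbs; ``invalid_rate`` is the fraction of
    records corrupted with one cleansing-threshold violation;
    ``outcome_base_rate`` is the target mean outcome prevalence (the base
    log-odds is solved so the cluster-shift mixture hits it exactly).
    """

    n_visits: int = 2000
    n_clusters: int = 4
    cluster_separation: float = 3.0
    missing_rate: float = 0.10
    invalid_rate: float = 0.02
    history_poisson_mean: float = 1.2
    outcome_base_rate: float = 0.016
    outcome_cluster_shifts: tuple = (-0.75, -0.25, 0.25, 0.75)
    vocab_overlap: float = 0.0
    vocabularies: list | None = None
    seed: int = 0

    def __post_init__(self):
        for rate in (self.missing_rate, self.invalid_rate, self.vocab_overlap):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if len(self.outcome_cluster_shifts) != self.n_clusters:
            raise ValueError("need one outcome shift per cluster")

    @classmethod
    def ablation_preset(cls, **overrides) -> "SyntheticConfig":
        """Conditions for the small-label finetuning/ablation protocol: the
        outcome is common enough (~10% prevalence) and cluster-driven
        enough that a few hundred labels carry signal."""
        kwargs = dict(n_visits=1500, outcome_base_rate=0.10,
                      outcome_cluster_shifts=(-2.5, -1.0, 1.0, 2.5),
                      invalid_rate=0.0, missing_rate=0.10)
        kwargs.update(overrides)
        return cls(**kwargs)

    def base_logit(self) -> float:
        """Base log-odds such that the equal-weight cluster mixture has
        mean prevalence ``outcome_base_rate``."""
        shifts = np.asarray(self.outcome_cluster_shifts, dtype=float)
        target = self.outcome_base_rate

        def gap(b):
            return expit(b + shifts).mean() - target

        return float(brentq(gap, logit(target) - 10.0, logit(target) + 10.0))

    def expected_prevalence(self) -> float:
        return float(expit(self.base_logit()
                           + np.asarray(self.outcome_cluster_shifts)).mean())

    def cluster_vocabularies(self, rng: np.random.Generator) -> list[list[str]]:
        if self.vocabularies is not None:
            vocabs = [list(v) for v in self.vocabularies]
        else:
            vocabs = [list(v) for v in DEFAULT_VOCABULARIES]
            for c in range(len(vocabs), self.n_clusters):
                vocabs.append([f"sym{c}x{i}" for i in range(10)])
            vocabs = vocabs[: self.n_clusters]
        if any(not v for v in vocabs):
            raise ValueError("empty cluster vocabulary")
        if self.vocab_overlap > 0:
            # replace a fraction of each cluster's tokens with shared ones,
            # degrading the text signal for robustness experiments
            shared = [f"common{i}" for i in range(10)]
            for v in vocabs:
                k = int(round(self.vocab_overlap * len(v)))
                for i in range(k):
                    v[i] = shared[i % len(shared)]
        return vocabs


@dataclass
class SyntheticCohort:
    """Generated visits plus the latent truth the tests score against."""

    visits: list[Visit]
    latent_cluster: np.ndarray
    generating_params: SyntheticConfig
    cluster_field_shifts: np.ndarray = field(default=None)  # (n_clusters, 15) in SD units
    injected_invalid: dict = field(default_factory=dict)    # visit_id -> RejectReason code

    def outcomes(self) -> np.ndarray:
        from .ehr import label_critical_outcome

        return np.array([label_critical_outcome(v) for v in self.visits], dtype=int)


def _draw_cluster_shifts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-cluster, per-field shift pattern in SD units: each cluster
    perturbs a random subset of CLUSTER_FIELDS up or down."""
    shifts = np.zeros((config.n_clusters, len(VITAL_FIELDS)))
    for c in range(config.n_clusters):
        while True:
            deltas = rng.choice([-1.0, 0.0, 1.0], size=len(CLUSTER_FIELDS),
                                p=[0.25, 0.5, 0.25])
            if np.abs(deltas).sum() >= 2:  # every cluster shifts >= 2 fields
                break
        for f, d in zip(CLUSTER_FIELDS, deltas):
            shifts[c, VITAL_FIELDS.index(f)] = d * config.cluster_separation
    return shifts


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a fully seeded cohort; identical configs give identical cohorts."""
    rng = np.random.default_rng(config.seed)
    vocabs = config.cluster_vocabularies(rng)
    shifts = _draw_cluster_shifts(config, rng)
    base_logit = config.base_logit()
    t0 = datetime(2017, 1, 1)
    visits: list[Visit] = []
    clusters = rng.integers(0, config.n_clusters, size=config.n_visits)
    injected: dict[str, str] = {}
    for i in range(config.n_visits):
        c = int(clusters[i])
        vit = StructuredVitals()
        vit.gender = "male" if rng.random() < MALE_FRACTION else "female"
        for f in FIELD_MEANS:
            j = VITAL_FIELDS.index(f)
            mu = FIELD_MEANS[f] + shifts[c, j] * FIELD_SDS[f]
            lo, hi = FIELD_BOUNDS[f]
            setattr(vit, f, float(np.clip(rng.normal(mu, FIELD_SDS[f]), lo, hi)))
        vit.pain = float(np.clip(round(vit.pain), 0, 10))
        if vit.dbp >= vit.sbp:
            vit.dbp = max(FIELD_BOUNDS["dbp"][0], vit.sbp - 5.0)
        vit.eye = float(np.clip(round(rng.normal(4.0, 0.3)), 1, 4))
        vit.verbal = float(np.clip(round(rng.normal(4.9, 0.6)), 1, 5))
        vit.motor = float(np.clip(round(rng.normal(5.9, 0.5)), 1, 6))
        vit.gcs_total = vit.eye + vit.verbal + vit.motor
        # missingness (never on the chief complaint)
        for f in VITAL_FIELDS:
            if rng.random() < config.missing_rate:
                setattr(vit, f, None)
        if vit.gcs_total is not None and None in (vit.eye, vit.verbal, vit.motor):
            vit.gcs_total = None

        vocab = vocabs[c]
        cc = " ".join(rng.choice(vocab, size=rng.integers(2, 6), replace=True))
        n_hx = rng.poisson(config.history_poisson_mean)
        triage = t0 + timedelta(days=float(rng.uniform(0, 365)))
        history = []
        for _ in range(n_hx):
            txt = " ".join(rng.choice(vocab, size=rng.integers(1, 4), replace=True))
            history.append((triage - timedelta(days=float(rng.uniform(1, 1000))), txt))
        history.sort(key=lambda p: p[0])

        y = rng.random() < expit(base_logit + config.outcome_cluster_shifts[c])
        icu_time = death_time = None
        if y:
            event = triage + timedelta(days=float(rng.uniform(0.05, 2.95)))
            if rng.random() < 0.5:
                icu_time = event
            else:
                death_time = event

        visit = Visit(
            visit_id=f"v{i:06d}", patient_id=f"p{i:06d}", account_id=f"a{i:06d}",
            revisit_flag=0, triage_time=triage, chief_complaint=cc,
            vitals=vit, history_texts=history,
            icu_time=icu_time, death_time=death_time,
        )
        if rng.random() < config.invalid_rate:
            code = RejectReason.ALL[rng.integers(0, len(RejectReason.ALL))]
            _inject_violation(visit, code, rng)
            injected[visit.visit_id] = code
        visits.append(visit)
    return SyntheticCohort(visits=visits, latent_cluster=clusters,
                           generating_params=config,
                           cluster_field_shifts=shifts, injected_invalid=injected)


def _inject_violation(visit: Visit, code: str, rng: np.random.Generator) -> None:
    """Corrupt an otherwise-valid visit so cleansing rejects it with
    exactly `code`."""
    v = visit.vitals
    if code == RejectReason.MISSING_CC:
        visit.chief_complaint = ""
    elif code == RejectReason.SBP_GT_300:
        v.sbp = float(rng.uniform(301, 400))
        if v.dbp is not None and v.dbp > v.sbp:
            v.dbp = v.sbp - 10.0
    elif code == RejectReason.DBP_GT_SBP:
        if v.sbp is None:
            v.sbp = 120.0
        v.dbp = v.sbp + float(rng.uniform(5, 40))
    elif code == RejectReason.HR_GT_250:
        v.hr = float(rng.uniform(251, 350))
    elif code == RejectReason.RR_GT_100:
        v.rr = float(rng.uniform(101, 150))
    elif code == RejectReason.BT_OUT_OF_RANGE:
        v.bt = float(rng.uniform(10, 19)) if rng.random() < 0.5 else float(rng.uniform(48.5, 55))
    elif code == RejectReason.WT_GT_400:
        v.weight = float(rng.uniform(401, 500))
    elif code == RejectReason.HT_GT_250:
        v.height = float(rng.uniform(251, 300))
    else:  # pragma: no cover
        raise ValueError(f"unknown rejection code {code}")


def cohort_to_files(cohort: SyntheticCohort, path) -> dict[str, Path]:
    """Write visits.jsonl (the pipeline input), truth.csv (latent cluster
    per visit), and config.json; returns the paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "visits": path / "visits.jsonl",
        "truth": path / "truth.csv",
        "config": path / "config.json",
    }
    visits_to_jsonl(cohort.visits, files["visits"])
    pd.DataFrame({
        "visit_id": [v.visit_id for v in cohort.visits],
        "latent_cluster": cohort.latent_cluster,
    }).to_csv(files["truth"], index=False)
    payload = asdict(cohort.generating_params)
    payload["_injected_invalid"] = cohort.injected_invalid
    payload["_cluster_field_shifts"] = cohort.cluster_field_shifts.tolist()
    files["config"].write_text(json.dumps(payload, indent=2))
    return files


def cohort_from_files(path) -> SyntheticCohort:
    path = Path(path)
    visits = visits_from_jsonl(path / "visits.jsonl")
    truth = pd.read_csv(path / "truth.csv")
    payload = json.loads((path / "config.json").read_text())
    injected = payload.pop("_injected_invalid", {})
    shifts = np.asarray(payload.pop("_cluster_field_shifts"))
    payload["outcome_cluster_shifts"] = tuple(payload["outcome_cluster_shifts"])
    config = SyntheticConfig(**payload)
    return SyntheticCohort(
        visits=visits,
        latent_cluster=truth["latent_cluster"].to_numpy(),
        generating_params=config,
        cluster_field_shifts=shifts,
        injected_invalid=injected,
    )
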