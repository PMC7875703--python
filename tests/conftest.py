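from datetime import datetime, timedelta

import numpy as np
import pytest

from edembed import (CohortStats, HashingTextEncoder, StructuredVitals,
                     SyntheticConfig, Visit, build_features, cleanse_visits,
                     generate_cohort)
from edembed.model import ModelConfig


def make_visit(visit_id="v1", cc="chest pain", account="a1", flag=0,
               triage=None, **vital_kwargs) -> Visit:
    return Visit(
        visit_id=visit_id,
        patient_id=f"p-{visit_id}",
        account_id=account,
        revisit_flag=flag,
        triage_time=triage or datetime(2017, 5, 1, 12, 0),
        chief_complaint=cc,
        vitals=StructuredVitals(**vital_kwargs),
    )


@pytest.fixture(scope="session")
def small_model_config():
    return ModelConfig.small_preset()


@pytest.fixture(scope="session")
def tiny_cohort():
    """300-visit clean synthetic cohort shared by model-level tests."""
    return generate_cohort(SyntheticConfig(n_visits=300, seed=7, invalid_rate=0.0))


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort, small_model_config):
    kept, _ = cleanse_visits(tiny_cohort.visits)
    stats = CohortStats.from_visits(kept)
    encoder = HashingTextEncoder(d_text=small_model_config.d_text)
    return build_features(kept, stats, encoder)


@pytest.fixture()
def default_stats():
    """Cohort statistics from a small deterministic clean cohort."""
    cohort = generate_cohort(SyntheticConfig(n_visits=200, seed=11, invalid_rate=0.0,
                                             missing_rate=0.0))
    return CohortStats.from_visits(cohort.visits)
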