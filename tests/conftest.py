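"""Shared fixtures.

The expensive fixtures (contrastively trained studies) are session-scoped
and shared by the acceptance tests so each 15-epoch training happens once.
"""

from __future__ import annotations

import pytest

from prser.corpus import PlantRecord
from prser.pipeline import StudyConfig, run_study

STUDY_SEEDS = (0, 1, 2)


def make_record(record_id: str = "r1", prescription: str = "rx-a",
                **overrides) -> PlantRecord:
    base = dict(
        record_id=record_id,
        environment={"onset_date": "june week2", "location": "north field",
                     "field_distribution": "patchy edges"},
        plant={"species": "tomato", "growth_stage": "flowering",
               "affected_part": "lower leaves"},
        symptom={"severity": "moderate", "main_symptoms": "brown concentric spots",
                 "detail": "yellow halo around lesions"},
        prescription=prescription,
    )
    base.update(overrides)
    return PlantRecord(**base)


@pytest.fixture(scope="session")
def cosent_studies():
    """CoSENT-trained studies (closed + open set + symptom ablation), one
    per seed — the scaled-down closed/open-set benchmark."""
    return {
        seed: run_study(StudyConfig(seed=seed),
                        with_open_set=True,
                        ablation_groups=[("symptom",)],
                        keep_encoder=True)
        for seed in STUDY_SEEDS
    }


@pytest.fixture(scope="session")
def sbert_studies():
    """Same corpora and budget, trained with the SBERT softmax objective."""
    return {
        seed: run_study(StudyConfig(seed=seed, loss_kind="sbert_softmax"),
                        with_open_set=False)
        for seed in STUDY_SEEDS
    }
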