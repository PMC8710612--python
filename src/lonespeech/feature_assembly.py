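"""Assembly of per-response summaries into the fixed 160-dimensional
session feature vector: 128 acoustic (16 per question x 8), 16 prosodic
(2 x 8) and 16 linguistic (2 x 4 + 1 x 8) features with stable names.

Unresolvable values (e.g. formants that no frame could produce) are stored
as NaN and imputed with the training-split median at modeling time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lonespeech.audio_features import AcousticSummary, ProsodySummary
from lonespeech.linguistic_features import QUESTION_IDS, SENTIMENT_QUESTIONS


def feature_names(sentiment_questions=SENTIMENT_QUESTIONS) -> list:
    """The canonical ordered 160 feature names (128 acoustic, 16 prosodic,
    16 linguistic)."""
    names = []
    for q in QUESTION_IDS:
        names.append(f"ac.f1.q{q}")
        names.append(f"ac.f2.q{q}")
        names.extend(f"ac.dmfccvar{j}.q{q}" for j in range(1, 15))
    for q in QUESTION_IDS:
        names.append(f"pr.pitchvar.q{q}")
        names.append(f"pr.pause.q{q}")
    for q in sorted(sentiment_questions):
        names.append(f"li.pos.q{q}")
        names.append(f"li.neg.q{q}")
    names.extend(f"li.filler.q{q}" for q in QUESTION_IDS)
    return names


FEATURE_NAMES = feature_names()


def feature_type(name: str) -> str:
    """'acoustic' | 'prosodic' | 'linguistic' from the name prefix."""
    prefix = name.split(".", 1)[0]
    return {"ac": "acoustic", "pr": "prosodic", "li": "linguistic"}[prefix]


@dataclass(frozen=True)
class SessionFeatureVector:
    values: pd.Series  # indexed by FEATURE_NAMES

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.values.index)
        if missing or len(self.values) != 160:
            raise ValueError(
                f"feature vector must carry exactly the 160 canonical names "
                f"(missing {sorted(missing)[:3]}...)"
            )
        object.__setattr__(self, "values", self.values.reindex(FEATURE_NAMES).astype(float))

    def partition_sizes(self):
        types = [feature_type(n) for n in self.values.index]
        return (
            types.count("acoustic"),
            types.count("prosodic"),
            types.count("linguistic"),
        )


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    ucla_score: int
    age: int
    sex: str  # 'F' | 'M'
    features: SessionFeatureVector | None = None

    def __post_init__(self):
        if not 20 <= self.ucla_score <= 80:
            raise ValueError("UCLA total score must lie in [20, 80]")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")


def assemble_session(acoustics, prosody, linguistics) -> SessionFeatureVector:
    """Build the 160-vector from per-question summaries.

    acoustics / prosody: mapping question_id -> AcousticSummary / ProsodySummary
    (any iteration order; names key the layout); linguistics: the 16 named
    values from summarize_session_linguistics.  Missing questions raise with
    the offending id; individual NaN values are allowed (imputed later).
    """
    acoustics = dict(acoustics)
    prosody = dict(prosody)
    for q in QUESTION_IDS:
        if q not in acoustics:
            raise ValueError(f"missing acoustic summary for question {q}")
        if q not in prosody:
            raise ValueError(f"missing prosody summary for question {q}")
    vals = {}
    for q, ac in acoustics.items():
        vals[f"ac.f1.q{q}"] = ac.f1_hz
        vals[f"ac.f2.q{q}"] = ac.f2_hz
        for j in range(1, 15):
            vals[f"ac.dmfccvar{j}.q{q}"] = ac.dmfcc_var[j - 1]
    for q, pr in prosody.items():
        vals[f"pr.pitchvar.q{q}"] = pr.pitch_variation_hz
        vals[f"pr.pause.q{q}"] = pr.pause_duration_s
    vals.update(linguistics)
    missing = set(FEATURE_NAMES) - set(vals)
    if missing:
        raise ValueError(f"missing features: {sorted(missing)[:3]} ...")
    return SessionFeatureVector(pd.Series(vals))


def nan_acoustic_summary() -> AcousticSummary:
    """Placeholder for a response whose acoustics could not be resolved."""
    return AcousticSummary(f1_hz=np.nan, f2_hz=np.nan, dmfcc_var=np.full(14, np.nan))


def build_feature_table(records) -> pd.DataFrame:
    """One row per participant: participant_id, ucla, age, sex + 160 features."""
    rows = []
    for rec in records:
        if rec.features is None:
            raise ValueError(f"participant {rec.participant_id} has no features")
        row = {"participant_id": rec.participant_id, "ucla": rec.ucla_score,
               "age": rec.age, "sex": rec.sex}
        row.update(rec.features.values.to_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["participant_id", "ucla", "age", "sex"] + FEATURE_NAMES)
    return df
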