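"""Single-patient prediction from pair scores, expression values or Ct values.

Mirrors the semantics of an interactive predictor: for each pair
"miRNA-A|miRNA-B" in the model's schema the input is 0 if the expression
of A is below B and 1 otherwise. Raw values are converted through
:func:`mirpair.pairs.pair_score`; for Ct input the comparison is
inverted by default (lower Ct = higher expression), overridable with
``ct_invert=False`` for data already encoded in expression direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COPD, HEALTHY, SCALE_CT, SCALE_EXPRESSION, SCALES
from .errors import SchemaMismatchError, ValidationError
from .modeling import FittedClassifier
from .pairs import pair_score, split_pair


@dataclass
class PatientInput:
    """One patient's measurements: either pair scores or raw values."""

    pair_scores: dict[str, int] | None = None
    raw_values: dict[str, float] | None = None
    scale: str = SCALE_EXPRESSION

    def __post_init__(self) -> None:
        if (self.pair_scores is None) == (self.raw_values is None):
            raise ValidationError(
                "provide exactly one of pair_scores or raw_values"
            )
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.pair_scores is not None:
            bad = {p: s for p, s in self.pair_scores.items() if s not in (0, 1)}
            if bad:
                raise ValidationError(f"pair scores must be 0 or 1, got {bad}")


@dataclass
class Prediction:
    """Predicted class with the model's estimated COPD probability."""

    predicted_class: str
    probability: float  # P(COPD)
    model_id: str
    schema: list[str] = field(default_factory=list)
    scores: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:
        return (
            f"{self.predicted_class} (P(COPD) = {self.probability:.3f}, "
            f"model = {self.model_id})"
        )


def _scores_from_input(patient: PatientInput, schema: list[str], ct_invert: bool) -> dict[str, int]:
    if patient.pair_scores is not None:
        missing = [p for p in schema if p not in patient.pair_scores]
        if missing:
            raise SchemaMismatchError(f"input lacks pair score(s) for: {missing}")
        extras = sorted(set(patient.pair_scores) - set(schema))
        if extras:
            warnings.warn(f"ignoring out-of-schema pairs: {extras}", stacklevel=3)
        return {p: int(patient.pair_scores[p]) for p in schema}

    assert patient.raw_values is not None
    needed = sorted({m for p in schema for m in split_pair(p)})
    missing = [m for m in needed if m not in patient.raw_values]
    if missing:
        raise SchemaMismatchError(f"input lacks value(s) for miRNA(s): {missing}")
    extras = sorted(set(patient.raw_values) - set(needed))
    if extras:
        warnings.warn(f"ignoring out-of-schema miRNAs: {extras}", stacklevel=3)
    scale = patient.scale
    if scale == SCALE_CT and not ct_invert:
        scale = SCALE_EXPRESSION  # caller asserts values are already inverted
    return {
        p: pair_score(
            patient.raw_values[split_pair(p)[0]],
            patient.raw_values[split_pair(p)[1]],
            scale,
        )
        for p in schema
    }


def predict_patient(
    patient: PatientInput, model: FittedClassifier, ct_invert: bool = True
) -> Prediction:
    """Score one patient against a fitted model's pair schema.

    Deterministic: raw values are reduced to schema-ordered pair scores
    and passed to the model; the predicted class is COPD iff the
    estimated probability is >= 0.5.
    """
    scores = _scores_from_input(patient, model.feature_schema, ct_invert)
    X = pd.DataFrame(
        [[float(scores[p]) for p in model.feature_schema]],
        columns=model.feature_schema,
    )
    proba = model.model.predict_proba(X)
    pos_col = int(np.flatnonzero(np.asarray(model.model.classes_) == 1)[0])
    p_copd = float(proba[0, pos_col])
    return Prediction(
        predicted_class=COPD if p_copd >= 0.5 else HEALTHY,
        probability=p_copd,
        model_id=model.algorithm,
        schema=list(model.feature_schema),
        scores=scores,
    )
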