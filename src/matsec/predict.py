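"""Apply trained models to sequences; combined two-model decision.

A preprotein-view model (signal-peptide aware) and a mature-view model are
combined into a four-way verdict:

===========  ============  =======================================
preprotein   mature        verdict
===========  ============  =======================================
negative     negative      cytoplasmic
negative     positive¹     mature         (a mature domain on its own)
positive     positive²     secretory-preprotein
positive     negative²     non-secretory  (signal peptide, incompatible
                                           mature region)
===========  ============  =======================================

¹ mature model scored from position 1 (sequence assumed already mature);
² mature model scored from the estimated cleavage site.

The cleavage site itself is estimated by scanning candidate positions and
keeping the one whose downstream window maximises the mature-model
probability.  The decision boundary is closed: probability == threshold is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .encoders import build_feature_matrix
from .models import TrainedModel
from .seqio import MATURE_OFFSET, SequenceRecord, Window, window_from_position

VERDICTS = ("cytoplasmic", "mature", "secretory-preprotein", "non-secretory")


@dataclass
class Prediction:
    id: str
    probability_preprotein: Optional[float]
    probability_mature: Optional[float]
    estimated_cleavage: Optional[int]
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def _features_for_windows(
    model: TrainedModel, windows: Sequence[Window], energy_model=None
) -> np.ndarray:
    """Model-ready feature rows (selected columns, raw scale) for windows."""
    fm = build_feature_matrix(
        windows,
        groups=model.groups,
        energy_model=energy_model,
        cpseaac_scale=model.cpseaac["scale"],
        cpseaac_lam=model.cpseaac["lam"],
        cpseaac_w=model.cpseaac["w"],
    )
    index = {name: i for i, name in enumerate(fm.feature_names)}
    cols = []
    for name in model.selected_features:
        if name not in index:
            raise KeyError(f"model feature {name!r} cannot be computed for this input")
        cols.append(index[name])
    return fm.values[:, cols]


def score_window(model: TrainedModel, window: Window, energy_model=None) -> float:
    """Probability that the window belongs to the secretory class."""
    if window.length != model.window_length:
        raise ValueError(
            f"window length {window.length} does not match model "
            f"window length {model.window_length}"
        )
    X = _features_for_windows(model, [window], energy_model)
    return model.score(X[0])


def classify(
    model: TrainedModel,
    record: SequenceRecord,
    view: Optional[str] = None,
    energy_model=None,
) -> tuple[str, float]:
    """(label, probability) for one record under the model's view.

    Mature view uses the annotated cleavage position when present, else
    starts at position 1 (sequence assumed already mature).  Positive iff
    probability >= threshold.
    """
    view = view or model.view
    if view != model.view:
        raise ValueError(f"model was trained on view {model.view!r}, not {view!r}")
    if view == "mature" and record.cleavage_pos is not None:
        start = record.cleavage_pos + MATURE_OFFSET
    else:
        start = 1
    window = window_from_position(record, view, model.window_length, start)
    prob = score_window(model, window, energy_model)
    label = "secretory" if prob >= model.threshold else "cytoplasmic"
    return label, prob


def estimate_cleavage(
    pre_model: TrainedModel,
    mat_model: TrainedModel,
    record: SequenceRecord,
    candidate_range: tuple[int, int] = (15, 40),
    energy_model=None,
) -> int:
    """Estimate the cleavage position by scanning the mature model.

    For each candidate position p in ``candidate_range`` (inclusive), the
    mature model scores the window starting at p+3; the p maximising the
    probability wins, ties going to the smallest p.
    """
    lo, hi = candidate_range
    if lo > hi:
        raise ValueError("empty candidate range")
    if len(record.seq) <= lo + MATURE_OFFSET:
        raise ValueError(
            f"record {record.id!r}: sequence too short to place a cleavage site"
        )
    candidates = [p for p in range(lo, hi + 1) if p + MATURE_OFFSET <= len(record.seq)]
    windows = [
        window_from_position(record, "mature", mat_model.window_length, p + MATURE_OFFSET)
        for p in candidates
    ]
    X = _features_for_windows(mat_model, windows, energy_model)
    probs = mat_model.score_matrix(X)
    return candidates[int(np.argmax(probs))]


def combined_predict(
    pre_model: TrainedModel,
    mat_model: TrainedModel,
    record: SequenceRecord,
    candidate_range: tuple[int, int] = (15, 40),
    energy_model=None,
) -> Prediction:
    """Four-way decision from the preprotein and mature models."""
    pre_window = window_from_position(record, "preprotein", pre_model.window_length, 1)
    p_pre = score_window(pre_model, pre_window, energy_model)
    if p_pre < pre_model.threshold:
        mat_window = window_from_position(record, "mature", mat_model.window_length, 1)
        p_mat = score_window(mat_model, mat_window, energy_model)
        verdict = "mature" if p_mat >= mat_model.threshold else "cytoplasmic"
        return Prediction(record.id, p_pre, p_mat, None, verdict)
    est = estimate_cleavage(pre_model, mat_model, record, candidate_range, energy_model)
    mat_window = window_from_position(
        record, "mature", mat_model.window_length, est + MATURE_OFFSET
    )
    p_mat = score_window(mat_model, mat_window, energy_model)
    verdict = "secretory-preprotein" if p_mat >= mat_model.threshold else "non-secretory"
    return Prediction(record.id, p_pre, p_mat, est, verdict)


def predict_batch(
    records: Sequence[SequenceRecord],
    mat_model: TrainedModel,
    pre_model: Optional[TrainedModel] = None,
    candidate_range: tuple[int, int] = (15, 40),
    energy_model=None,
) -> list[Prediction]:
    """Predictions for many records; without a preprotein model only the
    mature model is applied (from position 1)."""
    out = []
    for rec in records:
        if pre_model is None:
            label, prob = classify(mat_model, rec, energy_model=energy_model)
            verdict = "mature" if label == "secretory" else "cytoplasmic"
            out.append(Prediction(rec.id, None, prob, None, verdict))
        else:
            out.append(
                combined_predict(pre_model, mat_model, rec, candidate_range, energy_model)
            )
    return out


def write_predictions(predictions: Sequence[Prediction], path) -> None:
    def fmt(x, digits=6):
        return "" if x is None else (f"{x:.{digits}f}" if isinstance(x, float) else str(x))

    with open(path, "w") as fh:
        fh.write("id\tprob_pre\tprob_mature\test_cleavage\tverdict\n")
        for p in predictions:
            fh.write(
                "\t".join(
                    [
                        p.id,
                        fmt(p.probability_preprotein),
                        fmt(p.probability_mature),
                        fmt(p.estimated_cleavage),
                        p.verdict,
                    ]
                )
                + "\n"
            )
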