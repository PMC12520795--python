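"""Ensemble combination of constituent model predictions.

Three schemes combine member scores:

* **EMmean** — unweighted arithmetic mean of member probabilities;
* **EMca** — committee averaging: the mean of member binary votes, each
  member voting at its own TSS-optimal threshold (outputs live on the
  lattice {k/m} for m members);
* **EMwmean** — TSS-weighted mean, with negative-TSS members floored to
  weight 0 (a poor model should not drag the ensemble; cutoff configurable).

Members are combined by a streaming running sum, so per-cell maps of many
members never materialize at once; the result is identical to the eager
stacked computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

SCHEMES = ("EMmean", "EMca", "EMwmean")


def combine_scores(
    member_scores: np.ndarray,
    scheme: str = "EMmean",
    thresholds: Sequence[float] | None = None,
    member_tss: Sequence[float] | None = None,
    tss_floor: float = 0.0,
) -> np.ndarray:
    """Combine a (n_members, ...) score array under one scheme."""
    member_scores = np.asarray(member_scores, dtype=float)
    m = member_scores.shape[0]
    if m == 0:
        raise ValueError("empty member list")
    if scheme == "EMmean":
        return member_scores.mean(axis=0)
    if scheme == "EMca":
        if thresholds is None or len(thresholds) != m:
            raise ValueError("EMca needs one TSS-optimal threshold per member")
        votes = member_scores >= np.reshape(np.asarray(thresholds, dtype=float), (m,) + (1,) * (member_scores.ndim - 1))
        return votes.mean(axis=0)
    if scheme == "EMwmean":
        if member_tss is None or len(member_tss) != m:
            raise ValueError("EMwmean needs one TSS value per member")
        w = np.asarray(member_tss, dtype=float)
        w = np.where(w > tss_floor, w, 0.0)
        total = w.sum()
        if total <= 0:
            raise ValueError("all EMwmean weights are zero")
        w = w / total
        return np.tensordot(w, member_scores, axes=(0, 0))
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


@dataclass
class EnsembleModel:
    """A score function that streams over member models.

    ``members`` are objects with ``predict_frame``/``predict_stack`` (any
    :class:`invasdm.engine.FittedModel`-like object). For EMca/EMwmean the
    per-member TSS-optimal thresholds / TSS values must be supplied.
    """

    ensemble_id: str
    members: list
    scheme: str = "EMmean"
    thresholds: list[float] | None = None
    member_tss: list[float] | None = None
    tss_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty member list")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "EMca" and (
            self.thresholds is None or len(self.thresholds) != len(self.members)
        ):
            raise ValueError("EMca needs one threshold per member")
        if self.scheme == "EMwmean":
            if self.member_tss is None or len(self.member_tss) != len(self.members):
                raise ValueError("EMwmean needs one TSS per member")
            w = np.asarray(self.member_tss, dtype=float)
            if not np.any(w > self.tss_floor):
                raise ValueError("all EMwmean weights are zero")

    def _weights(self) -> np.ndarray:
        w = np.asarray(self.member_tss, dtype=float)
        w = np.where(w > self.tss_floor, w, 0.0)
        return w / w.sum()

    def _stream(self, predict: Callable) -> np.ndarray:
        """Running-sum combination; identical to eager stacking."""
        acc = None
        if self.scheme == "EMwmean":
            weights = self._weights()
        for i, member in enumerate(self.members):
            s = predict(member)
            if self.scheme == "EMmean":
                term = s / len(self.members)
            elif self.scheme == "EMca":
                term = (s >= self.thresholds[i]).astype(float) / len(self.members)
            else:
                term = weights[i] * s
            acc = term if acc is None else acc + term
        return acc

    def predict_frame(self, frame) -> np.ndarray:
        return self._stream(lambda m: m.predict_frame(frame))

    def predict_stack(self, stack) -> np.ndarray:
        return self._stream(lambda m: m.predict_stack(stack))


def algorithm_ensemble(ensemble_id: str, members: Iterable) -> EnsembleModel:
    """Per-algorithm EMmean over all constituent fits of one algorithm."""
    return EnsembleModel(ensemble_id=ensemble_id, members=list(members), scheme="EMmean")


def global_ensemble(
    ensemble_id: str,
    members: Iterable,
    scheme: str,
    thresholds: Sequence[float] | None = None,
    member_tss: Sequence[float] | None = None,
    tss_floor: float = 0.0,
) -> EnsembleModel:
    """Global ensemble pooling all algorithms x PA sets x reps."""
    return EnsembleModel(
        ensemble_id=ensemble_id,
        members=list(members),
        scheme=scheme,
        thresholds=list(thresholds) if thresholds is not None else None,
        member_tss=list(member_tss) if member_tss is not None else None,
        tss_floor=tss_floor,
    )
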