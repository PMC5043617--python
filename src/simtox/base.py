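"""Shared result types."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class PredictionResult:
    """Per-record continuous activity score in [0,1] plus hard class.

    ``score`` is probability-like evidence for the active class; the hard
    class is ``score >= threshold`` (default 0.5).  ``method`` records
    provenance (e.g. ``"5NN"``, ``"RF"``, ``"ensemble(min)"``).
    """

    id: str
    score: float
    predicted_class: int
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0,1] for {self.id!r}")
        if self.predicted_class not in (0, 1):
            raise ValueError("predicted_class must be 0 or 1")


def make_result(rec_id: str, score: float, method: str, threshold: float = 0.5) -> PredictionResult:
    return PredictionResult(
        id=rec_id,
        score=float(score),
        predicted_class=int(score >= threshold),
        method=method,
    )
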