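"""Fixed-dimension patient representations shared by both vectorisers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PatientVector:
    """One patient's pre-index history as a real vector.

    ``values`` has length ``d_model`` for the Transformer encoder and the
    vocabulary length for the TF-IDF baseline; ``vectoriser`` tags the origin.
    """

    values: np.ndarray
    patient_id: str
    vectoriser: str
    flagged: bool = False  # e.g. empty history / all-out-of-vocabulary

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite patient vector for {self.patient_id}")


def stack(vectors: list[PatientVector]) -> tuple[np.ndarray, list[str]]:
    """Stack patient vectors row-wise, returning the matrix and the id order."""
    if not vectors:
        raise ValueError("no vectors to stack")
    mat = np.vstack([v.values for v in vectors])
    return mat, [v.patient_id for v in vectors]
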