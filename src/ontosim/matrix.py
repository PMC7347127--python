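"""Labelled similarity matrix shared by term- and entity-level measures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SimilarityMatrix:
    """A labelled matrix of similarity scores.

    Square and symmetric when ``row_labels == col_labels``; ``measure``
    records provenance (e.g. ``"lin"`` or ``"bma(lin)"``) and is written as
    a header comment on export.
    """

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    measure: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels

    def loc(self, row: str, col: str) -> float:
        return float(
            self.values[self.row_labels.index(row), self.col_labels.index(col)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=self.col_labels
        )


@dataclass
class TermMeasureConfig:
    """Selection of a between-term measure.

    ``wang_weights`` are the hybrid measure's semantic contribution factors
    per relation type (defaults 0.8 for ``is_a``, 0.6 for ``part_of``);
    ``normalize_resnik`` rescales Resnik scores by the namespace maximum IC
    into [0, 1] for thresholding.
    """

    name: str = "resnik"
    wang_weights: dict[str, float] = field(
        default_factory=lambda: {"is_a": 0.8, "part_of": 0.6}
    )
    normalize_resnik: bool = False

    def __post_init__(self):
        if self.name not in TERM_MEASURES:
            raise ValueError(
                f"unknown term measure {self.name!r}; choose from {sorted(TERM_MEASURES)}"
            )
        for rel, w in self.wang_weights.items():
            if not 0 < w < 1:
                raise ValueError(f"wang weight for {rel!r} must be in (0,1), got {w}")


TERM_MEASURES = (
    "resnik",
    "lin",
    "jc",
    "rel",
    "resnik_grasm",
    "lin_grasm",
    "jc_grasm",
    "rel_grasm",
    "wu2005",
    "yu2005",
    "wang2007",
)
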