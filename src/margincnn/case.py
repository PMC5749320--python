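"""Core domain objects shared across the pipeline.

A :class:`NoduleCase` bundles one grayscale ultrasound image of a thyroid
follicular neoplasm with the closed contour outlining the nodule margin, the
histology label (benign adenoma vs. carcinoma) and a cohort tag identifying
the acquiring clinic. All in-memory coordinates are 0-based ``(row, col)``
with the origin at the top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ADENOMA = "adenoma"
CARCINOMA = "carcinoma"
LABELS = (ADENOMA, CARCINOMA)


class CaseValidationError(ValueError):
    """A nodule case violates a structural invariant."""


@dataclass
class NoduleCase:
    """One nodule: image, margin contour, label and cohort tag.

    Parameters
    ----------
    case_id : str
        Unique identifier.
    image : numpy.ndarray
        2-D uint8 array, intensities in [0, 255].
    contour : numpy.ndarray
        ``(n, 2)`` integer array of ``(row, col)`` points outlining the
        nodule margin. May be sparse polygon vertices (as read from an
        annotation file) or an already pixel-dense closed path; patch
        extraction densifies either.
    label : str
        ``"adenoma"`` or ``"carcinoma"``.
    cohort : str
        Clinic/cohort tag (e.g. ``"A"``, ``"B"``).
    """

    case_id: str
    image: np.ndarray
    contour: np.ndarray
    label: str
    cohort: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.contour = np.asarray(self.contour, dtype=np.int64)

    def validate(self) -> "NoduleCase":
        if self.image.ndim != 2:
            raise CaseValidationError(
                f"case {self.case_id!r}: image must be 2-D, got shape {self.image.shape}"
            )
        if self.image.dtype != np.uint8:
            raise CaseValidationError(
                f"case {self.case_id!r}: image must be uint8, got {self.image.dtype}"
            )
        if self.label not in LABELS:
            raise CaseValidationError(
                f"case {self.case_id!r}: unknown label {self.label!r}"
            )
        if self.contour.ndim != 2 or self.contour.shape[1] != 2 or len(self.contour) < 3:
            raise CaseValidationError(
                f"case {self.case_id!r}: contour must be an (n>=3, 2) point array"
            )
        h, w = self.image.shape
        r, c = self.contour[:, 0], self.contour[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() >= h or c.max() >= w:
            bad = self.contour[(r < 0) | (c < 0) | (r >= h) | (c >= w)][0]
            raise CaseValidationError(
                f"case {self.case_id!r}: contour point {tuple(bad)} outside "
                f"{h}x{w} image"
            )
        return self
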