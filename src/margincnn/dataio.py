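"""Reading and writing images, contour annotations and dataset manifests.

This module is the single owner of on-disk coordinate conventions:

* images are lossless 8-bit grayscale PNG (canonical) or BMP (accepted on
  read, since clinical exports are often bitmaps); in memory they are
  ``(row, col)`` uint8 arrays, origin top-left;
* contour files are JSON with vertices stored as ``[x, y] = [col, row]``
  (the usual annotation-tool convention); the x/y -> row/col swap happens
  here and nowhere else;
* a dataset manifest is a CSV with columns
  ``case_id, image_path, contour_path, label, cohort``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .case import LABELS, CaseValidationError, NoduleCase

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["case_id", "image_path", "contour_path", "label", "cohort"]


class UnsupportedDepthError(ValueError):
    """Image file is not (collapsible to) single-channel 8-bit."""


class ContourFormatError(ValueError):
    """Contour annotation file is malformed."""


class ManifestError(ValueError):
    """Dataset manifest is malformed or inconsistent."""


def read_image(path) -> np.ndarray:
    """Read a grayscale 8-bit image as a ``(row, col)`` uint8 array.

    Multi-channel inputs whose channels are all identical (a common export
    artifact) are collapsed to one channel; anything else, and any bit depth
    other than 8, is rejected.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise UnsupportedDepthError(
                f"{path}: unsupported bit depth (mode {im.mode}); expected 8-bit grayscale"
            )
        arr = np.asarray(im)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop a fully-opaque alpha channel
            if not np.all(arr[..., 3] == 255):
                raise UnsupportedDepthError(f"{path}: non-trivial alpha channel")
            arr = arr[..., :3]
        if not (arr[..., :1] == arr).all():
            raise UnsupportedDepthError(
                f"{path}: color image with differing channels cannot be collapsed"
            )
        arr = arr[..., 0]
    if arr.dtype != np.uint8:
        raise UnsupportedDepthError(f"{path}: dtype {arr.dtype} is not 8-bit")
    return arr


def write_image(path, image: np.ndarray) -> None:
    """Write a 2-D uint8 array as PNG (or BMP, by extension)."""
    image = np.asarray(image)
    if image.ndim != 2 or image.dtype != np.uint8:
        raise ValueError("write_image expects a 2-D uint8 array")
    Image.fromarray(image, mode="L").save(Path(path))


def read_contour(path) -> tuple[np.ndarray, dict]:
    """Read a contour JSON file.

    Returns
    -------
    vertices : numpy.ndarray
        ``(n, 2)`` integer array of ``(row, col)`` vertices, in file order,
        verbatim (no closure or densification — that is the patch sampler's
        job).
    meta : dict
        ``case_id``, ``label``, ``cohort`` from the file.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ContourFormatError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("case_id", "label", "cohort", "contour"):
        if key not in doc:
            raise ContourFormatError(f"{path}: missing field {key!r}")
    pts = doc["contour"]
    if not isinstance(pts, list) or len(pts) < 3:
        raise ContourFormatError(f"{path}: contour needs at least 3 vertices")
    try:
        xy = np.asarray(pts, dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise ContourFormatError(f"{path}: non-integer contour vertices") from exc
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ContourFormatError(f"{path}: contour must be a list of [x, y] pairs")
    vertices = xy[:, ::-1].copy()  # [x, y] -> (row, col)
    meta = {k: doc[k] for k in ("case_id", "label", "cohort")}
    return vertices, meta


def write_contour(path, vertices: np.ndarray, case_id: str, label: str, cohort: str) -> None:
    """Write a contour JSON file; vertices given as ``(row, col)``."""
    vertices = np.asarray(vertices, dtype=np.int64)
    doc = {
        "case_id": case_id,
        "label": label,
        "cohort": cohort,
        "contour": [[int(c), int(r)] for r, c in vertices],
    }
    Path(path).write_text(json.dumps(doc))


def write_dataset(cases, out_dir) -> Path:
    """Persist cases as PNG + contour JSON + manifest CSV; return manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        img_name = f"{case.case_id}.png"
        ctr_name = f"{case.case_id}.json"
        write_image(out_dir / img_name, case.image)
        write_contour(out_dir / ctr_name, case.contour, case.case_id, case.label, case.cohort)
        rows.append(
            {
                "case_id": case.case_id,
                "image_path": img_name,
                "contour_path": ctr_name,
                "label": case.label,
                "cohort": case.cohort,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_manifest(path) -> list[NoduleCase]:
    """Load a manifest CSV and pair every row into a validated NoduleCase.

    Paths in the manifest are resolved relative to the manifest's directory.
    Row order is preserved. Raises :class:`ManifestError` on duplicate ids,
    unknown labels, or contours falling outside their image.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    dup = df["case_id"][df["case_id"].duplicated()]
    if len(dup):
        raise ManifestError(f"{path}: duplicate case_id {dup.iloc[0]!r}")
    base = path.parent
    cases = []
    for row in df.itertuples(index=False):
        if row.label not in LABELS:
            raise ManifestError(f"case {row.case_id!r}: unknown label {row.label!r}")
        image = read_image(base / row.image_path)
        vertices, _ = read_contour(base / row.contour_path)
        case = NoduleCase(row.case_id, image, vertices, row.label, row.cohort)
        try:
            case.validate()
        except CaseValidationError as exc:
            raise ManifestError(str(exc)) from exc
        cases.append(case)
    counts = df.groupby(["label", "cohort"]).size()
    logger.info("loaded %d cases from %s:\n%s", len(cases), path, counts.to_string())
    return cases
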