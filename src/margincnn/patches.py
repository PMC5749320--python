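"""Margin-patch extraction.

The nodule margin is given as a closed contour. Test-time patches are square
blocks centered at *every* pixel of the densified contour; training patches
are a small, deterministic selection of "distinctive" blocks (highest
intensity variance, greedily spaced along the contour).

Even-size center convention: a ``size`` x ``size`` window centered at
``(r, c)`` covers rows ``[r - size//2, r + size//2)`` and the analogous
column range (half-open). Windows that would leave the image are discarded,
not padded: padding would inject non-ultrasound statistics into the margin
band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _bresenham_line

from .case import NoduleCase


class ContourError(ValueError):
    """Contour violates the dense-path invariants."""


@dataclass
class Contour:
    """Pixel-dense closed margin path.

    ``points`` is an ``(n, 2)`` integer array of ``(row, col)`` positions in
    which consecutive points (and last-to-first) are 8-adjacent and no two
    consecutive points coincide.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.points)

    def validate(self) -> "Contour":
        pts = self.points
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ContourError("dense contour needs >= 3 (row, col) points")
        diff = np.abs(np.diff(np.vstack([pts, pts[:1]]), axis=0))
        if diff.max() > 1:
            k = int(np.argmax(diff.max(axis=1) > 1))
            raise ContourError(f"points {k} and {k + 1} are not 8-adjacent")
        if (diff.max(axis=1) == 0).any():
            raise ContourError("consecutive duplicate points")
        return self

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class Patch:
    """A square intensity block centered on a margin pixel."""

    pixels: np.ndarray  # (size, size) uint8
    center: tuple[int, int]  # (row, col)
    case_id: str

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def densify_polygon(vertices) -> Contour:
    """Rasterize polygon vertices into a pixel-dense closed contour.

    Each consecutive vertex pair (and last back to first) is rasterized with
    an 8-connected Bresenham line; segment endpoints are deduplicated so the
    result has no consecutive repeats. Feeding an already-dense closed path
    back in returns it unchanged.
    """
    vertices = np.asarray(vertices, dtype=np.int64)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise ContourError("polygon needs >= 3 (row, col) vertices")
    if len(np.unique(vertices, axis=0)) < 3:
        raise ContourError("degenerate polygon: fewer than 3 distinct pixels")
    runs = []
    n = len(vertices)
    for i in range(n):
        r0, c0 = vertices[i]
        r1, c1 = vertices[(i + 1) % n]
        rr, cc = _bresenham_line(int(r0), int(c0), int(r1), int(c1))
        runs.append(np.column_stack([rr, cc])[:-1])  # drop endpoint: next run starts there
    pts = np.concatenate([run for run in runs if len(run)], axis=0)
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    pts = pts[keep]
    if len(pts) < 3:
        raise ContourError("degenerate polygon: rasterized path shorter than 3 pixels")
    return Contour(pts).validate()


def dense_contour(case: NoduleCase) -> Contour:
    """The case's contour as a validated dense path (densifying if needed)."""
    return densify_polygon(case.contour)


def _window_bounds(center, size):
    half = size // 2
    r, c = center
    return r - half, r - half + size, c - half, c - half + size


def extract_test_patches(
    case: NoduleCase, size: int = 50
) -> tuple[list[Patch], int]:
    """One candidate patch per contour pixel; out-of-bounds windows discarded.

    Returns the kept patches in contour order and the number of discarded
    candidates, so ``kept + discarded == len(contour)``.
    """
    h, w = case.image.shape
    if size > min(h, w):
        raise ValueError(f"patch size {size} exceeds image dimensions {h}x{w}")
    contour = dense_contour(case)
    patches: list[Patch] = []
    discarded = 0
    for r, c in contour.points:
        r0, r1, c0, c1 = _window_bounds((r, c), size)
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            discarded += 1
            continue
        patches.append(Patch(case.image[r0:r1, c0:c1], (int(r), int(c)), case.case_id))
    return patches, discarded


def select_training_patches(
    case: NoduleCase,
    size: int = 50,
    k: int = 18,
    min_spacing: int = 5,
    seed: int | None = None,
) -> list[Patch]:
    """Deterministic surrogate for manual "distinctive patch" selection.

    Candidates are the in-bounds test patches; each is scored by the
    intensity standard deviation of its pixels. The top-scoring patch is
    kept, then candidates within ``min_spacing`` path-steps (along the
    closed contour, circular distance) of any kept center are barred, and
    the greedy scan repeats until ``k`` patches are kept or candidates run
    out (a warning is emitted when fewer than ``k`` are feasible). Ties in
    score are broken by contour order, so the result is fully deterministic;
    ``seed`` is accepted for interface symmetry but unused by the default
    variance ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    contour = dense_contour(case)
    n_path = len(contour)
    h, w = case.image.shape
    candidates = []  # (path index, patch)
    for idx, (r, c) in enumerate(contour.points):
        r0, r1, c0, c1 = _window_bounds((r, c), size)
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            continue
        candidates.append((idx, Patch(case.image[r0:r1, c0:c1], (int(r), int(c)), case.case_id)))
    if not candidates:
        raise ValueError(f"case {case.case_id!r}: no in-bounds patch candidates")
    scores = np.array([p.pixels.astype(np.float64).std() for _, p in candidates])
    order = np.lexsort((np.array([i for i, _ in candidates]), -scores))
    kept: list[Patch] = []
    kept_idx: list[int] = []
    for j in order:
        if len(kept) == k:
            break
        idx = candidates[j][0]
        d = np.abs(np.array(kept_idx) - idx) if kept_idx else np.array([])
        if len(d) and (np.minimum(d, n_path - d) < min_spacing).any():
            continue
        kept.append(candidates[j][1])
        kept_idx.append(idx)
    if len(kept) < k:
        warnings.warn(
            f"case {case.case_id!r}: only {len(kept)} of {k} training patches "
            f"feasible under min_spacing={min_spacing}",
            stacklevel=2,
        )
    return kept


def inset_contour(contour, inset: float) -> np.ndarray:
    """Move every contour point radially toward the centroid by ``inset`` px.

    Used for interior-control experiments: patches centered on the inset
    path sample the nodule interior instead of the margin band. Returns
    integer polygon vertices (densify before use).
    """
    contour = Contour(np.asarray(contour)) if not isinstance(contour, Contour) else contour
    pts = contour.points.astype(np.float64)
    ctr = pts.mean(axis=0)
    vec = pts - ctr
    dist = np.hypot(vec[:, 0], vec[:, 1])
    if (dist <= inset).any():
        raise ValueError("inset exceeds the contour's distance to its centroid")
    scale = (dist - inset) / dist
    inner = np.rint(ctr + vec * scale[:, None]).astype(np.int64)
    keep = np.any(inner != np.roll(inner, 1, axis=0), axis=1)
    return inner[keep]
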