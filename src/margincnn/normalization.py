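"""Patch normalization: mean-zero min-max for training, alpha-scaled for test.

All statistics (min, max, mean) are computed over the pixels of the patch
itself, which is the only reading under which the alpha = 0 test
normalization reduces exactly to plain min-max scaling, and which keeps
train and test preprocessing self-contained per patch.

Training normalization (``u`` the raw patch):

.. math:: v_{ij} = \\frac{u_{ij} - \\min u}{\\max u - \\min u} - m
          = \\frac{u_{ij} - E[u]}{\\max u - \\min u}

where ``m`` is the mean of the min-max-scaled values, so the output is
exactly zero-mean with values in [-1, 1].

Test normalization with scaling parameter alpha (``p`` the raw patch):

.. math:: q_{ij} = \\frac{p_{ij} + \\alpha\\,E[p] - \\min p}{\\max p - \\min p}

At alpha = 0 this is min-max scaling to [0, 1]; for alpha != 0 every pixel
is shifted by the same amount ``alpha * E[p] / (max p - min p)``, so the
output is affine (and nondecreasing, for nonnegative data) in alpha.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


class DegeneratePatchError(ValueError):
    """Constant patch: min == max, normalization undefined."""


def _as_float(patch) -> np.ndarray:
    arr = getattr(patch, "pixels", patch)
    return np.asarray(arr, dtype=np.float64)


def _stats(arr: np.ndarray):
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise DegeneratePatchError(
            f"constant patch (all pixels == {lo!r}): min-max normalization undefined"
        )
    return lo, hi, arr.mean()


def normalize_train(patch, variant: str = "scaled") -> np.ndarray:
    """Mean-zero min-max normalization of a training patch.

    ``variant="scaled"`` (default) scales to [0, 1] then subtracts the mean
    of the scaled values; ``variant="literal"`` applies
    ``(u - E[u] - min) / (max - min)`` instead (a sensitivity-check variant
    that differs from the default by a constant ``min / (max - min)``).
    """
    arr = _as_float(patch)
    lo, hi, mean = _stats(arr)
    if variant == "scaled":
        return (arr - mean) / (hi - lo)
    if variant == "literal":
        return (arr - mean - lo) / (hi - lo)
    raise ValueError(f"unknown variant {variant!r}")


def normalize_test(patch, alpha: float) -> np.ndarray:
    """Alpha-parameterized min-max normalization of a test patch."""
    arr = _as_float(patch)
    lo, hi, mean = _stats(arr)
    return (arr + alpha * mean - lo) / (hi - lo)


def normalize_batch(
    patches, mode: str = "test", alpha: float = 0.0, variant: str = "scaled"
) -> tuple[np.ndarray, int]:
    """Normalize a sequence of patches into an ``(n, size, size)`` array.

    Degenerate (constant) patches are dropped, not imputed; the second
    return value is the number dropped.
    """
    out, dropped = [], 0
    for p in patches:
        try:
            if mode == "train":
                out.append(normalize_train(p, variant=variant))
            elif mode == "test":
                out.append(normalize_test(p, alpha))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        except DegeneratePatchError:
            dropped += 1
    if out:
        return np.stack(out), dropped
    return np.empty((0, 0, 0)), dropped


class AlphaMinMaxScaler(TransformerMixin, BaseEstimator):
    """Per-patch normalization as a stateless sklearn transformer.

    Parameters
    ----------
    mode : {"test", "train"}
        ``"train"`` applies the mean-zero min-max normalization;
        ``"test"`` the alpha-parameterized variant.
    alpha : float
        Scaling parameter (test mode only).
    variant : {"scaled", "literal"}
        Training-formula variant, see :func:`normalize_train`.

    The transformer keeps no fitted state (all statistics are per patch);
    ``fit`` validates parameters and returns ``self``.
    """

    def __init__(self, mode: str = "test", alpha: float = 0.0, variant: str = "scaled"):
        self.mode = mode
        self.alpha = alpha
        self.variant = variant

    def fit(self, X, y=None):
        if self.mode not in ("train", "test"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.variant not in ("scaled", "literal"):
            raise ValueError(f"unknown variant {self.variant!r}")
        self.n_features_in_ = np.prod(np.asarray(X).shape[1:], dtype=int) if len(X) else 0
        return self

    def transform(self, X) -> np.ndarray:
        """Normalize a stack of patches ``(n, size, size)`` patch-by-patch."""
        X = np.asarray(X)
        if self.mode == "train":
            return np.stack([normalize_train(x, variant=self.variant) for x in X]) if len(X) else X.astype(np.float64)
        return np.stack([normalize_test(x, self.alpha) for x in X]) if len(X) else X.astype(np.float64)
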