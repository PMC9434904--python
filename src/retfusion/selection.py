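"""Checkpoint selection by Fréchet distance between feature distributions.

Every saved generator translates the held-out sources; real targets and
synthesized images are embedded into a feature space, each set is fitted
with a Gaussian (mean, covariance), and the Fréchet distance

    FID = ||mu_r - mu_s||^2 + Tr(S_r + S_s - 2 (S_r S_s)^{1/2})

scores the checkpoint; lower is better and the argmin (earliest on ties,
to avoid over-trained generators) is selected.

The embedding is pluggable.  The default desk extractor — resize to 32x32
grayscale, flatten, project through a fixed seeded random matrix to 64
dimensions — is deterministic and dependency-free; an inception-style
pretrained extractor can be plugged in where fidelity to the original FID
matters.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import NumericalError, ParameterError, StatsUndefined
from .image import as_pixels, gray_float, resize_image

_PSD_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class GaussianStats:
    """Gaussian fit of an embedded image set: mean vector and covariance."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu, dtype=np.float64))
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=np.float64))
        if sigma.shape != (mu.size, mu.size):
            raise ParameterError("sigma must be d x d with d = len(mu)")
        if not np.allclose(sigma, sigma.T, atol=1e-8):
            raise ParameterError("sigma must be symmetric")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", (sigma + sigma.T) / 2.0)


@dataclasses.dataclass(frozen=True)
class FIDCurve:
    """FID per checkpoint epoch; best_index = argmin (earliest on ties)."""

    epochs: tuple
    scores: tuple

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.scores))  # argmin takes the first minimum

    @property
    def best_epoch(self) -> int:
        return self.epochs[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, "fid": self.scores})


class DeskExtractor:
    """Deterministic fixed embedding: 32x32 gray -> random 64-d projection."""

    def __init__(self, out_dim: int = 64, patch: int = 32, seed: int = 12345):
        rng = np.random.default_rng(seed)
        self.patch = patch
        self.proj = rng.standard_normal((patch * patch, out_dim)) / np.sqrt(patch * patch)

    def __call__(self, images) -> np.ndarray:
        rows = []
        for img in images:
            g = gray_float(as_pixels(img))
            if g.shape != (self.patch, self.patch):
                g = gray_float(resize_image(g, self.patch, self.patch).pixels)
            rows.append((g.ravel() / 255.0) @ self.proj)
        return np.asarray(rows)


def embed_images(images, extractor=None) -> np.ndarray:
    """Embed a set of images into feature rows (one per image)."""
    images = list(images)
    if len(images) < 2:
        raise StatsUndefined("need at least 2 images to fit feature statistics")
    extractor = extractor or DeskExtractor()
    feats = np.asarray(extractor(images), dtype=np.float64)
    if feats.ndim != 2 or feats.shape[0] != len(images):
        raise ParameterError("extractor must return one row per image")
    return feats


def gaussian_stats(features: np.ndarray) -> GaussianStats:
    """Sample mean and unbiased sample covariance of feature rows."""
    f = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if f.shape[0] < 2:
        raise StatsUndefined("need at least 2 feature rows")
    return GaussianStats(f.mean(axis=0), np.cov(f, rowvar=False).reshape(
        f.shape[1], f.shape[1]))


def frechet_distance(a: GaussianStats, b: GaussianStats) -> float:
    """Fréchet distance between two Gaussians.

    The cross term Tr((sigma_a sigma_b)^{1/2}) is computed on the
    symmetrized product sigma_a^{1/2} sigma_b sigma_a^{1/2} (same trace,
    PSD by construction) via eigendecomposition; small negative
    eigenvalues (numerical noise) are clamped to zero, larger ones raise.
    """
    if a.mu.size != b.mu.size:
        raise ParameterError("feature dimensions differ")
    eigs = []
    for s in (a.sigma, b.sigma):
        w, v = np.linalg.eigh(s)
        if w.min() < -_PSD_TOL * max(abs(w).max(), 1.0):
            raise NumericalError("covariance is not PSD within tolerance")
        eigs.append((np.clip(w, 0.0, None), v))
    diff = a.mu - b.mu
    wa, va = eigs[0]
    sqrt_a = (va * np.sqrt(wa)) @ va.T
    sym = sqrt_a @ b.sigma @ sqrt_a
    sym = (sym + sym.T) / 2.0
    w = scipy.linalg.eigvalsh(sym)
    if w.min() < -_PSD_TOL * max(abs(w).max(), 1.0):
        raise NumericalError("product matrix far from PSD")
    tr_sqrt = np.sqrt(np.clip(w, 0.0, None)).sum()
    fid = float(diff @ diff + np.trace(a.sigma) + np.trace(b.sigma) - 2.0 * tr_sqrt)
    return max(fid, 0.0)


def fid_between(real_images, synth_images, extractor=None) -> float:
    """FID between two image sets (embed -> fit -> Fréchet)."""
    return frechet_distance(gaussian_stats(embed_images(real_images, extractor)),
                            gaussian_stats(embed_images(synth_images, extractor)))


def select_best_checkpoint(checkpoints, real_targets, sources,
                           extractor=None) -> FIDCurve:
    """Score every checkpoint by FID of its translations vs real targets."""
    from .translator import translate

    if len(checkpoints) < 1:
        raise ParameterError("need at least one checkpoint")
    extractor = extractor or DeskExtractor()
    real_feats = gaussian_stats(embed_images(real_targets, extractor))
    epochs, scores = [], []
    for i in range(len(checkpoints)):
        gen = checkpoints.generator_at(i)
        synth = [translate(gen, s) for s in sources]
        score = frechet_distance(real_feats,
                                 gaussian_stats(embed_images(synth, extractor)))
        epochs.append(checkpoints.epochs[i])
        scores.append(score)
    return FIDCurve(tuple(epochs), tuple(scores))
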