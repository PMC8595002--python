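"""Multiscale PCA denoising.

Each channel is decomposed with a level-5 orthogonal Daubechies DWT; at
every scale the coefficient matrix (coefficient index x channel) undergoes a
PCA across channels, low-variance components are dropped under the chosen
retention rule, coefficients are rebuilt from the survivors, and the
channels are resynthesized.  With retention "none" the whole operation is
the identity to floating-point precision.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import EEGSegment, PCAResult, ValidationError, WaveletSpec
from .wavelets import daubechies_filters, wavedec, waverec

__all__ = ["MSPCAConfig", "pca_decompose", "retain_components", "denoise"]

RETENTION_RULES = ("kaiser", "fixed_k", "none")


@dataclass
class MSPCAConfig:
    wavelet: WaveletSpec = field(
        default_factory=lambda: WaveletSpec("db", 4, 5))
    retention_rule: str = "kaiser"
    fixed_k: int | None = None
    center: bool = True
    #: also PCA-process the final approximation band (see denoise docstring)
    process_approximation: bool = True

    def __post_init__(self):
        if self.retention_rule not in RETENTION_RULES:
            raise ValidationError(
                f"retention_rule must be one of {RETENTION_RULES}")
        if self.retention_rule == "fixed_k" and (
                self.fixed_k is None or self.fixed_k < 1):
            raise ValidationError("fixed_k must be a positive integer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wavelet"] = dataclasses.asdict(self.wavelet)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MSPCAConfig":
        d = dict(d)
        if "wavelet" in d:
            d["wavelet"] = WaveletSpec(**d["wavelet"])
        return cls(**d)


def pca_decompose(X: np.ndarray, center: bool = True) -> PCAResult:
    """Full PCA of ``X`` (observations x variables).

    Eigendecomposition of the sample covariance (divisor n - 1); scores are
    the centered data projected on the loadings.  All components are
    retained, so the residual is zero.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (observations x variables)")
    n, m = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 observations")
    if m < 1:
        raise ValidationError("PCA needs at least 1 variable")
    mean = X.mean(axis=0, keepdims=True) if center else np.zeros((1, m))
    Xc = X - mean
    cov = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order]
    scores = Xc @ loadings
    return PCAResult(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigvals,
        n_retained=m,
        residual=np.zeros_like(X),
        mean=mean,
    )


def retain_components(result: PCAResult, rule: str,
                      fixed_k: int | None = None) -> PCAResult:
    """Apply a retention rule, zeroing trailing components from the model.

    kaiser keeps eigenvalues strictly above their mean (at least one, so a
    degenerate all-equal spectrum keeps the first component); fixed_k keeps
    exactly k; none keeps everything.
    """
    if rule not in RETENTION_RULES:
        raise ValidationError(f"unknown retention rule {rule!r}")
    m = result.loadings.shape[1]
    if rule == "none":
        k = m
    elif rule == "fixed_k":
        if fixed_k is None or not (1 <= fixed_k <= m):
            raise ValidationError(
                f"fixed_k must lie in [1, {m}], got {fixed_k}")
        k = fixed_k
    else:  # kaiser
        lam = result.eigenvalues
        k = int(np.sum(lam > lam.mean()))
        if k == 0:
            k = 1
    retained = result.scores[:, :k] @ result.loadings[:, :k].T
    residual = (result.scores @ result.loadings.T) - retained
    return PCAResult(
        loadings=result.loadings,
        scores=result.scores,
        eigenvalues=result.eigenvalues,
        n_retained=k,
        residual=residual,
        mean=result.mean,
    )


def _denoise_band(coeffs: np.ndarray, config: MSPCAConfig) -> np.ndarray:
    """PCA-filter one coefficient matrix (coefficient index x channel)."""
    if coeffs.shape[0] < 2:
        return coeffs
    result = pca_decompose(coeffs, center=config.center)
    result = retain_components(result, config.retention_rule, config.fixed_k)
    return result.reconstruct()


def denoise(segment: EEGSegment, config: MSPCAConfig | None = None
            ) -> EEGSegment:
    """MSPCA-denoise one trial; shape, rate, label and subject are kept.

    A single-channel segment passes through unchanged (PCA across one
    variable is the identity) with a warning.
    """
    config = config or MSPCAConfig()
    level = config.wavelet.level
    if segment.n_samples < 2 ** level:
        raise ValidationError(
            f"segment of {segment.n_samples} samples too short for "
            f"level {level}")
    if segment.n_channels == 1 and config.retention_rule != "none":
        warnings.warn("single-channel segment: MSPCA is a pass-through",
                      stacklevel=2)
        return EEGSegment(segment.samples.copy(), segment.rate, segment.label,
                          segment.subject, segment.channel_names)

    lo, hi = daubechies_filters(config.wavelet.order)
    per_channel = []
    lengths = None
    for ch in range(segment.n_channels):
        bands, lengths = wavedec(segment.samples[ch], lo, hi, level)
        per_channel.append(bands)

    n_bands = level + 1  # D1..Dlevel, A_level
    cleaned = [[None] * n_bands for _ in range(segment.n_channels)]
    for b in range(n_bands):
        is_approx = b == level
        mat = np.column_stack([per_channel[ch][b]
                               for ch in range(segment.n_channels)])
        if is_approx and not config.process_approximation:
            out = mat
        else:
            out = _denoise_band(mat, config)
        for ch in range(segment.n_channels):
            cleaned[ch][b] = out[:, ch]

    rebuilt = np.vstack([
        waverec(cleaned[ch], lengths, lo, hi)
        for ch in range(segment.n_channels)])
    return EEGSegment(rebuilt, segment.rate, segment.label,
                      segment.subject, segment.channel_names)
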