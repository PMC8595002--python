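"""Domain types shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_LABELS = frozenset({1, 2})

#: Minimum trial length: the deepest analysis used anywhere is level 5.
MIN_SAMPLES = 32

#: Canonical per-subband statistic order.
STAT_NAMES = ("mav", "pow", "std", "skew", "kurt")

N_SUBBANDS = 16
N_FEATURES = 95

#: Canonical feature-column names: sb01_mav ... sb16_kurt, ratio_01 ... ratio_15.
FEATURE_NAMES = tuple(
    f"sb{b + 1:02d}_{s}" for b in range(N_SUBBANDS) for s in STAT_NAMES
) + tuple(f"ratio_{i + 1:02d}" for i in range(N_SUBBANDS - 1))


class ValidationError(ValueError):
    """Raised when a domain object violates its contract."""


@dataclass
class WaveletSpec:
    """A discrete wavelet choice: family, order within the family, depth."""

    family: str = "db"
    order: int = 4
    level: int = 5

    def __post_init__(self):
        if self.family not in ("db", "daubechies"):
            raise ValidationError(f"unsupported wavelet family {self.family!r}")
        if self.order < 1:
            raise ValidationError("wavelet order must be >= 1")
        if self.level < 0:
            raise ValidationError("wavelet level must be >= 0")

    @property
    def name(self) -> str:
        return f"db{self.order}"


@dataclass
class EEGSegment:
    """One labelled multichannel trial (channels x time, microvolts)."""

    samples: np.ndarray
    rate: float
    label: int
    subject: str = "S1"
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels x time matrix")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if self.label not in VALID_LABELS:
            raise ValidationError(
                f"label {self.label} not in {sorted(VALID_LABELS)}")
        if self.n_samples < MIN_SAMPLES:
            raise ValidationError(
                f"trial has {self.n_samples} samples; need >= {MIN_SAMPLES}")
        if not self.channel_names:
            self.channel_names = tuple(
                f"ch{i + 1}" for i in range(self.n_channels))
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.n_channels:
            raise ValidationError("channel_names count != channel row count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EEGDataset:
    """An ordered collection of trials sharing rate and montage."""

    segments: list[EEGSegment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.segments:
            raise ValidationError("dataset must contain at least one segment")
        first = self.segments[0]
        for i, seg in enumerate(self.segments):
            if seg.rate != first.rate:
                raise ValidationError(f"segment {i}: rate differs from segment 0")
            if seg.n_channels != first.n_channels:
                raise ValidationError(
                    f"segment {i}: channel count differs from segment 0")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def rate(self) -> float:
        return self.segments[0].rate

    @property
    def n_channels(self) -> int:
        return self.segments[0].n_channels

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.segments[0].channel_names

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=int)

    @property
    def subjects(self) -> list[str]:
        return [s.subject for s in self.segments]


@dataclass
class PCAResult:
    """Eigendecomposition of a data matrix's covariance.

    ``loadings`` columns are the orthonormal principal directions (variables
    x components), ``scores`` = centered data projected on them, and
    ``residual`` is whatever the first ``n_retained`` components leave
    unexplained.  ``mean`` is the column mean removed before decomposition
    (zeros when uncentered).
    """

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    n_retained: int
    residual: np.ndarray
    mean: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValidationError("eigenvalues must be non-increasing")
        g = self.loadings.T @ self.loadings
        if np.max(np.abs(g - np.eye(g.shape[0]))) > 1e-8:
            raise ValidationError("loadings are not orthonormal")

    def reconstruct(self) -> np.ndarray:
        """Data rebuilt from the retained components (mean restored)."""
        k = self.n_retained
        return self.scores[:, :k] @ self.loadings[:, :k].T + self.mean


@dataclass
class SubbandSet:
    """Terminal coefficient blocks of one complete wavelet-packet tree."""

    blocks: list[np.ndarray]
    wavelet: WaveletSpec
    source_length: int
    ordering: str = "natural"

    def __post_init__(self):
        expected = 2 ** self.wavelet.level
        if len(self.blocks) != expected:
            raise ValidationError(
                f"expected {expected} blocks for level {self.wavelet.level}, "
                f"got {len(self.blocks)}")

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass
class FeatureVector:
    """The 95-entry statistical descriptor of one trial."""

    values: np.ndarray
    label: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValidationError(
                f"feature vector must have length {N_FEATURES}, "
                f"got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature vector contains non-finite entries")
        if self.label not in VALID_LABELS:
            raise ValidationError(f"label {self.label} invalid")


@dataclass
class FeatureMatrix:
    """Stacked feature vectors with aligned labels and subject codes."""

    values: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if self.values.shape[1] != N_FEATURES:
            raise ValidationError(
                f"feature matrix must have {N_FEATURES} columns, "
                f"got {self.values.shape[1]}")
        n = self.values.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValidationError("labels / subject_ids misaligned with rows")
        if not set(np.unique(self.labels)) <= VALID_LABELS:
            raise ValidationError("labels must be drawn from {1, 2}")

    def __len__(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(mask)
        return FeatureMatrix(
            self.values[idx],
            self.labels[idx],
            [s for s, m in zip(self.subject_ids, np.asarray(mask, bool))
             if m] if idx.dtype == bool
            else [self.subject_ids[i] for i in idx],
        )
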