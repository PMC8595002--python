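"""Wavelet-packet subband features.

A complete level-4 wavelet-packet tree turns one signal into 16 terminal
subbands (natural filter-bank order).  Five statistics per subband — mean
absolute value, average power, standard deviation, skewness, kurtosis —
give 80 features; the 15 ratios of adjacent-subband mean absolute values
complete the 95-entry vector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .model import (
    FEATURE_NAMES,
    N_SUBBANDS,
    EEGDataset,
    EEGSegment,
    FeatureMatrix,
    FeatureVector,
    SubbandSet,
    ValidationError,
    WaveletSpec,
)
from .wavelets import daubechies_filters, wp_decompose

__all__ = [
    "FeatureConfig",
    "wpd_decompose",
    "subband_stats",
    "adjacent_ratios",
    "extract_features",
    "extract_feature_matrix",
]

AGGREGATION_MODES = ("mean", "concat_signal", "single_channel")


@dataclass
class FeatureConfig:
    wavelet: WaveletSpec = field(
        default_factory=lambda: WaveletSpec("db", 4, 4))
    channel_aggregation: str = "mean"
    single_channel: str | None = None
    std_divisor: str = "n_minus_1"
    kurtosis_convention: str = "pearson"
    ratio_epsilon: float = 1e-12

    def __post_init__(self):
        if self.channel_aggregation not in AGGREGATION_MODES:
            raise ValidationError(
                f"channel_aggregation must be one of {AGGREGATION_MODES}")
        if self.std_divisor not in ("n_minus_1", "n"):
            raise ValidationError("std_divisor must be 'n_minus_1' or 'n'")
        if self.kurtosis_convention not in ("pearson", "excess"):
            raise ValidationError(
                "kurtosis_convention must be 'pearson' or 'excess'")
        if self.ratio_epsilon <= 0:
            raise ValidationError("ratio_epsilon must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wavelet"] = dataclasses.asdict(self.wavelet)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        if "wavelet" in d:
            d["wavelet"] = WaveletSpec(**d["wavelet"])
        return cls(**d)


def wpd_decompose(signal: np.ndarray, wavelet: WaveletSpec) -> SubbandSet:
    """Complete wavelet-packet tree of ``signal`` at the spec'd level."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValidationError("wpd_decompose expects a 1-D signal")
    if wavelet.level > 0 and len(signal) < 2 ** wavelet.level:
        raise ValidationError(
            f"signal of {len(signal)} samples too short for level "
            f"{wavelet.level}")
    lo, hi = daubechies_filters(wavelet.order)
    blocks = wp_decompose(signal, lo, hi, wavelet.level)
    return SubbandSet(blocks=blocks, wavelet=wavelet,
                      source_length=len(signal))


def subband_stats(block: np.ndarray, config: FeatureConfig | None = None
                  ) -> np.ndarray:
    """(MAV, average power, std, skewness, kurtosis) of one block.

    Skewness and kurtosis are population-moment based (third/fourth
    standardized moments); zero-variance blocks return 0 for both by
    convention so downstream vectors stay finite.
    """
    config = config or FeatureConfig()
    c = np.asarray(block, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValidationError("block must be a non-empty 1-D array")
    n = len(c)
    mav = float(np.mean(np.abs(c)))
    power = float(np.mean(c * c))
    mu = float(np.mean(c))
    dev = c - mu
    m2 = float(np.mean(dev ** 2))
    ddof = 1 if config.std_divisor == "n_minus_1" else 0
    if n - ddof <= 0:
        std = 0.0
    else:
        std = float(np.sqrt(np.sum(dev ** 2) / (n - ddof)))
    if m2 > 0.0:
        skew = float(np.mean(dev ** 3) / m2 ** 1.5)
        kurt = float(np.mean(dev ** 4) / m2 ** 2)
        if config.kurtosis_convention == "excess":
            kurt -= 3.0
    else:
        skew = 0.0
        kurt = 0.0
    return np.array([mav, power, std, skew, kurt])


def adjacent_ratios(subbands: SubbandSet, config: FeatureConfig | None = None
                    ) -> np.ndarray:
    """MAV(block i) / (MAV(block i+1) + eps) for i = 1..15, canonical order."""
    config = config or FeatureConfig()
    if len(subbands) != N_SUBBANDS:
        raise ValidationError(
            f"adjacent_ratios needs exactly {N_SUBBANDS} blocks, "
            f"got {len(subbands)}")
    mavs = np.array([np.mean(np.abs(b)) for b in subbands.blocks])
    return mavs[:-1] / (mavs[1:] + config.ratio_epsilon)


def _features_of_signal(signal: np.ndarray, config: FeatureConfig
                        ) -> np.ndarray:
    subbands = wpd_decompose(signal, config.wavelet)
    stats = np.concatenate(
        [subband_stats(b, config) for b in subbands.blocks])
    ratios = adjacent_ratios(subbands, config)
    return np.concatenate([stats, ratios])


def extract_features(segment: EEGSegment,
                     config: FeatureConfig | None = None) -> FeatureVector:
    """95-entry feature vector of one trial.

    Channel handling: ``mean`` extracts the 95 features per channel and
    averages them; ``concat_signal`` joins channels end-to-end before one
    decomposition; ``single_channel`` uses the named channel only.
    """
    config = config or FeatureConfig()
    mode = config.channel_aggregation
    if mode == "mean":
        per_ch = [_features_of_signal(segment.samples[c], config)
                  for c in range(segment.n_channels)]
        values = np.mean(per_ch, axis=0)
    elif mode == "concat_signal":
        values = _features_of_signal(segment.samples.reshape(-1), config)
    elif mode == "single_channel":
        name = config.single_channel or segment.channel_names[0]
        if name not in segment.channel_names:
            raise ValidationError(
                f"channel {name!r} not in {segment.channel_names}")
        idx = segment.channel_names.index(name)
        values = _features_of_signal(segment.samples[idx], config)
    else:  # pragma: no cover - guarded by FeatureConfig
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    return FeatureVector(values=values, label=segment.label)


def extract_feature_matrix(dataset: EEGDataset,
                           config: FeatureConfig | None = None
                           ) -> FeatureMatrix:
    """One feature row per segment; labels and subject codes carried through."""
    config = config or FeatureConfig()
    rows = []
    for i, seg in enumerate(dataset):
        try:
            rows.append(extract_features(seg, config).values)
        except ValidationError as exc:
            raise ValidationError(f"trial {i}: {exc}") from exc
    return FeatureMatrix(
        values=np.vstack(rows),
        labels=dataset.labels,
        subject_ids=dataset.subjects,
    )


#: exported for table writers; mirrors model.FEATURE_NAMES
feature_names = FEATURE_NAMES
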