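"""Two-class synthetic motor-imagery EEG.

Each trial is a sum of sustained mu- and beta-band oscillations and
1/f^alpha background noise.  Class identity is encoded spatially: class 1
attenuates the rhythm amplitude on the first lateral channel, class 2 on the
last one (multiplicative factor ``erd_factor``, so band power scales by its
square).  Each channel carries a slightly different peak frequency inside
the band — without that, channel-averaged subband features would be blind to
a purely spatial power swap between two otherwise symmetric channels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .model import EEGDataset, EEGSegment, ValidationError

__all__ = ["SimulationConfig", "generate_dataset", "generate_null_dataset"]

#: relative amplitude of the beta rhythm vs the mu rhythm
_BETA_WEIGHT = 0.7

#: sigma of the per-subject lognormal gains on rhythm and noise amplitude
_SUBJECT_SIGMA = 0.10


@dataclass
class SimulationConfig:
    n_subjects: int = 5
    trials_per_class_per_subject: int = 140
    rate: float = 100.0
    duration: float = 3.5
    channels: tuple[str, ...] = ("C3", "Cz", "C4")
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (18.0, 26.0)
    erd_factor: float = 0.5
    noise_exponent: float = 1.0
    snr_db: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.trials_per_class_per_subject < 1:
            raise ValidationError("trials_per_class_per_subject must be >= 1")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        n = self.duration * self.rate
        if abs(n - round(n)) > 1e-9 or round(n) < 32:
            raise ValidationError(
                "duration x rate must be an integer >= 32")
        if not (0.0 < self.erd_factor <= 1.0):
            raise ValidationError("erd_factor must lie in (0, 1]")
        if len(self.channels) < 1:
            raise ValidationError("channels must not be empty")
        for name, band in (("mu_band", self.mu_band),
                           ("beta_band", self.beta_band)):
            lo, hi = band
            if not (0 < lo < hi <= self.rate / 2):
                raise ValidationError(
                    f"{name} must satisfy 0 < low < high <= Nyquist")
        if self.noise_exponent < 0:
            raise ValidationError("noise_exponent must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("channels", "mu_band", "beta_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _channel_freqs(band: tuple[float, float], n_channels: int) -> np.ndarray:
    """Evenly spaced per-channel peak frequencies inside a band."""
    lo, hi = band
    return lo + (np.arange(n_channels) + 0.5) * (hi - lo) / n_channels


def _colored_noise(rng: np.random.Generator, n: int, rate: float,
                   exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _make_trial(rng: np.random.Generator, config: SimulationConfig,
                label: int, rhythm_gain: float, noise_gain: float,
                erd_factor: float) -> np.ndarray:
    n = config.n_samples
    n_ch = len(config.channels)
    t = np.arange(n) / config.rate
    f_mu = _channel_freqs(config.mu_band, n_ch)
    f_beta = _channel_freqs(config.beta_band, n_ch)
    rhythm_scale = np.sqrt(10.0 ** (config.snr_db / 10.0))
    target = 0 if label == 1 else n_ch - 1
    out = np.empty((n_ch, n))
    for ch in range(n_ch):
        ph_mu, ph_beta = rng.uniform(0.0, 2.0 * np.pi, size=2)
        rhythm = (np.sin(2 * np.pi * f_mu[ch] * t + ph_mu)
                  + _BETA_WEIGHT * np.sin(2 * np.pi * f_beta[ch] * t + ph_beta))
        rhythm = rhythm / rhythm.std() * rhythm_scale * rhythm_gain
        if ch == target:
            rhythm = rhythm * erd_factor
        noise = _colored_noise(rng, n, config.rate,
                               config.noise_exponent) * noise_gain
        out[ch] = rhythm + noise
    return out


def _generate(config: SimulationConfig, erd_factor: float,
              shuffle_labels: bool) -> EEGDataset:
    rng = np.random.default_rng(config.seed)
    segments = []
    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        rhythm_gain = float(np.exp(rng.normal(0.0, _SUBJECT_SIGMA)))
        noise_gain = float(np.exp(rng.normal(0.0, _SUBJECT_SIGMA)))
        labels = np.repeat([1, 2], config.trials_per_class_per_subject)
        assigned = rng.permutation(labels) if shuffle_labels else labels
        for signal_label, assigned_label in zip(labels, assigned):
            samples = _make_trial(rng, config, int(signal_label),
                                  rhythm_gain, noise_gain, erd_factor)
            segments.append(EEGSegment(
                samples=samples, rate=config.rate, label=int(assigned_label),
                subject=subject, channel_names=config.channels))
    return EEGDataset(segments, metadata={
        "generator": "mieeg.simulate",
        "config": config.to_dict(),
        "null": shuffle_labels,
    })


def generate_dataset(config: SimulationConfig) -> EEGDataset:
    """Class-informative dataset: n_subjects x 2 classes x trials segments."""
    return _generate(config, config.erd_factor, shuffle_labels=False)


def generate_null_dataset(config: SimulationConfig) -> EEGDataset:
    """Same trial layout but erd_factor forced to 1 and labels randomly
    permuted within subject — no signal-label association survives."""
    return _generate(config, 1.0, shuffle_labels=True)
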