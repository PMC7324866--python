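"""Synthetic EEG segments and Bonn-format I/O.

The synthetic generator emulates three qualitative single-channel EEG
regimes so that class separability is controllable:

* ``healthy`` — dominant alpha-band (8–13 Hz) oscillation over pink-ish
  background noise;
* ``interictal`` — the healthy background plus Poisson-timed high-amplitude
  spike transients (2 per second at 4x the background amplitude, so every
  segment reliably contains discharges);
* ``ictal`` — high-amplitude rhythmic 3–5 Hz spike-wave activity.

Real segments are read in the Bonn single-column ASCII format: one numeric
sample per line, 4,097 samples at 173.61 Hz per segment in the original
recordings.  Nothing here claims physiological fidelity; see the methods
note for what these surrogates do and do not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .exceptions import (
    BonnFormatError,
    ConfigurationError,
    DataError,
    DegenerateSignalError,
    InsufficientDataError,
    StratificationError,
)

BONN_FS = 173.61
"""Sampling rate (Hz) of the Bonn recordings: 4,097 samples per 23.6 s segment."""

SPIKE_DURATION_S = 0.060
"""Spike transient length in seconds (one-cycle raised-cosine pulse)."""


@dataclass(frozen=True)
class EEGSegment:
    """One channel's samples plus sampling rate and optional class label.

    Parameters
    ----------
    samples : array-like of float
        The signal, arbitrary amplitude units.  Must be non-empty and finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : int, optional
        Class identifier (small integer).
    source_id : str, optional
        Free-text provenance tag (file name, generator tag, ...).
    """

    samples: np.ndarray
    fs: float
    label: int | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise InsufficientDataError("segment must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise DataError("segment contains non-finite values (NaN/Inf)")
        if not self.fs > 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "EEGSegment":
        return EEGSegment(samples, self.fs, self.label, self.source_id)


@dataclass(frozen=True)
class ClassProfile:
    """Generator parameters for one signal regime.

    ``band`` is the dominant rhythm band in Hz; the oscillation frequency is
    drawn uniformly from it per segment.  ``spike_rate`` is spikes per second
    (Poisson-timed), ``spike_amp`` a multiplier on ``amplitude`` for the spike
    transients.  ``rhythmic_spikes`` locks one spike per oscillation cycle
    (the ictal spike-wave pattern) instead of Poisson timing.
    """

    name: str
    band: tuple[float, float] = (8.0, 13.0)
    amplitude: float = 1.0
    spike_rate: float = 0.0
    spike_amp: float = 0.0
    noise_sd: float = 0.5
    rhythmic_spikes: bool = False

    def __post_init__(self) -> None:
        if self.spike_rate < 0:
            raise ConfigurationError("spike rate must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")
        if not (0 < self.band[0] <= self.band[1]):
            raise ConfigurationError(f"invalid band {self.band}")


def default_profiles(noise_scale: float = 1.0) -> dict[str, ClassProfile]:
    """The three stock regimes; ``noise_scale`` multiplies every noise sd.

    Ictal amplitude is 4x the healthy scale, so at the default noise level
    the regimes are well separated; raising ``noise_scale`` dials up class
    overlap without touching the deterministic structure.
    """
    ns = float(noise_scale)
    return {
        "healthy": ClassProfile("healthy", band=(8.0, 13.0), amplitude=1.0,
                                noise_sd=0.5 * ns),
        "interictal": ClassProfile("interictal", band=(8.0, 13.0), amplitude=1.0,
                                   spike_rate=2.0, spike_amp=4.0,
                                   noise_sd=0.5 * ns),
        "ictal": ClassProfile("ictal", band=(3.0, 5.0), amplitude=4.0,
                              spike_amp=1.5, rhythmic_spikes=True,
                              noise_sd=0.5 * ns),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic dataset; the dataset is a pure function of it."""

    n_per_class: int = 40
    n_samples: int = 1024
    fs: float = BONN_FS
    profiles: tuple[ClassProfile, ...] = field(
        default_factory=lambda: tuple(default_profiles().values())
    )
    seed: int = 0

    def class_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.profiles)


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum, rescaled to the given sd."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    spec[0] = 0.0
    spec[1:] /= np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec, n)
    s = pink.std()
    if s > 0:
        pink *= sd / s
    return pink


def _raised_cosine_pulse(n: int) -> np.ndarray:
    # one full cycle of 0.5*(1 - cos), zero at both ends
    k = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / max(n - 1, 1)))


def generate_segment(
    profile: ClassProfile | str,
    n_samples: int,
    fs: float,
    seed: int,
    *,
    profiles: dict[str, ClassProfile] | None = None,
    label: int | None = None,
    source_id: str | None = None,
) -> EEGSegment:
    """Generate one synthetic segment; bit-identical for identical arguments.

    The segment is a band-limited oscillation at the profile's dominant band,
    plus pink-ish Gaussian noise, plus spike transients (Poisson-timed, or one
    per cycle for rhythmic spike-wave profiles).
    """
    if isinstance(profile, str):
        table = profiles if profiles is not None else default_profiles()
        if profile not in table:
            raise ConfigurationError(
                f"unknown profile {profile!r}; known: {sorted(table)}"
            )
        profile = table[profile]
    if n_samples < 64:
        raise ConfigurationError(f"n_samples must be >= 64, got {n_samples}")
    rng = np.random.default_rng(seed)

    t = np.arange(n_samples) / fs
    freq = rng.uniform(*profile.band)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    x = profile.amplitude * np.sin(2.0 * np.pi * freq * t + phase)
    x += _pink_noise(rng, n_samples, profile.noise_sd)

    pulse_len = max(int(round(SPIKE_DURATION_S * fs)), 3)
    pulse = _raised_cosine_pulse(pulse_len)
    spike_height = profile.spike_amp * profile.amplitude
    duration = n_samples / fs
    if profile.rhythmic_spikes:
        period = 1.0 / freq
        start = rng.uniform(0.0, period)
        spike_times = np.arange(start, duration, period)
    else:
        n_spikes = rng.poisson(profile.spike_rate * duration)
        spike_times = np.sort(rng.uniform(0.0, duration, size=n_spikes))
    for ts in spike_times:
        i0 = int(round(ts * fs))
        i1 = min(i0 + pulse_len, n_samples)
        if i0 < n_samples:
            x[i0:i1] += spike_height * pulse[: i1 - i0]

    return EEGSegment(x, fs, label=label, source_id=source_id)


def generate_dataset(config: SynthConfig) -> list[EEGSegment]:
    """Generate ``n_per_class`` labeled segments per profile, deterministically.

    Labels are the profile indices (0..C-1 in ``config.profiles`` order); each
    segment's seed is derived from (config.seed, class index, segment index)
    via a SeedSequence, so the whole dataset is a pure function of the config.
    """
    segments: list[EEGSegment] = []
    for ci, profile in enumerate(config.profiles):
        for i in range(config.n_per_class):
            child_seed = int(
                np.random.SeedSequence([config.seed, ci, i]).generate_state(1)[0]
            )
            segments.append(
                generate_segment(
                    profile,
                    config.n_samples,
                    config.fs,
                    child_seed,
                    label=ci,
                    source_id=f"{profile.name}-{i:03d}",
                )
            )
    return segments


# ---------------------------------------------------------------------------
# Bonn single-column ASCII format
# ---------------------------------------------------------------------------

def read_bonn_ascii(
    path: str | Path,
    fs: float = BONN_FS,
    label: int | None = None,
) -> EEGSegment:
    """Read a Bonn-format file: one numeric sample per line, LF or CRLF.

    The sampling rate defaults to the Bonn recordings' 173.61 Hz; the label
    comes from the caller (the files carry none).
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise BonnFormatError(
                    f"{path}: line {lineno}: cannot parse {stripped!r} as a number"
                ) from None
    if not values:
        raise BonnFormatError(f"{path}: empty file")
    return EEGSegment(np.array(values), fs, label=label, source_id=path.name)


def write_bonn_ascii(segment: EEGSegment, path: str | Path) -> None:
    """Write a segment in the same one-value-per-line format (fixture writer).

    Values are written with ``repr`` so floats round-trip exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for v in segment.samples:
            if v == int(v):
                fh.write(f"{int(v)}\n")
            else:
                fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Normalization, splitting, oversampling
# ---------------------------------------------------------------------------

def normalize_segment(segment: EEGSegment) -> EEGSegment:
    """Z-score a segment to mean 0, population (1/N) standard deviation 1.

    Per-segment scaling puts every signal on a uniform scale before feature
    extraction and makes the entropy tolerance r = 0.2*sd comparable across
    segments.
    """
    x = segment.samples
    if x.size < 2:
        raise InsufficientDataError("need >= 2 samples to normalize")
    sd = x.std()  # population (1/N) convention
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError("zero-variance segment cannot be normalized")
    return segment.with_samples((x - x.mean()) / sd)


def split_train_test(
    segments: Sequence[EEGSegment],
    ratio: float,
    seed: int,
) -> tuple[list[EEGSegment], list[EEGSegment]]:
    """Stratified train/test split; ``ratio`` is the training fraction.

    With ratio 0.5 (the 1:1 protocol) the halves differ by at most one
    segment per class.  Deterministic given the seed.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ConfigurationError(f"ratio must be in [0, 1], got {ratio}")
    by_label: dict[int | None, list[EEGSegment]] = {}
    for seg in segments:
        by_label.setdefault(seg.label, []).append(seg)
    for lab, group in by_label.items():
        if len(group) < 2:
            raise StratificationError(
                f"class {lab!r} has {len(group)} segment(s); need >= 2 for a split"
            )
    rng = np.random.default_rng(seed)
    train: list[EEGSegment] = []
    test: list[EEGSegment] = []
    for lab in sorted(by_label, key=lambda v: (v is None, v)):
        group = by_label[lab]
        order = rng.permutation(len(group))
        n_train = int(round(ratio * len(group)))
        for rank, idx in enumerate(order):
            (train if rank < n_train else test).append(group[idx])
    return train, test


def oversample_with_jitter(
    segments: Sequence[EEGSegment],
    factor: int,
    jitter_sd: float,
    seed: int,
) -> list[EEGSegment]:
    """Optional utility: duplicate each segment (factor-1) times with additive
    Gaussian jitter.  Off by default everywhere; exposed for experiments with
    imbalanced positive classes."""
    if factor < 1:
        raise ConfigurationError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out = list(segments)
    for seg in segments:
        for k in range(factor - 1):
            noisy = seg.samples + rng.normal(0.0, jitter_sd, size=seg.n_samples)
            out.append(
                EEGSegment(noisy, seg.fs, seg.label,
                           f"{seg.source_id or 'seg'}-jitter{k}")
            )
    return out


# ---------------------------------------------------------------------------
# SynthConfig (de)serialization: flat key/value YAML
# ---------------------------------------------------------------------------

def synth_config_to_yaml(config: SynthConfig, path: str | Path) -> None:
    """Serialize a SynthConfig as flat dotted keys (YAML scalars only).

    Profile fields become ``profile.<name>.<field>`` keys; ``band`` splits
    into ``band_lo`` / ``band_hi``.
    """
    flat: dict[str, object] = {
        "n_per_class": config.n_per_class,
        "n_samples": config.n_samples,
        "fs": config.fs,
        "seed": config.seed,
        "classes": ",".join(config.class_names()),
    }
    for p in config.profiles:
        prefix = f"profile.{p.name}"
        flat[f"{prefix}.band_lo"] = p.band[0]
        flat[f"{prefix}.band_hi"] = p.band[1]
        flat[f"{prefix}.amplitude"] = p.amplitude
        flat[f"{prefix}.spike_rate"] = p.spike_rate
        flat[f"{prefix}.spike_amp"] = p.spike_amp
        flat[f"{prefix}.noise_sd"] = p.noise_sd
        flat[f"{prefix}.rhythmic_spikes"] = p.rhythmic_spikes
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)


def synth_config_from_yaml(path: str | Path) -> SynthConfig:
    with open(path) as fh:
        flat = yaml.safe_load(fh)
    if not isinstance(flat, dict):
        raise ConfigurationError(f"{path}: not a flat key/value mapping")
    try:
        names = [n for n in str(flat["classes"]).split(",") if n]
        profiles = []
        for name in names:
            prefix = f"profile.{name}"
            profiles.append(
                ClassProfile(
                    name,
                    band=(float(flat[f"{prefix}.band_lo"]),
                          float(flat[f"{prefix}.band_hi"])),
                    amplitude=float(flat[f"{prefix}.amplitude"]),
                    spike_rate=float(flat[f"{prefix}.spike_rate"]),
                    spike_amp=float(flat[f"{prefix}.spike_amp"]),
                    noise_sd=float(flat[f"{prefix}.noise_sd"]),
                    rhythmic_spikes=bool(flat[f"{prefix}.rhythmic_spikes"]),
                )
            )
        return SynthConfig(
            n_per_class=int(flat["n_per_class"]),
            n_samples=int(flat["n_samples"]),
            fs=float(flat["fs"]),
            profiles=tuple(profiles),
            seed=int(flat["seed"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing key {exc}") from None
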