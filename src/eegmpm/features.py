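"""Linear and non-linear features for one EEG segment.

The linear feature is the *wave coefficient* of each wavelet subband: the
mean absolute first difference of the coefficient sequence, a simple
waveform-variability measure.  The non-linear features are approximate
entropy AE(m, r) (self-matches included), sample entropy SE(m, r)
(self-matches excluded) and multiscale permutation entropy: the Shannon
entropy of ordinal patterns of the coarse-grained series, normalized by
ln(m!) so it lies in [0, 1].

Template matching for both ApEn and SampEn uses the Chebyshev
(max-coordinate) distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .exceptions import ConfigurationError, InsufficientDataError, UndefinedEntropyError
from .synth import EEGSegment


@dataclass(frozen=True)
class EntropyParams:
    """Entropy estimation parameters.

    m, r apply to ApEn/SampEn (embedding dimension and similarity tolerance,
    in units of the normalized signal); mpe_m, tau and scales apply to
    multiscale permutation entropy.  Defaults are the field-standard choices:
    m=2, r=0.2 (i.e. 0.2*sd on a z-scored segment); mpe_m=3, tau=1,
    scales 1..5.
    """

    m: int = 2
    r: float = 0.2
    mpe_m: int = 3
    tau: int = 1
    scales: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if self.m < 1 or self.mpe_m < 2:
            raise ConfigurationError("embedding dimensions: m >= 1, mpe_m >= 2")
        if self.r <= 0:
            raise ConfigurationError("tolerance r must be > 0")
        if self.tau < 1:
            raise ConfigurationError("delay tau must be >= 1")
        if any(s < 1 for s in self.scales) or not self.scales:
            raise ConfigurationError("every scale must be >= 1")


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-order numeric features for one segment."""

    values: np.ndarray
    names: tuple[str, ...]
    label: int | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names),):
            raise ConfigurationError("feature values/names length mismatch")
        object.__setattr__(self, "values", values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


# ---------------------------------------------------------------------------
# Wavelet subbands and the wave coefficient
# ---------------------------------------------------------------------------

def wavelet_decompose(
    x: EEGSegment | np.ndarray,
    wavelet: str = "db4",
    levels: int = 4,
    mode: str = "periodization",
) -> list[np.ndarray]:
    """Decompose into detail subbands d1..dL plus the final approximation aL.

    Returns levels+1 sequences ordered finest detail first.  The default
    periodization mode keeps an orthogonal wavelet energy-preserving.  With
    levels=0 the original (full-band) signal is returned as the single
    subband.
    """
    data = x.samples if isinstance(x, EEGSegment) else np.asarray(x, dtype=float)
    if levels < 0:
        raise ConfigurationError("levels must be >= 0")
    if levels == 0:
        return [data.copy()]
    if data.size < 2 ** levels:
        raise InsufficientDataError(
            f"segment of length {data.size} too short for {levels}-level decomposition"
        )
    coeffs = pywt.wavedec(data, wavelet, level=levels, mode=mode)
    # pywt returns [aL, dL, ..., d1]; reorder to [d1, ..., dL, aL]
    approx, details = coeffs[0], coeffs[1:]
    return [np.asarray(d) for d in reversed(details)] + [np.asarray(approx)]


def subband_names(levels: int) -> tuple[str, ...]:
    if levels == 0:
        return ("full",)
    return tuple(f"d{k}" for k in range(1, levels + 1)) + (f"a{levels}",)


def wave_coefficient(a: np.ndarray) -> float:
    """Mean absolute first difference of an amplitude sequence.

    Translation-invariant and absolutely homogeneous; zero exactly for
    constant sequences.
    """
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise InsufficientDataError("wave coefficient needs length >= 2")
    return float(np.mean(np.abs(np.diff(a))))


# ---------------------------------------------------------------------------
# Approximate and sample entropy (Chebyshev template matching)
# ---------------------------------------------------------------------------

def _chebyshev_template_distances(x: np.ndarray, m: int, n_templates: int) -> np.ndarray:
    """Pairwise Chebyshev distances between the first ``n_templates``
    length-m templates, built as a running max over shifted difference
    matrices (O(m N^2) time, O(N^2) memory)."""
    base = np.abs(x[:, None] - x[None, :])
    d = base[:n_templates, :n_templates].copy()
    for k in range(1, m):
        np.maximum(d, base[k : k + n_templates, k : k + n_templates], out=d)
    return d


def approximate_entropy(x: np.ndarray, m: int, r: float) -> float:
    """Pincus approximate entropy AE(m, r) = phi^m(r) - phi^{m+1}(r).

    phi^m is the mean over templates of ln of the fraction of templates
    (self included) within Chebyshev distance r.  Not clipped: small
    negative values can occur and are returned as-is.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise InsufficientDataError(f"ApEn needs N >= m+2 = {m + 2}, got {n}")
    if r <= 0:
        raise ConfigurationError("tolerance r must be > 0")

    def phi(mm: int) -> float:
        nt = n - mm + 1
        d = _chebyshev_template_distances(x, mm, nt)
        frac = np.count_nonzero(d <= r, axis=1) / nt
        return float(np.mean(np.log(frac)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int, r: float) -> float:
    """Sample entropy SE(m, r) = -ln(A/B), self-matches excluded.

    B counts ordered pairs (i != j) of length-m templates within Chebyshev
    distance r, A the same for length m+1; both use the N-m templates whose
    (m+1)-extension exists.  A = 0 or B = 0 raises rather than returning an
    infinity.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise InsufficientDataError(f"SampEn needs N >= m+2 = {m + 2}, got {n}")
    if r <= 0:
        raise ConfigurationError("tolerance r must be > 0")
    nt = n - m  # templates with a valid (m+1)-extension
    d_m = _chebyshev_template_distances(x, m, nt)
    b = int(np.count_nonzero(d_m <= r)) - nt  # drop self-pairs
    d_m1 = _chebyshev_template_distances(x, m + 1, nt)
    a = int(np.count_nonzero(d_m1 <= r)) - nt
    if b == 0:
        raise UndefinedEntropyError("no m-template pairs within tolerance (B = 0)")
    if a == 0:
        raise UndefinedEntropyError("no (m+1)-template pairs within tolerance (A = 0)")
    return float(-math.log(a / b))


# ---------------------------------------------------------------------------
# Multiscale permutation entropy
# ---------------------------------------------------------------------------

def coarse_grain(x: np.ndarray, s: int) -> np.ndarray:
    """Non-overlapping window means of width s; remainder samples dropped.

    Scale 1 returns the series unchanged.
    """
    x = np.asarray(x, dtype=float)
    if s < 1:
        raise ConfigurationError("scale must be >= 1")
    if s > x.size:
        raise InsufficientDataError(f"scale {s} exceeds series length {x.size}")
    n_windows = x.size // s
    if s == 1:
        return x.copy()
    return x[: n_windows * s].reshape(n_windows, s).mean(axis=1)


def permutation_entropy(x: np.ndarray, m: int, tau: int = 1) -> float:
    """Normalized permutation entropy h_P = H_P / ln(m!) in [0, 1].

    Each delay-embedded window maps to its ascending-order pattern; ties
    break by earlier index first (stable sort), so a constant signal yields
    a single pattern and entropy 0.
    """
    x = np.asarray(x, dtype=float)
    if m < 2:
        raise ConfigurationError("permutation entropy needs m >= 2")
    if tau < 1:
        raise ConfigurationError("delay tau must be >= 1")
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise InsufficientDataError(
            f"series of length {x.size} yields no embedded vectors for m={m}, tau={tau}"
        )
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * tau
    windows = x[idx]
    patterns = np.argsort(windows, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / n_vec
    h = float(-np.sum(p * np.log(p)))
    return min(max(h / math.log(math.factorial(m)), 0.0), 1.0)


def multiscale_permutation_entropy(
    x: np.ndarray, params: EntropyParams
) -> np.ndarray:
    """Permutation entropy of the coarse-grained series at each scale."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(params.scales))
    for k, s in enumerate(params.scales):
        out[k] = permutation_entropy(coarse_grain(x, s), params.mpe_m, params.tau)
    return out


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

def feature_names(
    params: EntropyParams, levels: int = 4
) -> tuple[str, ...]:
    """The documented fixed feature order: wave coefficient per subband
    (finest detail first, approximation last), ApEn, SampEn, then one MPE
    value per scale."""
    wc = tuple(f"wc_{b}" for b in subband_names(levels))
    mpe = tuple(f"mpe_s{s}" for s in params.scales)
    return wc + ("apen", "sampen") + mpe


def extract_features(
    segment: EEGSegment,
    params: EntropyParams | None = None,
    wavelet: str = "db4",
    levels: int = 4,
) -> FeatureVector:
    """Compute the full feature vector for one (normalized) segment.

    Callers are expected to normalize the segment first so the tolerance r
    is on the 0.2*sd scale; this function does not renormalize.  Errors from
    a constituent feature are re-raised with the feature's name attached.
    """
    params = params or EntropyParams()
    x = segment.samples
    values: list[float] = []
    names = feature_names(params, levels)
    try:
        subbands = wavelet_decompose(segment, wavelet, levels)
    except Exception as exc:
        raise type(exc)(f"wavelet_decompose: {exc}") from exc
    for band_name, band in zip(subband_names(levels), subbands):
        try:
            values.append(wave_coefficient(band))
        except Exception as exc:
            raise type(exc)(f"wc_{band_name}: {exc}") from exc
    try:
        values.append(approximate_entropy(x, params.m, params.r))
    except Exception as exc:
        raise type(exc)(f"apen: {exc}") from exc
    try:
        values.append(sample_entropy(x, params.m, params.r))
    except Exception as exc:
        raise type(exc)(f"sampen: {exc}") from exc
    try:
        values.extend(multiscale_permutation_entropy(x, params))
    except Exception as exc:
        raise type(exc)(f"mpe: {exc}") from exc
    return FeatureVector(np.array(values), names, segment.label, segment.source_id)


def feature_table(
    segments: list[EEGSegment],
    params: EntropyParams | None = None,
    wavelet: str = "db4",
    levels: int = 4,
) -> pd.DataFrame:
    """Feature matrix for a list of segments, one row each, with ``label``
    and ``source_id`` columns appended after the feature columns."""
    params = params or EntropyParams()
    rows = [extract_features(s, params, wavelet, levels) for s in segments]
    if not rows:
        return pd.DataFrame(columns=list(feature_names(params, levels)) + ["label", "source_id"])
    df = pd.DataFrame([fv.values for fv in rows], columns=list(rows[0].names))
    df["label"] = [fv.label for fv in rows]
    df["source_id"] = [fv.source_id for fv in rows]
    return df


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
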