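"""Spectral characterisation of calls and soundscapes.

Per-clip mean spectra (short-time Fourier transform, FFT length 512, no
overlap, Hann window, magnitudes averaged over time), SNR screening of
focal recordings, the cumulative spectral dissimilarity index D_cf between
species calls, and discrimination of pre- versus mid-event soundscape
profiles with the bagged-tree classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .exceptions import InvalidInputError, UndefinedSNRError
from .weather import OnsetForest, OnsetForestResults

#: SNR acceptance threshold (dB) for focal call recordings; strict.
SNR_THRESHOLD_DB = 30.0

#: Relative offset added before the log transform of mean magnitudes.
LOG_EPS = 1e-12


@dataclass
class Spectrum:
    """Mean magnitude spectrum of one clip on a fixed FFT bin grid.

    ``mass`` is the average magnitude normalised to sum to one (a discrete
    distribution over frequency); ``log_profile`` is the log-transformed
    unnormalised average, used as the feature vector for soundscape
    classification.
    """

    bin_freqs: np.ndarray
    mass: np.ndarray
    log_profile: np.ndarray

    def __post_init__(self) -> None:
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        self.log_profile = np.asarray(self.log_profile, dtype=float)
        if not (len(self.bin_freqs) == len(self.mass) == len(self.log_profile)):
            raise InvalidInputError("bin grid and spectra must have equal length")
        if np.any(np.diff(self.bin_freqs) <= 0):
            raise InvalidInputError("bin_freqs must be increasing")
        if np.any(self.mass < 0) or abs(self.mass.sum() - 1.0) > 1e-9:
            raise InvalidInputError("mass must be a distribution summing to 1")


def mean_spectrum(clip: np.ndarray, sr: float, fft_len: int = 512) -> Spectrum:
    """Average magnitude spectrum over non-overlapping Hann-windowed frames.

    The clip is cut into ``floor(len/fft_len)`` frames (remainder samples
    dropped), each windowed and Fourier-transformed; magnitudes are averaged
    over frames.  ``fft_len//2`` bins are kept (DC included, Nyquist
    dropped) with spacing ``sr / fft_len``.
    """
    clip = np.asarray(clip, dtype=float)
    if clip.size < fft_len:
        raise InvalidInputError(
            f"clip of {clip.size} samples is shorter than fft_len={fft_len}"
        )
    n_frames = clip.size // fft_len
    frames = clip[: n_frames * fft_len].reshape(n_frames, fft_len)
    window = hann(fft_len, sym=False)
    mags = np.abs(np.fft.rfft(frames * window, axis=1))[:, : fft_len // 2]
    avg = mags.mean(axis=0)
    total = avg.sum()
    if total == 0:
        raise InvalidInputError("silent clip: mean spectrum has no energy")
    bin_freqs = np.arange(fft_len // 2) * sr / fft_len
    log_profile = np.log(avg + LOG_EPS * avg.max())
    return Spectrum(bin_freqs=bin_freqs, mass=avg / total, log_profile=log_profile)


def snr_db(signal_rms: float, noise_rms: float) -> float:
    """Signal-to-noise ratio 20*log10(RMS_signal / RMS_noise) in dB."""
    if noise_rms <= 0:
        raise UndefinedSNRError("noise RMS must be positive")
    return 20.0 * np.log10(signal_rms / noise_rms)


def passes_snr(signal_rms: float, noise_rms: float) -> bool:
    """Focal-recording screen: SNR strictly above 30 dB."""
    return snr_db(signal_rms, noise_rms) > SNR_THRESHOLD_DB


def dcf(s1: Spectrum, s2: Spectrum) -> float:
    """Cumulative spectral dissimilarity D_cf in [0, 1].

    With C the cumulative sum of the normalised mean spectrum,
    ``D_cf = sum_f |C1(f) - C2(f)| / (N - 1)``; the constant bounds the
    index at 1 (attained by point masses at the opposite ends of the grid)
    and it is 0 iff the two mass vectors are identical.
    """
    if len(s1.bin_freqs) != len(s2.bin_freqs) or not np.allclose(
        s1.bin_freqs, s2.bin_freqs
    ):
        raise InvalidInputError("spectra must share the same bin grid")
    c1 = np.cumsum(s1.mass)
    c2 = np.cumsum(s2.mass)
    n = len(c1)
    return float(np.abs(c1 - c2).sum() / (n - 1))


def dcf_matrix(spectra: dict[str, Spectrum]) -> pd.DataFrame:
    """Symmetric species x species D_cf matrix with zero diagonal."""
    ids = list(spectra)
    d = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            v = dcf(spectra[a], spectra[b])
            d.loc[a, b] = d.loc[b, a] = v
    return d


def classify_profiles(
    profiles: pd.DataFrame,
    labels,
    n_trees: int = 500,
    importance_repeats: int = 5,
    seed: int | None = None,
) -> OnsetForestResults:
    """Discriminate labelled soundscape spectral profiles with a bagged forest.

    ``profiles`` holds one log-profile per row (columns = FFT bin
    frequencies); ``labels`` the phase of each recording (e.g. "pre"/"mid").
    Returns the fitted results object with OOB accuracy and per-bin
    permutation importance (reusing the onset-model machinery).
    """
    labels = pd.Series(np.asarray(labels), index=profiles.index)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise InvalidInputError("need at least two profile labels")
    y = labels.map({lab: k for k, lab in enumerate(uniq)}).to_numpy()
    model = OnsetForest(
        profiles,
        y,
        n_trees=n_trees,
        class_weight=None,
        importance_repeats=importance_repeats,
        seed=seed,
    )
    return model.fit()
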