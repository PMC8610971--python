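"""1-D wavelet scattering transform for single-lead ECG signals.

A scattering network cascades wavelet convolutions and modulus nonlinearities,
then low-pass filters the result at the invariance scale, producing features
that are stable to translation and small deformation — a good fit for
beat-quasi-periodic signals.  The configuration used by the scattering model
is an invariance scale of 5 s with two Morlet filter banks of 8 and 2 wavelets
per octave.

Implementation: analytic Morlet filters defined directly on the positive FFT
frequencies of the full signal; order-1 paths ``|x * psi1| * phi`` and order-2
paths ``||x * psi1| * psi2| * phi`` are kept for centre frequencies
``xi2 < xi1/2`` (the energy of higher pairs is negligible).  The smoothed
outputs are subsampled at the frame centres, one frame per invariance window,
so a 10 s record yields two time frames.  The order-0 coefficient is the
modulus of the low-pass output, making every coefficient non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

XI_MAX = 0.35  # highest wavelet centre frequency, cycles/sample


@dataclass(frozen=True)
class ScatteringConfig:
    invariance_s: float = 5.0
    q1: int = 8
    q2: int = 2

    def frame_samples(self, fs: float) -> int:
        return int(round(self.invariance_s * fs))


def _morlet_bank(n: int, q: int, xi_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian (Morlet-style) analytic band-pass filters on an n-point grid.

    Returns (filters, centre_frequencies); filters are defined over the full
    FFT frequency axis but supported on positive frequencies only.
    """
    freqs = np.fft.fftfreq(n)
    xis = []
    xi = XI_MAX
    while xi > xi_min:
        xis.append(xi)
        xi *= 2.0 ** (-1.0 / q)
    if not xis:
        xis = [XI_MAX]
    bank = np.empty((len(xis), n))
    for i, xi_c in enumerate(xis):
        sigma = xi_c * (2.0 ** (1.0 / q) - 1.0)
        h = np.exp(-0.5 * ((freqs - xi_c) / sigma) ** 2)
        h[freqs <= 0] = 0.0
        bank[i] = h
    return bank, np.array(xis)


def _lowpass(n: int, frame: int) -> np.ndarray:
    """Gaussian low-pass at the invariance scale (time std = frame/4 samples)."""
    freqs = np.fft.fftfreq(n)
    sigma_t = frame / 4.0
    return np.exp(-2.0 * (np.pi * freqs * sigma_t) ** 2)


def _smooth_and_frame(z: np.ndarray, phi: np.ndarray,
                      centres: np.ndarray) -> np.ndarray:
    out = np.real(np.fft.ifft(np.fft.fft(z) * phi))
    return out[centres]


def scattering_features(signal: np.ndarray, fs: float,
                        config: ScatteringConfig | None = None) -> np.ndarray:
    """Scattering coefficients of one single-lead signal.

    Returns a ``(n_frames, n_coeffs)`` matrix: consecutive invariance-scale
    time intervals by [order-0, order-1..., order-2...] coefficients, all
    non-negative.  Raises if the signal is shorter than the invariance scale.
    """
    config = config or ScatteringConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("scattering_features expects a single-lead 1-D signal")
    n = x.size
    frame = config.frame_samples(fs)
    if n < frame:
        raise ValueError(
            f"signal length {n} is below the invariance scale ({frame} samples)")
    n_frames = n // frame
    centres = frame // 2 + frame * np.arange(n_frames)

    xi_min = 1.0 / frame
    bank1, xis1 = _morlet_bank(n, config.q1, xi_min)
    bank2, xis2 = _morlet_bank(n, config.q2, xi_min)
    phi = _lowpass(n, frame)

    X = np.fft.fft(x)
    coeffs = [np.abs(_smooth_and_frame(x.astype(complex), phi, centres))]

    u1 = []
    for h in bank1:
        u = np.abs(np.fft.ifft(X * h))
        u1.append(u)
        coeffs.append(_smooth_and_frame(u, phi, centres))
    for i, u in enumerate(u1):
        U = np.fft.fft(u)
        for j, h2 in enumerate(bank2):
            if xis2[j] >= xis1[i] / 2.0:
                continue
            u2 = np.abs(np.fft.ifft(U * h2))
            coeffs.append(_smooth_and_frame(u2, phi, centres))
    out = np.stack(coeffs, axis=1)  # (n_frames, n_coeffs)
    # smoothing of non-negative envelopes can undershoot by tiny negatives
    return np.maximum(out, 0.0)


def multichannel_scattering(signals: np.ndarray, fs: float,
                            config: ScatteringConfig | None = None) -> np.ndarray:
    """Per-lead scattering, concatenated per frame: (n_frames, 12 * n_coeffs)."""
    mats = [scattering_features(ch, fs, config) for ch in np.atleast_2d(signals)]
    return np.concatenate(mats, axis=1)
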