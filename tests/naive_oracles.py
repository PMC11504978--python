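"""Deliberately slow, loop-level reference implementations used as oracles.

These never import the pipeline code paths they check: the DFT is written
as an explicit double sum, Mel triangles as scalar loops, and the DCT as a
double loop, so agreement with the vectorized pipeline is meaningful.
"""

import numpy as np


def naive_dft_power(frame, n_fft):
    """|DFT|^2 on the one-sided grid, by the explicit O(N^2) sum."""
    x = np.zeros(n_fft)
    x[: len(frame)] = frame
    out = np.empty(n_fft // 2 + 1)
    n = np.arange(n_fft)
    for k in range(n_fft // 2 + 1):
        re = np.sum(x * np.cos(-2 * np.pi * k * n / n_fft))
        im = np.sum(x * np.sin(-2 * np.pi * k * n / n_fft))
        out[k] = re * re + im * im
    return out


def naive_mel_triangle_energies(power, boundary_bins, floor):
    """sum_k E(k) H_m(k) with triangles evaluated point by point."""
    m_filters = len(boundary_bins) - 2
    s = np.empty(m_filters)
    for m in range(1, m_filters + 1):
        left, center, right = boundary_bins[m - 1], boundary_bins[m], boundary_bins[m + 1]
        acc = 0.0
        for k in range(len(power)):
            if k < left or k > right:
                continue
            if k <= center:
                w = 1.0 if center == left else (k - left) / (center - left)
            else:
                w = 0.0 if right == center else (right - k) / (right - center)
            if k == center:
                w = 1.0
            acc += power[k] * w
        s[m - 1] = max(acc, floor)
    return s


def naive_dct(log_s, n_coeffs, offset):
    """sqrt(2/M) * sum_m log S(m) cos(pi n (2m+offset) / (2M)), double loop."""
    m_filters = len(log_s)
    out = np.empty(n_coeffs)
    for i, n in enumerate(range(1, n_coeffs + 1)):
        acc = 0.0
        for m in range(m_filters):
            acc += log_s[m] * np.cos(np.pi * n * (2 * m + offset) / (2 * m_filters))
        out[i] = np.sqrt(2.0 / m_filters) * acc
    return out


def naive_mfcc_frame(frame, boundary_bins, n_fft, n_coeffs, floor, offset):
    """Full frame -> cepstrum chain through the naive stages."""
    power = naive_dft_power(frame, n_fft)
    s = naive_mel_triangle_energies(power, boundary_bins, floor)
    return naive_dct(np.log(s), n_coeffs, offset)


def naive_delta(c, width):
    """Regression delta with edge replication, scalar loops."""
    t_max, d = c.shape
    out = np.zeros_like(c)
    denom = 2.0 * sum(tau * tau for tau in range(1, width + 1))
    for t in range(t_max):
        for tau in range(1, width + 1):
            hi = c[min(t + tau, t_max - 1)]
            lo = c[max(t - tau, 0)]
            out[t] += tau * (hi - lo)
    return out / denom


def band_energy_ratio(x, fs, f_cut):
    """Fraction of total spectral energy above f_cut, by direct rfft."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return spec[freqs > f_cut].sum() / spec.sum()
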