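"""Lightweight MCMC diagnostics: effective sample size (Geyer's initial
monotone sequence), Geweke z-scores and split-R-hat."""

from __future__ import annotations

import numpy as np


def autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance by FFT, lags 0..n-1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    return acov


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a single chain via Geyer's initial monotone positive sequence."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    acov = autocovariance(x)
    if acov[0] == 0:
        return float(n)
    rho = acov / acov[0]
    # sums of adjacent pairs; truncate at first negative, enforce monotone
    pair = rho[1:-1:2] + rho[2::2]
    tau = 1.0
    running_min = np.inf
    for p in pair:
        if p < 0:
            break
        running_min = min(running_min, p)
        tau += 2.0 * running_min
    return float(min(n, n / max(tau, 1e-12)))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z: compare means of the first and last chain
    fractions, with variances scaled by each segment's ESS."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if np.allclose(x, x[0]):
        return 0.0
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2) :]
    va = a.var(ddof=1) / max(effective_sample_size(a), 1.0)
    vb = b.var(ddof=1) / max(effective_sample_size(b), 1.0)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat for draws shaped (n_chains, n_draws)."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = splits.mean(axis=1)
    vars_ = splits.var(axis=1, ddof=1)
    W = vars_.mean()
    B = half * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))
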