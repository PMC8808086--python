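"""MCMC trace diagnostics."""

from __future__ import annotations

import numpy as np

__all__ = ["compute_ess"]


def compute_ess(trace: np.ndarray) -> float:
    """Effective sample size n / (1 + 2 * sum_k rho_k).

    Autocorrelations are summed by Geyer's initial-positive-sequence
    rule: consecutive pairs (rho_{2m-1} + rho_{2m}) are accumulated while
    they remain positive.  A constant trace returns 0, the "always
    excluded" sentinel.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("need a 1-D trace of length >= 10")
    n = len(x)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var < 1e-300:
        return 0.0
    # autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence over lag pairs (1,2), (3,4), ...
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    ess = n / (1.0 + 2.0 * s)
    return float(min(ess, n))
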