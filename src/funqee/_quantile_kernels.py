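"""Optional numba acceleration for the exact QMEM marginal likelihood.

The jitted kernel mirrors the vectorized numpy implementation in
``quantile_models`` term by term; the numpy path remains the reference
and a unit test pins the two together.  Importing this module never
fails: ``exact_loglik_jit`` is None when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
except Exception:  # pragma: no cover - numba is present in the target env
    njit = None

exact_loglik_jit = None

if njit is not None:

    @njit(cache=True)
    def _log_ndtr_scalar(x: float) -> float:
        # stable log Phi: direct erfc until it underflows, then the
        # standard asymptotic tail expansion
        if x > -25.0:
            return math.log(0.5 * math.erfc(-x * 0.7071067811865476))
        ix2 = 1.0 / (x * x)
        series = 1.0 - ix2 * (1.0 - 3.0 * ix2 * (1.0 - 5.0 * ix2))
        return -0.5 * x * x - math.log(-x) - 0.9189385332046727 + math.log(series)

    @njit(cache=True)
    def _log_ndtr_diff_scalar(lo: float, hi: float) -> float:
        # log(Phi(hi) - Phi(lo)); reflect right-tail intervals
        if hi <= lo:
            return -np.inf
        if lo > 0.0:
            lo, hi = -hi, -lo
        la = _log_ndtr_scalar(lo)
        lb = _log_ndtr_scalar(hi)
        d = la - lb
        if d > -0.6931472:
            return lb + math.log(-math.expm1(d))
        return lb + math.log1p(-math.exp(d))

    @njit(cache=True)
    def exact_loglik_jit(
        resid: np.ndarray,
        bounds: np.ndarray,
        tau: float,
        sigma_ald: float,
        sigma_b: float,
    ) -> float:
        """Sum over clusters of the closed-form log integral.

        ``resid`` is ordered by cluster; ``bounds`` gives the segment
        boundaries (J+1 entries).
        """
        total = resid.size * math.log(tau * (1.0 - tau) / sigma_ald)
        for j in range(bounds.size - 1):
            r = np.sort(resid[bounds[j] : bounds[j + 1]])
            nj = r.size
            csum = 0.0
            rtot = 0.0
            for i in range(nj):
                rtot += r[i]
            # online logsumexp over the nj+1 intervals
            mx = -np.inf
            acc = 0.0
            for k in range(nj + 1):
                m = (k - tau * nj) / sigma_ald
                alpha = (tau * (rtot - csum) - (1.0 - tau) * csum) / sigma_ald
                lo = -np.inf if k == 0 else r[k - 1]
                hi = np.inf if k == nj else r[k]
                shift = m * sigma_b
                lo_s = lo / sigma_b + shift if lo > -np.inf else -np.inf
                hi_s = hi / sigma_b + shift if hi < np.inf else np.inf
                term = -alpha + 0.5 * shift * shift + _log_ndtr_diff_scalar(lo_s, hi_s)
                if term > mx:
                    acc = acc * math.exp(mx - term) + 1.0
                    mx = term
                elif term > -np.inf:
                    acc += math.exp(term - mx)
                if k < nj:
                    csum += r[k]
            total += mx + math.log(acc)
        return total
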