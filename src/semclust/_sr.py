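"""Vectorized studentized-range tail probabilities.

Used for Tukey HSD p-values.  The generic scipy distribution object evaluates
its integral one point at a time (tens of milliseconds per call), which is
prohibitive for array-scale pipelines, so the double integral is evaluated
here with tensorized Gauss-Legendre quadrature:

    F(q; k, nu) = int_0^inf f_nu(s) * P(R_k <= q s) ds
    P(R_k <= u) = k * int phi(z) [Phi(z) - Phi(z - u)]^(k-1) dz

where ``s`` is the square root of a chi-square_nu / nu variate and ``R_k`` the
range of k standard normals.  With the default 64-point rules accuracy is
~2e-8 against scipy's implementation for k in 2..10 and nu >= 2 (verified in
the test suite).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, ndtr

_Z_LIM = 8.5
_NODES: dict[tuple[int, float, float], tuple[np.ndarray, np.ndarray]] = {}


def _gauss_nodes(n: int, lo: float, hi: float):
    key = (n, lo, hi)
    if key not in _NODES:
        x, w = np.polynomial.legendre.leggauss(n)
        half = 0.5 * (hi - lo)
        _NODES[key] = (lo + half * (x + 1.0), half * w)
    return _NODES[key]


def _range_cdf(u: np.ndarray, k: int, n_z: int = 64) -> np.ndarray:
    """P(range of k iid standard normals <= u), elementwise."""
    z, wz = _gauss_nodes(n_z, -_Z_LIM, _Z_LIM)
    phi = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    u = u[..., None]  # broadcast over z
    inner = np.clip(ndtr(z) - ndtr(z - u), 0.0, 1.0)
    return np.clip(k * np.sum(wz * phi * inner ** (k - 1), axis=-1), 0.0, 1.0)


def studentized_range_cdf(
    q, k: int, df: float, *, n_s: int = 64, n_z: int = 64
) -> np.ndarray:
    """CDF of the studentized range for ``k`` groups and ``df`` error dof."""
    if k < 2:
        raise ValueError("studentized range needs k >= 2")
    if df <= 0:
        raise ValueError("df must be positive")
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    out = np.zeros_like(q)
    pos = q > 0
    if np.any(pos):
        # s = sqrt(chi2_df / df): density 2 (df/2)^(df/2) / Gamma(df/2)
        #   * s^(df-1) exp(-df s^2 / 2)
        s_hi = 1.0 + 12.0 / math.sqrt(df)
        s, ws = _gauss_nodes(n_s, 1e-9, s_hi)
        log_fs = (
            math.log(2.0)
            + 0.5 * df * math.log(df / 2.0)
            - gammaln(df / 2.0)
            + (df - 1.0) * np.log(s)
            - 0.5 * df * s * s
        )
        fs = np.exp(log_fs)
        u = q[pos][:, None] * s[None, :]  # (nq, ns)
        # chunk the (nq, ns, nz) tensor to bound memory
        vals = np.empty(u.shape[0])
        step = max(1, 4_000_000 // (n_s * n_z))
        for i in range(0, u.shape[0], step):
            block = _range_cdf(u[i : i + step], k, n_z=n_z)
            vals[i : i + step] = np.sum(ws * fs * block, axis=-1)
        out[pos] = np.clip(vals, 0.0, 1.0)
    return out[0] if scalar else out


def studentized_range_sf(q, k: int, df: float, **kw) -> np.ndarray:
    """Survival function 1 - CDF (upper tail), elementwise over ``q``."""
    return 1.0 - studentized_range_cdf(q, k, df, **kw)
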