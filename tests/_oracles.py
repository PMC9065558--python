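"""Independent reference computations used to check the fitters.

These deliberately avoid the package's solution paths: relaxation times are
recovered by dense grid search over the parameter(s) with the amplitude
profiled out linearly, refined by recursive zooming — no linearization, no
ratio tricks, no golden section.
"""

from __future__ import annotations

import numpy as np


def _profiled_ss(signals: np.ndarray, model_shapes: np.ndarray) -> np.ndarray:
    """Residual sum of squares with the amplitude solved per candidate.

    ``model_shapes`` is (n_candidates, n_frames); the best amplitude for
    candidate c is (s.m_c)/(m_c.m_c).
    """
    mm = (model_shapes**2).sum(axis=1)
    sm = model_shapes @ signals
    return (signals**2).sum() - sm**2 / mm


def grid_fit_decay(signals, tes, lo=1.0, hi=5000.0, n=400, zooms=2) -> float:
    """T2 by dense grid search on A*exp(-TE/T2)."""
    tes = np.asarray(tes, dtype=float)
    for _ in range(zooms + 1):
        cand = np.logspace(np.log10(lo), np.log10(hi), n)
        shapes = np.exp(-tes[None, :] / cand[:, None])
        best = int(np.argmin(_profiled_ss(np.asarray(signals, float), shapes)))
        lo = cand[max(best - 1, 0)]
        hi = cand[min(best + 1, n - 1)]
    return float(cand[best])


def grid_fit_vfa(signals, flip_deg, tr_ms, lo=1.0, hi=10000.0, n=400, zooms=2) -> float:
    """T1 by dense grid search on the spoiled-GRE signal shape."""
    th = np.deg2rad(np.asarray(flip_deg, dtype=float))
    for _ in range(zooms + 1):
        cand = np.logspace(np.log10(lo), np.log10(hi), n)
        e1 = np.exp(-tr_ms / cand)[:, None]
        shapes = np.sin(th)[None, :] * (1 - e1) / (1 - np.cos(th)[None, :] * e1)
        best = int(np.argmin(_profiled_ss(np.asarray(signals, float), shapes)))
        lo = cand[max(best - 1, 0)]
        hi = cand[min(best + 1, n - 1)]
    return float(cand[best])


def magic_shapes(t1_cand, t2_cand, tis, tes, tr_ms, sat_flip_deg, exc_flip_deg, b1=1.0):
    """|recovery| x decay model shapes for a (T1, T2) candidate grid.

    Returns (n_t1, n_t2, n_frames) with frames delay-major, echo-minor.
    """
    t1_cand = np.asarray(t1_cand, float)
    t2_cand = np.asarray(t2_cand, float)
    ct = np.cos(np.deg2rad(sat_flip_deg) * b1)
    ca = np.cos(np.deg2rad(exc_flip_deg) * b1)
    e_tr = np.exp(-tr_ms / t1_cand)
    denom = 1.0 - ca - ct * e_tr
    rec = (
        1.0
        - (1.0 - ct) * np.exp(-np.asarray(tis)[None, :] / t1_cand[:, None])
        - ct * e_tr[:, None]
    ) / denom[:, None]
    rec = np.abs(rec)  # magnitude detection
    dec = np.exp(-np.asarray(tes)[None, :] / t2_cand[:, None])
    return rec[:, None, :, None] * dec[None, :, None, :]


def grid_fit_magic(
    signals,
    tis,
    tes,
    tr_ms,
    sat_flip_deg=120.0,
    exc_flip_deg=90.0,
    b1=1.0,
    t1_range=(5.0, 9000.0),
    t2_range=(1.0, 4500.0),
    n=60,
    zooms=3,
) -> tuple[float, float]:
    """(T1, T2) by dense 2-D grid search with profiled amplitude."""
    s = np.asarray(signals, dtype=float).ravel()
    lo1, hi1 = t1_range
    lo2, hi2 = t2_range
    for _ in range(zooms + 1):
        c1 = np.logspace(np.log10(lo1), np.log10(hi1), n)
        c2 = np.logspace(np.log10(lo2), np.log10(hi2), n)
        shapes = magic_shapes(c1, c2, tis, tes, tr_ms, sat_flip_deg, exc_flip_deg, b1)
        flat = shapes.reshape(n * n, -1)
        ss = _profiled_ss(s, flat)
        b = int(np.argmin(ss))
        i, j = divmod(b, n)
        lo1, hi1 = c1[max(i - 1, 0)], c1[min(i + 1, n - 1)]
        lo2, hi2 = c2[max(j - 1, 0)], c2[min(j + 1, n - 1)]
    return float(c1[i]), float(c2[j])
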