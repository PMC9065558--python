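"""Per-voxel inversion of the relaxometry forward models.

Three fitters produce parameter maps from multi-frame magnitude stacks:

* :func:`fit_vfa_t1` — variable-flip-angle T1 mapping via the linearized
  DESPOT1 regression (signal/sin vs signal/tan), optionally refined by
  trust-region nonlinear least squares.
* :func:`fit_mese_t2` — multi-echo spin-echo T2 mapping via weighted
  log-linear regression (weights ~ S^2 to counter log-noise amplification).
* :func:`fit_magic` — staged inversion of the multispectral
  saturation-recovery model: T2 from the echo decay, then T1 by
  variable projection over the saturation-delay dependence (the amplitude is
  solved linearly for each candidate T1, so only a 1-D search in T1 remains),
  then PD from the amplitude.  Optional joint (T1, T2, PD) refinement.

Voxels whose maximum frame signal falls below 1% of the stack's 99th
percentile are treated as background and masked; voxels whose intermediate
quantities leave the physical domain (DESPOT1 slope outside (0,1),
non-positive log ratios, parameters outside bounds) are masked rather than
clipped, to avoid silent bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .signal_models import (
    B1Scale,
    MagicProtocol,
    MeseProtocol,
    VfaProtocol,
)

__all__ = [
    "ImageStack",
    "ParameterMap",
    "VoiStats",
    "fit_vfa_t1",
    "fit_mese_t2",
    "fit_magic",
    "voi_stats",
    "T1_BOUNDS_MS",
    "T2_BOUNDS_MS",
]

T1_BOUNDS_MS = (1.0, 10_000.0)
T2_BOUNDS_MS = (0.1, 5_000.0)
MASK_THRESHOLD_FRACTION = 0.01
_NLLS_XTOL = 1e-8
_NLLS_MAX_ITER = 200


@dataclass
class ImageStack:
    """Ordered set of equally shaped magnitude frames with pixel geometry.

    ``data`` has the frame axis first: (n_frames, *spatial).  Frames are one
    per flip angle (VFA), one per echo (ME-SE) or delay-major/echo-minor for
    the multispectral acquisition.
    """

    data: np.ndarray
    axis_labels: Sequence[str] = ()
    pixel_size_mm: tuple[float, float] = (1.02, 1.02)
    slice_thickness_mm: float = 2.5
    slice_spacing_mm: float = 2.5

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 3:
            raise ValueError("stack data must be (n_frames, *spatial) with >=2 spatial dims")
        if np.any(self.data < 0):
            raise ValueError("magnitude frames must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]


@dataclass
class ParameterMap:
    """A fitted per-voxel parameter with validity mask and fit residual."""

    values: np.ndarray
    mask: np.ndarray
    fit_residual: np.ndarray
    method_tag: str = ""
    flags: np.ndarray | None = None  # e.g. NLLS fallback-to-linear markers

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.fit_residual = np.asarray(self.fit_residual, dtype=float)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if np.any(~np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside validity mask")


@dataclass
class VoiStats:
    """Summary statistics over a volume of interest."""

    mean: float
    sd: float
    cv_percent: float
    n_voxels: int


def _finalize(values, valid, residual, tag, spatial_shape, flags=None) -> ParameterMap:
    """Reshape flat per-voxel arrays into a map, zeroing masked voxels."""
    out = np.zeros(spatial_shape, dtype=float)
    res = np.zeros(spatial_shape, dtype=float)
    v = np.where(valid & np.isfinite(values), values, 0.0)
    out.flat[:] = v
    res.flat[:] = np.where(valid & np.isfinite(residual), residual, 0.0)
    mask = np.zeros(spatial_shape, dtype=bool)
    mask.flat[:] = valid
    fl = None
    if flags is not None:
        fl = np.zeros(spatial_shape, dtype=bool)
        fl.flat[:] = flags
    return ParameterMap(out, mask, res, method_tag=tag, flags=fl)


def _signal_mask(frames: np.ndarray) -> np.ndarray:
    """Background suppression: max frame signal >= 1% of the 99th percentile."""
    ref = np.percentile(frames, 99)
    return frames.max(axis=0) >= MASK_THRESHOLD_FRACTION * ref


def _b1_flat(b1: B1Scale | None, n_vox: int) -> np.ndarray | float:
    if b1 is None:
        return 1.0
    arr = np.asarray(b1.b1, dtype=float)
    if arr.ndim == 0:
        return float(arr)
    if arr.size != n_vox:
        raise ValueError(f"b1 map size {arr.size} does not match {n_vox} voxels")
    return arr.reshape(-1)


def fit_vfa_t1(
    stack: ImageStack,
    protocol: VfaProtocol,
    b1: B1Scale | None = None,
    refine: bool = False,
) -> tuple[ParameterMap, ParameterMap]:
    """DESPOT1 T1 fit from a variable-flip-angle stack.

    Regresses y = S/sin(B1*theta) on x = S/tan(B1*theta); the slope is
    E1 = exp(-TR/T1) and the intercept is M0*(1-E1).  Returns (t1_map,
    m0_map); M0 is the effective amplitude K*pd*exp(-TE/T2*) divided by the
    protocol's scale factor K.  No transmit-field correction is applied
    unless a ``b1`` scale is passed explicitly.
    """
    angles = np.asarray(protocol.flip_angles_deg, dtype=float)
    if stack.n_frames != angles.size:
        raise ValueError(
            f"stack has {stack.n_frames} frames but protocol lists {angles.size} flip angles"
        )
    if angles.size < 2:
        raise ValueError("at least 2 flip angles are required")
    if np.unique(angles).size < 2:
        raise ValueError("flip angles must not be all equal")

    spatial = stack.spatial_shape
    s = stack.data.reshape(stack.n_frames, -1)
    n_vox = s.shape[1]
    b1f = _b1_flat(b1, n_vox)
    theta = np.deg2rad(angles)[:, None] * b1f  # (nf, nvox) or (nf, 1)
    sin_t, tan_t = np.sin(theta), np.tan(theta)
    y = s / sin_t
    x = s / tan_t
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    xc = x - xm
    sxx = (xc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (xc * (y - ym)).sum(axis=0) / sxx
    intercept = ym - slope * xm

    sigmask = _signal_mask(s)
    valid = sigmask & np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = -protocol.tr_ms / np.log(slope)
        m0 = intercept / (1.0 - slope) / protocol.scale_k
    valid &= np.isfinite(t1) & (t1 >= T1_BOUNDS_MS[0]) & (t1 <= T1_BOUNDS_MS[1])

    flags = np.zeros(n_vox, dtype=bool)
    if refine:
        t1, m0, flags = _refine_vfa(s, theta, protocol, t1, m0, valid)

    resid = _vfa_residual(s, theta, protocol, t1, m0)
    t1_map = _finalize(t1, valid, resid, "vfa-despot1" + ("+nlls" if refine else ""), spatial, flags)
    m0_map = _finalize(m0, valid, resid, t1_map.method_tag, spatial, flags)
    return t1_map, m0_map


def _vfa_model(theta_col, tr, k, t1, m0):
    e1 = np.exp(-tr / t1)
    return k * m0 * np.sin(theta_col) * (1 - e1) / (1 - np.cos(theta_col) * e1)


def _vfa_residual(s, theta, protocol, t1, m0):
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        model = _vfa_model(theta, protocol.tr_ms, protocol.scale_k, t1[None, :], m0[None, :])
        # Invalid voxels produce non-finite model values; their residuals are
        # zeroed at finalization, so substitute 0 rather than propagate NaN.
        r = np.sqrt(np.mean((np.nan_to_num(model, nan=0.0, posinf=0.0, neginf=0.0) - s) ** 2, axis=0))
    return r


def _refine_vfa(s, theta, protocol, t1, m0, valid):
    t1r, m0r = t1.copy(), m0.copy()
    flags = np.zeros(t1.size, dtype=bool)
    theta_full = np.broadcast_to(theta, s.shape)
    for i in np.flatnonzero(valid):
        th = theta_full[:, i]
        si = s[:, i]

        def resid(p):
            return _vfa_model(th, protocol.tr_ms, protocol.scale_k, p[0], p[1]) - si

        try:
            sol = least_squares(
                resid,
                x0=[t1[i], max(m0[i], 1e-12)],
                bounds=([T1_BOUNDS_MS[0], 0.0], [T1_BOUNDS_MS[1], np.inf]),
                xtol=_NLLS_XTOL,
                max_nfev=_NLLS_MAX_ITER * 3,
            )
            if sol.success:
                t1r[i], m0r[i] = sol.x
            else:
                flags[i] = True
        except Exception:
            flags[i] = True
    return t1r, m0r, flags


def fit_mese_t2(
    stack: ImageStack,
    protocol: MeseProtocol,
    refine: bool = False,
) -> tuple[ParameterMap, ParameterMap]:
    """Mono-exponential T2 fit from a multi-echo spin-echo stack.

    Weighted least squares of ln(S) on TE with weights proportional to S^2;
    the slope is -1/T2 and the amplitude absorbs K*pd*(1-exp(-TR/T1)).
    Returns (t2_map, amp_map); the amplitude map is divided by the protocol
    scale factor.  Voxels with non-positive signals in any echo, or with a
    non-negative decay slope (e.g. constant signal), are masked.
    """
    tes = np.asarray(protocol.te_list_ms, dtype=float)
    if stack.n_frames != tes.size:
        raise ValueError(
            f"stack has {stack.n_frames} frames but protocol lists {tes.size} echoes"
        )
    if tes.size < 2:
        raise ValueError("at least 2 echoes are required")

    spatial = stack.spatial_shape
    s = stack.data.reshape(stack.n_frames, -1)
    n_vox = s.shape[1]
    positive = s > 0
    sigmask = _signal_mask(s) & np.all(positive, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(positive, np.log(np.where(positive, s, 1.0)), np.nan)
    w = s**2
    wsum = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        te_bar = (w * tes[:, None]).sum(axis=0) / wsum
        y_bar = np.nansum(w * logs, axis=0) / wsum
        tec = tes[:, None] - te_bar
        slope = np.nansum(w * tec * (logs - y_bar), axis=0) / (w * tec**2).sum(axis=0)
        intercept = y_bar - slope * te_bar
        t2 = -1.0 / slope
        amp = np.exp(intercept) / protocol.scale_k

    valid = sigmask & np.isfinite(t2) & (slope < 0.0)
    valid &= (t2 >= T2_BOUNDS_MS[0]) & (t2 <= T2_BOUNDS_MS[1])

    flags = np.zeros(n_vox, dtype=bool)
    if refine:
        t2, amp, flags = _refine_mese(s, tes, protocol, t2, amp, valid)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        model = protocol.scale_k * amp[None, :] * np.exp(-tes[:, None] / t2[None, :])
        model = np.nan_to_num(model, nan=0.0, posinf=0.0, neginf=0.0)
        resid = np.sqrt(np.mean((model - s) ** 2, axis=0))
    tag = "mese-loglin" + ("+nlls" if refine else "")
    t2_map = _finalize(t2, valid, resid, tag, spatial, flags)
    amp_map = _finalize(amp, valid, resid, tag, spatial, flags)
    return t2_map, amp_map


def _refine_mese(s, tes, protocol, t2, amp, valid):
    t2r, ampr = t2.copy(), amp.copy()
    flags = np.zeros(t2.size, dtype=bool)
    for i in np.flatnonzero(valid):
        si = s[:, i]

        def resid(p):
            return protocol.scale_k * p[1] * np.exp(-tes / p[0]) - si

        try:
            sol = least_squares(
                resid,
                x0=[t2[i], max(amp[i], 1e-12)],
                bounds=([T2_BOUNDS_MS[0], 0.0], [T2_BOUNDS_MS[1], np.inf]),
                xtol=_NLLS_XTOL,
                max_nfev=_NLLS_MAX_ITER * 3,
            )
            if sol.success:
                t2r[i], ampr[i] = sol.x
            else:
                flags[i] = True
        except Exception:
            flags[i] = True
    return t2r, ampr, flags


# ---------------------------------------------------------------------------
# Multispectral (saturation-recovery) fit


def _magic_recovery_matrix(t1, protocol, cos_theta, cos_alpha):
    """R(TI_d, T1_v) for delays x voxels; t1 is (nvox,) or scalar."""
    tis = np.asarray(protocol.sat_delays_ms, dtype=float)
    e_tr = np.exp(-protocol.tr_ms / t1)
    denom = 1.0 - cos_alpha - cos_theta * e_tr
    e_ti = np.exp(-tis[:, None] / np.atleast_1d(t1)[None, :])
    return (1.0 - (1.0 - cos_theta) * e_ti - cos_theta * e_tr) / denom


def _magic_t1_objective(t1, s_proj, protocol, cos_theta, cos_alpha):
    """Profiled residual over T1 candidates; amplitude solved linearly.

    Magnitude detection: the data are |A * R(TI)|, so the model fitted is
    A * |R|.  Returns (sum-of-squares residual, amplitude) per voxel for a
    per-voxel T1 vector.
    """
    r = np.abs(_magic_recovery_matrix(t1, protocol, cos_theta, cos_alpha))  # (nd, nvox)
    rr = (r * r).sum(axis=0)
    sr = (s_proj * r).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sr / rr
    ss = (s_proj**2).sum(axis=0) - np.where(rr > 0, sr**2 / rr, 0.0)
    return ss, a


def fit_magic(
    stack: ImageStack,
    protocol: MagicProtocol,
    b1: B1Scale | None = None,
    refine: bool = False,
) -> tuple[ParameterMap, ParameterMap, ParameterMap]:
    """Staged inversion of the multispectral saturation-recovery model.

    Stack frames must be ordered delay-major, echo-minor.  Stages:

    1. T2 per voxel from the weighted log-linear echo decay, with the
       per-delay slopes averaged (weights ~ signal^2).
    2. The echo dimension is projected out: for each delay the TE-corrected
       amplitude ``A*R(TI)`` is the least-squares projection of the echo
       signals onto exp(-TE/T2).
    3. T1 by variable projection: a coarse log-spaced candidate grid
       followed by per-voxel golden-section refinement of the profiled
       residual; the amplitude A = K*pd falls out linearly.
    4. Optional joint (T1, T2, PD) trust-region refinement on all frames.

    Returns (t1_map, t2_map, pd_map); PD is A divided by the protocol scale
    factor.
    """
    tes = np.asarray(protocol.te_list_ms, dtype=float)
    tis = np.asarray(protocol.sat_delays_ms, dtype=float)
    nd, ne = tis.size, tes.size
    if nd < 2 or ne < 2:
        raise ValueError("at least 2 delays and 2 echoes are required")
    if stack.n_frames != nd * ne:
        raise ValueError(
            f"stack has {stack.n_frames} frames, expected {nd}x{ne}="
            f"{nd * ne} (delay-major, echo-minor)"
        )

    spatial = stack.spatial_shape
    s = stack.data.reshape(nd, ne, -1)
    n_vox = s.shape[2]
    sflat = stack.data.reshape(nd * ne, -1)
    sigmask = _signal_mask(sflat)

    b1f = _b1_flat(b1, n_vox)
    cos_theta = np.cos(np.deg2rad(protocol.sat_flip_deg) * b1f)
    cos_alpha = np.cos(np.deg2rad(protocol.exc_flip_deg) * b1f)

    # --- stage 1: T2 from echo decay, per delay, averaged ------------------
    positive = s > 0
    all_pos = np.all(positive, axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(positive, np.log(np.where(positive, s, 1.0)), np.nan)
    w = s**2
    wsum = w.sum(axis=1)  # (nd, nvox)
    with np.errstate(divide="ignore", invalid="ignore"):
        te_bar = (w * tes[None, :, None]).sum(axis=1) / wsum
        y_bar = np.nansum(w * logs, axis=1) / wsum
        tec = tes[None, :, None] - te_bar[:, None, :]
        slope_d = np.nansum(w * tec * (logs - y_bar[:, None, :]), axis=1) / (w * tec**2).sum(axis=1)
        wd = wsum  # weight each delay's slope by its total signal power
        slope = (wd * slope_d).sum(axis=0) / wd.sum(axis=0)
        t2 = -1.0 / slope

    valid = sigmask & all_pos & np.isfinite(t2) & (slope < 0.0)
    valid &= (t2 >= T2_BOUNDS_MS[0]) & (t2 <= T2_BOUNDS_MS[1])
    t2_safe = np.where(valid, t2, 100.0)

    # --- stage 2: project out the echo dimension ----------------------------
    f = np.exp(-tes[None, :, None] / t2_safe[None, None, :])  # (1, ne, nvox)
    s_proj = (s * f).sum(axis=1) / (f * f).sum(axis=1)  # (nd, nvox) = A * R(TI)

    # --- stage 3: T1 grid + golden-section ----------------------------------
    log_lo, log_hi = np.log10(T1_BOUNDS_MS[0]), np.log10(T1_BOUNDS_MS[1])
    grid = np.logspace(log_lo, log_hi, 80)
    best_ss = np.full(n_vox, np.inf)
    best_idx = np.zeros(n_vox, dtype=int)
    for k, t1c in enumerate(grid):
        ss, _ = _magic_t1_objective(np.full(n_vox, t1c), s_proj, protocol, cos_theta, cos_alpha)
        better = ss < best_ss
        best_ss = np.where(better, ss, best_ss)
        best_idx = np.where(better, k, best_idx)
    lo = np.log10(grid[np.maximum(best_idx - 1, 0)])
    hi = np.log10(grid[np.minimum(best_idx + 1, grid.size - 1)])

    t1 = _golden_section_vec(
        lambda lt: _magic_t1_objective(10**lt, s_proj, protocol, cos_theta, cos_alpha)[0],
        lo,
        hi,
        n_iter=60,
    )
    _, a = _magic_t1_objective(t1, s_proj, protocol, cos_theta, cos_alpha)
    valid &= np.isfinite(t1) & np.isfinite(a) & (a > 0)
    valid &= (t1 >= T1_BOUNDS_MS[0]) & (t1 <= T1_BOUNDS_MS[1])

    flags = np.zeros(n_vox, dtype=bool)
    if refine:
        t1, t2, a, flags = _refine_magic(s, tes, tis, protocol, cos_theta, cos_alpha, t1, t2, a, valid)

    pd = a / protocol.scale_k
    resid = _magic_residual(s, tes, protocol, cos_theta, cos_alpha, t1, t2, a, valid)
    tag = "magic-staged" + ("+nlls" if refine else "")
    t1_map = _finalize(t1, valid, resid, tag, spatial, flags)
    t2_map = _finalize(t2, valid, resid, tag, spatial, flags)
    pd_map = _finalize(pd, valid, resid, tag, spatial, flags)
    return t1_map, t2_map, pd_map


def _magic_residual(s, tes, protocol, cos_theta, cos_alpha, t1, t2, a, valid):
    nd, ne, n_vox = s.shape
    t1s = np.where(valid & np.isfinite(t1) & (t1 > 0), t1, 1.0)
    t2s = np.where(valid & np.isfinite(t2) & (t2 > 0), t2, 1.0)
    r = np.abs(_magic_recovery_matrix(t1s, protocol, cos_theta, cos_alpha))  # (nd, nvox)
    decay = np.exp(-tes[None, :, None] / t2s[None, None, :])  # (1, ne, nvox)
    model = a[None, None, :] * r[:, None, :] * decay
    return np.sqrt(np.mean((model - s) ** 2, axis=(0, 1)))


def _refine_magic(s, tes, tis, protocol, cos_theta, cos_alpha, t1, t2, a, valid):
    t1r, t2r, ar = t1.copy(), t2.copy(), a.copy()
    flags = np.zeros(t1.size, dtype=bool)
    scalar_b1 = np.ndim(cos_theta) == 0
    for i in np.flatnonzero(valid):
        ct = cos_theta if scalar_b1 else cos_theta[i]
        ca = cos_alpha if scalar_b1 else cos_alpha[i]
        si = s[:, :, i].ravel()

        def resid(p):
            e_tr = np.exp(-protocol.tr_ms / p[0])
            denom = 1.0 - ca - ct * e_tr
            r = np.abs((1.0 - (1.0 - ct) * np.exp(-tis / p[0]) - ct * e_tr) / denom)
            model = p[2] * r[:, None] * np.exp(-tes[None, :] / p[1])
            return model.ravel() - si

        try:
            sol = least_squares(
                resid,
                x0=[t1[i], t2[i], max(a[i], 1e-12)],
                bounds=(
                    [T1_BOUNDS_MS[0], T2_BOUNDS_MS[0], 0.0],
                    [T1_BOUNDS_MS[1], T2_BOUNDS_MS[1], np.inf],
                ),
                xtol=_NLLS_XTOL,
                max_nfev=_NLLS_MAX_ITER * 4,
            )
            if sol.success:
                t1r[i], t2r[i], ar[i] = sol.x
            else:
                flags[i] = True
        except Exception:
            flags[i] = True
    return t1r, t2r, ar, flags


def _golden_section_vec(f, lo, hi, n_iter=60):
    """Element-wise golden-section minimization over per-voxel brackets.

    ``f`` maps a per-voxel argument vector to a per-voxel objective vector;
    ``lo``/``hi`` bracket the minimum per voxel (here in log10-T1 space).
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.astype(float).copy(), hi.astype(float).copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(n_iter):
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        # Recompute both probe points; element-wise reuse of the surviving
        # evaluation is not worth the bookkeeping at these problem sizes.
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
    mid = 0.5 * (a + b)
    return 10**mid


def voi_stats(pmap: ParameterMap, mask: np.ndarray, name: str = "VOI") -> VoiStats:
    """Mean, SD (n-1 denominator) and CV% of a parameter map over a VOI.

    ``mask`` is a boolean array over the map's spatial shape; only voxels
    that are also inside the map's validity mask contribute.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.values.shape:
        raise ValueError(f"{name}: mask shape {mask.shape} != map shape {pmap.values.shape}")
    sel = mask & pmap.mask
    n = int(sel.sum())
    if n < 1:
        raise ValueError(f"{name}: no valid voxels inside the VOI")
    vals = pmap.values[sel]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return VoiStats(mean=mean, sd=sd, cv_percent=cv, n_voxels=n)
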