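"""Digital phantoms and simulated acquisitions.

Everything the analysis modules consume can be generated here with known
ground truth:

* :func:`make_insert_phantom` — a water-filled box carrying eight narrow
  gadolinium-doped inserts whose T1/T2 reference values span 29-2386 ms /
  25-1311 ms, rasterized as piecewise-constant truth maps plus a label
  image.
* :func:`make_qa_phantom` — a cylindrical QA phantom slice stack with the
  standard feature layout (uniform disk, landmark grid, ramp insert,
  diagonal rod, line-pair groups) rendered analytically.  Sub-pixel
  features (ramp, rod, dots, bars) use exact area-coverage weighting — the
  through-plane signal integration a scanner performs — while the disk edge
  is binary so geometric targets stay quantization-exact.
* :func:`simulate_acquisition` — forward-evaluates the matching signal
  model frame by frame, applies an optional multiplicative bias field and
  adds seeded Gaussian or Rician noise (Rician = magnitude of two
  independent Gaussian channels).
* :func:`simulate_sessions` — repeats an acquisition over n sessions with
  session-wise gain and parameter jitter; session 1 is the unperturbed
  reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .map_fitting import ImageStack, ParameterMap
from .phantom_qa import QaLayout, QaNominal
from .signal_models import (
    B1Scale,
    MagicProtocol,
    MeseProtocol,
    TissueParams,
    VfaProtocol,
    magic_signal,
    mese_signal,
    spgr_signal,
)

__all__ = [
    "INSERT_REFERENCE_VALUES",
    "InsertPhantomSpec",
    "NoiseModel",
    "SessionDrift",
    "make_insert_phantom",
    "make_qa_phantom",
    "simulate_acquisition",
    "simulate_sessions",
    "smooth_bias_field",
]

# Reference (T1_ms, T2_ms) of the eight gadoteric-acid inserts, ordered I1..I8
# (decreasing concentration, pure water last).
INSERT_REFERENCE_VALUES: tuple[tuple[float, float], ...] = (
    (29.1, 24.7),
    (57.7, 48.8),
    (113.1, 95.5),
    (217.8, 181.7),
    (489.7, 399.6),
    (838.9, 665.6),
    (1303.8, 997.5),
    (2385.7, 1311.3),
)


def _default_inserts() -> tuple[TissueParams, ...]:
    return tuple(TissueParams(t1_ms=t1, t2_ms=t2, pd=1.0) for t1, t2 in INSERT_REFERENCE_VALUES)


def _default_background() -> TissueParams:
    # Water-like surround of the insert box.
    return TissueParams(t1_ms=2800.0, t2_ms=1500.0, pd=1.0)


@dataclass
class InsertPhantomSpec:
    """Geometry and ground truth of the eight-insert relaxometry phantom."""

    insert_params: Sequence[TissueParams] = field(default_factory=_default_inserts)
    background: TissueParams = field(default_factory=_default_background)
    insert_width_mm: float = 10.0
    insert_height_mm: float = 50.0
    grid: tuple[int, int] = (2, 4)  # rows x columns of inserts
    column_pitch_mm: float = 25.0
    row_pitch_mm: float = 60.0
    pixel_size_mm: tuple[float, float] = (1.02, 1.02)
    shape: tuple[int, int] = (128, 128)
    n_slices: int = 1
    slice_thickness_mm: float = 2.5

    def __post_init__(self):
        if self.insert_width_mm <= 0 or self.insert_height_mm <= 0:
            raise ValueError("insert dimensions must be positive")
        if len(self.insert_params) > self.grid[0] * self.grid[1]:
            raise ValueError("more inserts than grid cells")


@dataclass
class NoiseModel:
    """Magnitude-image noise: none, additive Gaussian, or Rician.

    ``sigma`` is the per-channel noise SD in signal units; alternatively
    ``target_snr`` sets sigma to (99th percentile of the noiseless stack) /
    target_snr.  Reproducible under a fixed seed.
    """

    kind: str = "none"  # none | gaussian | rician
    sigma: float | None = None
    target_snr: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind != "none" and self.sigma is None and self.target_snr is None:
            raise ValueError("noisy models need sigma or target_snr")

    def resolve_sigma(self, frames: np.ndarray) -> float:
        if self.sigma is not None:
            return float(self.sigma)
        return float(np.percentile(frames, 99) / self.target_snr)

    def apply(self, frames: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return frames
        rng = np.random.default_rng(self.seed)
        sig = self.resolve_sigma(frames)
        if self.kind == "gaussian":
            return np.clip(frames + rng.normal(0.0, sig, frames.shape), 0.0, None)
        re = frames + rng.normal(0.0, sig, frames.shape)
        im = rng.normal(0.0, sig, frames.shape)
        return np.hypot(re, im)


@dataclass
class SessionDrift:
    """Session-to-session perturbations for repeatability studies.

    Gain jitter is a session-wise multiplicative factor shared by every
    frame of the session (so ratio-based fits cancel it); parameter jitter
    multiplies the T1/T2 truth maps.  Session 1 is never perturbed.
    """

    gain_jitter_sd_percent: float = 2.0
    param_jitter_sd_percent: float = 0.0
    n_sessions: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_sessions < 2:
            raise ValueError("at least 2 sessions are required")


# ---------------------------------------------------------------------------
# Insert phantom


def make_insert_phantom(
    spec: InsertPhantomSpec | None = None,
) -> tuple[ParameterMap, ParameterMap, ParameterMap, np.ndarray]:
    """Rasterize the insert phantom into truth maps and a label image.

    Returns (t1_truth, t2_truth, pd_truth, labels) with labels 1..n for the
    inserts (row-major across the grid) and 0 for the water background.
    Truth maps are exactly piecewise constant.
    """
    spec = spec or InsertPhantomSpec()
    ny, nx = spec.shape
    px_x, px_y = spec.pixel_size_mm
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    y_mm = (yy - cy) * px_y
    x_mm = (xx - cx) * px_x

    t1 = np.full(spec.shape, float(np.asarray(spec.background.t1_ms)))
    t2 = np.full(spec.shape, float(np.asarray(spec.background.t2_ms)))
    pd = np.full(spec.shape, float(np.asarray(spec.background.pd)))
    labels = np.zeros(spec.shape, dtype=int)

    rows, cols = spec.grid
    half_w, half_h = spec.insert_width_mm / 2.0, spec.insert_height_mm / 2.0
    fov_y, fov_x = ny * px_y / 2.0, nx * px_x / 2.0
    for k, params in enumerate(spec.insert_params):
        r, c = divmod(k, cols)
        yc = (r - (rows - 1) / 2.0) * spec.row_pitch_mm
        xc = (c - (cols - 1) / 2.0) * spec.column_pitch_mm
        if abs(yc) + half_h > fov_y or abs(xc) + half_w > fov_x:
            raise ValueError(f"insert {k + 1} exceeds the field of view")
        sel = (np.abs(y_mm - yc) <= half_h) & (np.abs(x_mm - xc) <= half_w)
        if np.any(labels[sel] != 0):
            raise ValueError(f"insert {k + 1} overlaps another insert")
        labels[sel] = k + 1
        t1[sel] = float(np.asarray(params.t1_ms))
        t2[sel] = float(np.asarray(params.t2_ms))
        pd[sel] = float(np.asarray(params.pd))

    if spec.n_slices > 1:
        t1 = np.repeat(t1[None], spec.n_slices, axis=0)
        t2 = np.repeat(t2[None], spec.n_slices, axis=0)
        pd = np.repeat(pd[None], spec.n_slices, axis=0)
        labels = np.repeat(labels[None], spec.n_slices, axis=0)

    full = np.ones_like(t1, dtype=bool)
    zeros = np.zeros_like(t1)
    return (
        ParameterMap(t1, full, zeros, "truth"),
        ParameterMap(t2, full, zeros, "truth"),
        ParameterMap(pd, full, zeros, "truth"),
        labels,
    )


# ---------------------------------------------------------------------------
# QA phantom rendering


def _cov1d(n: int, a: float, b: float) -> np.ndarray:
    """Fractional coverage of interval [a, b] (pixel units) per pixel."""
    i = np.arange(n)
    return np.clip(np.minimum(b, i + 0.5) - np.maximum(a, i - 0.5), 0.0, 1.0)


def _add_rect(img: np.ndarray, layout: QaLayout, yc, xc, half_h, half_w, amp=1.0):
    shape = img.shape
    y0, x0 = layout.mm_to_px(yc - half_h, xc - half_w, shape)
    y1, x1 = layout.mm_to_px(yc + half_h, xc + half_w, shape)
    img += amp * np.outer(_cov1d(shape[0], y0, y1), _cov1d(shape[1], x0, x1))


def _add_linepair_group(img, layout, nominal, gi, amp=1.0, subsamples=64):
    shape = img.shape
    freq = nominal.linepair_groups_plcm[gi]
    period_mm = 10.0 / freq
    width = layout.linepair_group_width_mm(gi)
    yc = layout.linepair_group_center_y_mm(gi)
    half_h = layout.LINEPAIR_GROUP_HEIGHT_MM / 2.0
    y0, x0 = layout.mm_to_px(yc - half_h, -width / 2.0, shape)
    y1, x1 = layout.mm_to_px(yc + half_h, width / 2.0, shape)
    cov_y = _cov1d(shape[0], y0, y1)
    # Column coverage of the square wave by sub-pixel sampling.
    cols = np.arange(shape[1])
    offs = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    xs = cols[:, None] + offs[None, :]
    inside = (xs >= x0) & (xs <= x1)
    px_x = nominal.pixel_size_mm[0]
    phase = ((xs - x0) * px_x) % period_mm
    bar = inside & (phase < period_mm / 2.0)
    cov_x = bar.mean(axis=1)
    img += amp * np.outer(cov_y, cov_x)


def make_qa_phantom(
    nominal: QaNominal | None = None,
    n_slices: int = 5,
    shape: tuple[int, int] | None = None,
    smooth_sigma_px: float = 0.0,
) -> ImageStack:
    """Render the standard-layout QA phantom as a slice stack.

    Slice roles: slice 0 carries only the uniform disk (plus the peripheral
    ramp bar and, from slice 1 on, nothing extra there), slice 1 the
    landmark grid, slice 2 the line-pair block.  The ramp bar appears on
    every slice; the diagonal rod dot appears on every slice at its
    slice-dependent x position.  ``smooth_sigma_px`` optionally applies a
    Gaussian blur for realism (off by default so geometric metrics are
    quantization-exact).
    """
    nominal = nominal or QaNominal()
    layout = QaLayout(nominal)
    px_x, px_y = nominal.pixel_size_mm
    if shape is None:
        n = int(np.ceil((nominal.diameter_mm + 14.0) / min(px_x, px_y)))
        shape = (n, n)
    ny, nx = shape
    if nominal.diameter_mm > min(ny * px_y, nx * px_x) - 4 * max(px_x, px_y):
        raise ValueError("phantom disk does not fit in the requested field of view")

    # Rod track must stay inside the disk chord at its y position.
    tan_a = np.tan(np.deg2rad(nominal.ramp_angle_deg))
    track_half = (n_slices - 1) / 2.0 * nominal.slice_spacing_mm / tan_a + layout.DOT_SIZE_MM
    chord_half = np.sqrt(max(layout.radius_mm**2 - layout.rod_y_mm**2, 0.0))
    if track_half > 0.9 * chord_half:
        raise ValueError("rod track leaves the phantom disk; features would overlap the edge")

    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = ((yy - cy) * px_y) ** 2 + ((xx - cx) * px_x) ** 2
    disk = (r2 <= layout.radius_mm**2).astype(float)

    frames = np.empty((n_slices, ny, nx))
    for k in range(n_slices):
        img = disk.copy()
        _add_rect(
            img,
            layout,
            layout.ramp_y_mm,
            0.0,
            layout.ramp_width_mm / 2.0,
            layout.ramp_half_length_mm,
        )
        _add_rect(
            img,
            layout,
            layout.rod_y_mm,
            layout.rod_x_mm(k, n_slices),
            layout.DOT_SIZE_MM / 2.0,
            layout.DOT_SIZE_MM / 2.0,
        )
        if k == 1:
            for y_mm, x_mm in layout.landmark_positions_mm():
                _add_rect(img, layout, y_mm, x_mm, layout.DOT_SIZE_MM / 2.0, layout.DOT_SIZE_MM / 2.0)
        if k == 2:
            for gi in range(len(nominal.linepair_groups_plcm)):
                _add_linepair_group(img, layout, nominal, gi)
        if smooth_sigma_px > 0:
            img = ndimage.gaussian_filter(img, smooth_sigma_px)
        frames[k] = img

    roles = ["uniform", "landmarks", "linepairs"] + ["plain"] * max(n_slices - 3, 0)
    return ImageStack(
        frames,
        axis_labels=tuple(roles[:n_slices]),
        pixel_size_mm=nominal.pixel_size_mm,
        slice_thickness_mm=nominal.slice_thickness_mm,
        slice_spacing_mm=nominal.slice_spacing_mm,
    )


# ---------------------------------------------------------------------------
# Forward simulation


def smooth_bias_field(shape, amplitude: float = 0.1, seed: int = 0) -> np.ndarray:
    """Smooth multiplicative field around 1.0 (coil sensitivity / B1-like).

    A heavily blurred seeded random field rescaled to 1 +/- amplitude.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(raw, sigma=max(min(shape) / 6.0, 1.0))
    span = np.abs(smooth).max()
    return 1.0 + amplitude * smooth / (span if span > 0 else 1.0)


def _truth_tissue(t1_map, t2_map, pd_map) -> TissueParams:
    return TissueParams(t1_ms=t1_map.values, t2_ms=t2_map.values, pd=pd_map.values)


def simulate_acquisition(
    t1_map: ParameterMap,
    t2_map: ParameterMap,
    pd_map: ParameterMap,
    protocol: VfaProtocol | MeseProtocol | MagicProtocol,
    noise: NoiseModel | None = None,
    bias_field: np.ndarray | None = None,
    b1: B1Scale | None = None,
) -> ImageStack:
    """Forward-simulate a magnitude stack from truth maps.

    The frame structure follows the protocol type: one frame per flip angle
    (VFA), per echo (ME-SE), or delay-major/echo-minor (multispectral).
    ``bias_field`` multiplies every frame (receive-side intensity bias);
    ``b1`` scales the flip angles (transmit side).  Noise is applied last.
    """
    shapes = {m.values.shape for m in (t1_map, t2_map, pd_map)}
    if len(shapes) != 1:
        raise ValueError(f"truth map shapes differ: {sorted(shapes)}")
    params = _truth_tissue(t1_map, t2_map, pd_map)
    spatial = t1_map.values.shape

    if isinstance(protocol, VfaProtocol):
        frames = np.stack(
            [spgr_signal(params, protocol, a, b1=b1) for a in protocol.flip_angles_deg]
        )
    elif isinstance(protocol, MeseProtocol):
        frames = np.stack([mese_signal(params, protocol, te) for te in protocol.te_list_ms])
    elif isinstance(protocol, MagicProtocol):
        # Magnitude detection: the recovery term is negative at short delays
        # for long T1, but the scanner records |S|.
        frames = np.abs(
            np.stack(
                [
                    magic_signal(params, protocol, ti, te, b1=b1)
                    for ti in protocol.sat_delays_ms
                    for te in protocol.te_list_ms
                ]
            )
        )
    else:
        raise ValueError(f"no forward model for protocol type {type(protocol).__name__}")

    if bias_field is not None:
        bias = np.asarray(bias_field, dtype=float)
        if bias.shape != spatial:
            raise ValueError(f"bias field shape {bias.shape} != map shape {spatial}")
        frames = frames * bias[None]
    if noise is not None:
        frames = noise.apply(frames)

    return ImageStack(frames, pixel_size_mm=(1.02, 1.02))


def simulate_sessions(
    t1_map: ParameterMap,
    t2_map: ParameterMap,
    pd_map: ParameterMap,
    protocol,
    noise: NoiseModel | None = None,
    drift: SessionDrift | None = None,
) -> list[ImageStack]:
    """Simulate repeated scan sessions with seeded gain/parameter jitter.

    Session 1 uses the unperturbed truth maps and unit gain.  Each later
    session draws one gain factor and one T1/T2 scale factor (both
    multiplicative, shared by all frames), then runs
    :func:`simulate_acquisition` with a session-specific noise seed.
    """
    drift = drift or SessionDrift()
    rng = np.random.default_rng(drift.seed)
    stacks = []
    for k in range(drift.n_sessions):
        if k == 0:
            gain, pscale = 1.0, 1.0
        else:
            gain = 1.0 + rng.normal(0.0, drift.gain_jitter_sd_percent / 100.0)
            pscale = 1.0 + rng.normal(0.0, drift.param_jitter_sd_percent / 100.0)
        t1_k = ParameterMap(t1_map.values * pscale, t1_map.mask, t1_map.fit_residual, "truth")
        t2_k = ParameterMap(t2_map.values * pscale, t2_map.mask, t2_map.fit_residual, "truth")
        pd_k = ParameterMap(pd_map.values * gain, pd_map.mask, pd_map.fit_residual, "truth")
        noise_k = None
        if noise is not None:
            noise_k = replace(noise, seed=noise.seed + 1000 * k)
        stacks.append(simulate_acquisition(t1_k, t2_k, pd_k, protocol, noise=noise_k))
    return stacks
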