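"""QA-phantom image analysis: the geometric and intensity quality metrics.

Measures the standard scanner-QA battery from images of a cylindrical QA
phantom with known nominal geometry (a 190 mm disk containing a landmark
grid, a 45-degree ramp insert, a through-plane diagonal rod, line-pair
resolution groups and uniform regions):

* geometric distortion (mean caliper diameter over 36 directions),
* spatial linearity (relative error of inter-landmark distances),
* in-plane pixel size (physical landmark spacing / pixel spacing),
* slice thickness and slice increment (ramp-profile width and rod
  displacement, both scaled by the ramp-angle tangent),
* high-contrast detectability (highest line-pair group with modulation
  >= 0.2), SNR and noise of a uniform ROI,
* integral uniformity over a central ROI covering 75% of the phantom area
  after 3x3 mean smoothing.

The measurement functions assume the standard feature layout described by
:class:`QaLayout`, which positions every feature as a fixed fraction of the
phantom radius; the synthetic-phantom generator renders exactly this layout.
All metrics are 2D (per slice), matching how such phantoms are read in
practice for axial QA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "QaNominal",
    "QaLayout",
    "QaReport",
    "measure_diameter",
    "measure_spatial_linearity",
    "measure_pixel_size",
    "measure_slice_geometry",
    "measure_contrast_detectability",
    "measure_uniformity",
    "compute_qa_report",
    "MODULATION_THRESHOLD",
]

MODULATION_THRESHOLD = 0.2
UNIFORMITY_ROI_AREA_FRACTION = 0.75


@dataclass
class QaNominal:
    """Nominal phantom geometry; defaults follow the study phantom."""

    diameter_mm: float = 190.0
    landmark_spacing_mm: float = 20.4
    landmark_grid: tuple[int, int] = (5, 5)
    pixel_size_mm: tuple[float, float] = (1.02, 1.02)  # (x, y)
    slice_thickness_mm: float = 2.5
    slice_spacing_mm: float = 2.5
    ramp_angle_deg: float = 45.0
    linepair_groups_plcm: Sequence[float] = (5.0, 6.0, 7.0, 8.0, 9.0, 10.0)

    def __post_init__(self):
        vals = [
            self.diameter_mm,
            self.landmark_spacing_mm,
            *self.pixel_size_mm,
            self.slice_thickness_mm,
            self.slice_spacing_mm,
            self.ramp_angle_deg,
            *self.linepair_groups_plcm,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all nominal geometry values must be positive")


@dataclass
class QaReport:
    """The measured QA parameter set for one synthetic or acquired series."""

    mean_diameter_mm: float
    distortion_percent: float
    spatial_linearity_percent: float
    pixel_size_mm: tuple[float, float]
    slice_increment_mm: float
    slice_thickness_mm: float
    high_contrast_plcm: float
    snr: float
    noise_percent: float
    uniformity_percent: float


class QaLayout:
    """Physical feature positions (mm, relative to the phantom center).

    Peripheral features (ramp bar, rod track) sit at 0.916*R so they stay
    outside the 75%-area uniformity ROI (radius 0.866*R) plus smoothing
    margin; central features (landmark grid on its slice, line-pair block on
    its slice) stay within 0.65*R.  y runs along array axis -2 (rows), x
    along axis -1 (columns).
    """

    RAMP_Y_FRACTION = -0.916
    ROD_Y_FRACTION = 0.916
    RAMP_HALF_LENGTH_FRACTION = 0.158
    DOT_SIZE_MM = 3.06
    LINEPAIR_GROUP_PITCH_MM = 10.0
    LINEPAIR_GROUP_HEIGHT_MM = 6.0
    LINEPAIR_N_PERIODS = 4
    SNR_ROI_X_FRACTION = (0.35, 0.60)
    SNR_ROI_Y_FRACTION = (-0.15, 0.15)

    def __init__(self, nominal: QaNominal):
        self.nominal = nominal
        self.radius_mm = nominal.diameter_mm / 2.0
        ny, nx = nominal.landmark_grid
        span = max(nx - 1, ny - 1) * nominal.landmark_spacing_mm
        if span / 2.0 > 0.65 * self.radius_mm:
            raise ValueError("landmark grid does not fit inside the phantom")
        n_groups = len(nominal.linepair_groups_plcm)
        if (n_groups - 1) * self.LINEPAIR_GROUP_PITCH_MM / 2.0 > 0.65 * self.radius_mm:
            raise ValueError("line-pair block does not fit inside the phantom")

    # -- feature coordinates -------------------------------------------------
    def landmark_positions_mm(self) -> np.ndarray:
        """(n, 2) array of (y, x) landmark centers."""
        ny, nx = self.nominal.landmark_grid
        sp = self.nominal.landmark_spacing_mm
        ys = (np.arange(ny) - (ny - 1) / 2.0) * sp
        xs = (np.arange(nx) - (nx - 1) / 2.0) * sp
        return np.array([(y, x) for y in ys for x in xs])

    @property
    def ramp_y_mm(self) -> float:
        return self.RAMP_Y_FRACTION * self.radius_mm

    @property
    def ramp_half_length_mm(self) -> float:
        return self.RAMP_HALF_LENGTH_FRACTION * self.radius_mm

    @property
    def ramp_width_mm(self) -> float:
        """In-plane width of the slice/ramp intersection."""
        return self.nominal.slice_thickness_mm / np.tan(np.deg2rad(self.nominal.ramp_angle_deg))

    @property
    def rod_y_mm(self) -> float:
        return self.ROD_Y_FRACTION * self.radius_mm

    def rod_x_mm(self, slice_index: int, n_slices: int) -> float:
        """In-plane x of the diagonal rod in the given slice."""
        step = self.nominal.slice_spacing_mm / np.tan(np.deg2rad(self.nominal.ramp_angle_deg))
        return (slice_index - (n_slices - 1) / 2.0) * step

    def linepair_group_center_y_mm(self, group_index: int) -> float:
        n = len(self.nominal.linepair_groups_plcm)
        return (group_index - (n - 1) / 2.0) * self.LINEPAIR_GROUP_PITCH_MM

    def linepair_group_width_mm(self, group_index: int) -> float:
        f = self.nominal.linepair_groups_plcm[group_index]
        return self.LINEPAIR_N_PERIODS * 10.0 / f  # period = 10/f mm

    def snr_roi_mm(self) -> tuple[float, float, float, float]:
        """(y0, y1, x0, x1) of the uniform ROI used for SNR/noise."""
        r = self.radius_mm
        return (
            self.SNR_ROI_Y_FRACTION[0] * r,
            self.SNR_ROI_Y_FRACTION[1] * r,
            self.SNR_ROI_X_FRACTION[0] * r,
            self.SNR_ROI_X_FRACTION[1] * r,
        )

    # -- coordinate transforms ----------------------------------------------
    def mm_to_px(self, y_mm, x_mm, shape) -> tuple[np.ndarray, np.ndarray]:
        px_x, px_y = self.nominal.pixel_size_mm
        cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        return np.asarray(y_mm) / px_y + cy, np.asarray(x_mm) / px_x + cx

    def px_to_mm(self, row, col, shape) -> tuple[np.ndarray, np.ndarray]:
        px_x, px_y = self.nominal.pixel_size_mm
        cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        return (np.asarray(row) - cy) * px_y, (np.asarray(col) - cx) * px_x


def _as_2d(image) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    return img


def measure_diameter(image, nominal: QaNominal) -> tuple[float, float]:
    """Mean caliper diameter (mm) over 36 directions and distortion percent.

    The disk is segmented by Otsu thresholding; for each direction a ray is
    cast from the centroid both ways and the foreground extent recorded.
    Distortion is 100*|d - d_nominal|/d_nominal.
    """
    img = _as_2d(image)
    thr = threshold_otsu(img)
    binary = img > thr
    if not binary.any():
        raise ValueError("no foreground object found in QA image")
    layout = QaLayout(nominal)
    cy, cx = ndimage.center_of_mass(binary)
    px_x, px_y = nominal.pixel_size_mm
    step_mm = 0.1 * min(px_x, px_y)
    r_max_mm = 0.75 * max(img.shape[0] * px_y, img.shape[1] * px_x)
    radii = np.arange(0.0, r_max_mm, step_mm)

    diameters = []
    for ang in np.deg2rad(np.arange(0, 180, 5)):
        dy, dx = np.sin(ang), np.cos(ang)
        extent = 0.0
        for sign in (1.0, -1.0):
            rows = cy + sign * radii * dy / px_y
            cols = cx + sign * radii * dx / px_x
            vals = ndimage.map_coordinates(
                binary.astype(float), [rows, cols], order=0, mode="constant"
            )
            hit = np.flatnonzero(vals > 0.5)
            if hit.size:
                extent += radii[hit[-1]]
        diameters.append(extent)
    d = float(np.mean(diameters))
    return d, 100.0 * abs(d - nominal.diameter_mm) / nominal.diameter_mm


def _find_landmarks(img: np.ndarray, nominal: QaNominal) -> np.ndarray:
    """Weighted centroids (row, col) of grid dots above the disk background.

    The search is restricted to the central 0.75*R region so the peripheral
    ramp/rod features are never mistaken for landmarks.
    """
    inside = img > 0
    if not inside.any():
        raise ValueError("empty QA image")
    layout = QaLayout(nominal)
    px_x, px_y = nominal.pixel_size_mm
    cy, cx = (img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    central = ((yy - cy) * px_y) ** 2 + ((xx - cx) * px_x) ** 2 <= (0.75 * layout.radius_mm) ** 2
    bg = float(np.median(img[inside & central]))
    peak = float(img[central].max())
    if peak <= bg:
        raise ValueError("no landmarks visible above background")
    dots = (img > bg + 0.2 * (peak - bg)) & central
    lab = label(dots)
    props = regionprops(lab)
    # Weighted centroid over the region's bounding box expanded by 2 px, so
    # partially covered dot-edge pixels (below any threshold) still
    # contribute; with area-coverage rendering this recovers sub-pixel dot
    # centers exactly.  Non-dot pixels carry zero weight (img == bg there).
    cents = []
    for p in props:
        r0, c0, r1, c1 = p.bbox
        r0, c0 = max(r0 - 2, 0), max(c0 - 2, 0)
        r1, c1 = min(r1 + 2, img.shape[0]), min(c1 + 2, img.shape[1])
        w = np.clip(img[r0:r1, c0:c1] - bg, 0.0, None)
        rows, cols = np.mgrid[r0:r1, c0:c1]
        cents.append(((w * rows).sum() / w.sum(), (w * cols).sum() / w.sum()))
    cents = np.array(cents) if cents else np.empty((0, 2))
    if len(cents) < 4:
        raise ValueError(f"only {len(cents)} landmarks found; need at least 4")
    return cents


def _grid_spacings_px(cents: np.ndarray, spacing_px: tuple[float, float]):
    """Adjacent-neighbour separations along x and y from detected centroids.

    Landmarks are snapped to integer grid coordinates by rounding their
    offset from the grid minimum; spacings are taken between horizontally
    and vertically adjacent pairs.
    """
    iy = np.round((cents[:, 0] - cents[:, 0].min()) / spacing_px[1]).astype(int)
    ix = np.round((cents[:, 1] - cents[:, 1].min()) / spacing_px[0]).astype(int)
    pos = {(r, c): cents[k] for k, (r, c) in enumerate(zip(iy, ix))}
    dx, dy = [], []
    for (r, c), p in pos.items():
        q = pos.get((r, c + 1))
        if q is not None:
            dx.append(np.hypot(*(q - p)))
        q = pos.get((r + 1, c))
        if q is not None:
            dy.append(np.hypot(*(q - p)))
    if not dx or not dy:
        raise ValueError("degenerate landmark layout: no adjacent pairs on some axis")
    return np.asarray(dx), np.asarray(dy)


def measure_spatial_linearity(image, nominal: QaNominal) -> float:
    """Mean signed relative error (%) of inter-landmark distances vs nominal."""
    img = _as_2d(image)
    cents = _find_landmarks(img, nominal)
    px_x, px_y = nominal.pixel_size_mm
    sp_px = (nominal.landmark_spacing_mm / px_x, nominal.landmark_spacing_mm / px_y)
    dx_px, dy_px = _grid_spacings_px(cents, sp_px)
    d_mm = np.concatenate([dx_px * px_x, dy_px * px_y])
    return float(100.0 * np.mean((d_mm - nominal.landmark_spacing_mm) / nominal.landmark_spacing_mm))


def measure_pixel_size(image, nominal: QaNominal) -> tuple[float, float]:
    """Recovered (x, y) pixel size: physical landmark spacing / pixel spacing."""
    img = _as_2d(image)
    cents = _find_landmarks(img, nominal)
    px_x, px_y = nominal.pixel_size_mm
    sp_px = (nominal.landmark_spacing_mm / px_x, nominal.landmark_spacing_mm / px_y)
    dx_px, dy_px = _grid_spacings_px(cents, sp_px)
    return (
        float(nominal.landmark_spacing_mm / np.mean(dx_px)),
        float(nominal.landmark_spacing_mm / np.mean(dy_px)),
    )


def _profile_equivalent_width(profile: np.ndarray, step: float) -> float:
    """Width of a compact bump: integral / peak of the baseline-free profile.

    Exact for rectangular and trapezoidal profiles (the projected slice
    profile of an ideal ramp) and insensitive to where pixel boundaries fall,
    unlike literal half-maximum crossing on a coarse raster.
    """
    peak = profile.max()
    if peak <= 0:
        raise ValueError("ramp profile not localized (no signal above baseline)")
    return float(profile.sum() * step / peak)


def measure_slice_geometry(stack, nominal: QaNominal) -> tuple[float, float]:
    """(slice_thickness_mm, slice_increment_mm) from ramp and rod features.

    Thickness: equivalent width of the ramp-bar profile across y, scaled by
    tan(ramp_angle).  Increment: mean in-plane displacement of the diagonal
    rod between adjacent slices, scaled by tan(ramp_angle).
    """
    data = np.asarray(getattr(stack, "data", stack), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a slice stack (n_slices, ny, nx), got {data.shape}")
    n_slices = data.shape[0]
    layout = QaLayout(nominal)
    px_x, px_y = nominal.pixel_size_mm
    tan_a = np.tan(np.deg2rad(nominal.ramp_angle_deg))
    shape = data.shape[1:]

    # Ramp ROI: a band of rows around the bar, over the bar's x extent,
    # clipped so the band never leaves the disk (the baseline rows must sit
    # on the uniform disk signal, not on background).
    x_ext = layout.ramp_half_length_mm * 0.8
    disk_y = np.sqrt(max(layout.radius_mm**2 - x_ext**2, 0.0))
    margin = max(2.0 * layout.ramp_width_mm, 5.0 * px_y)
    margin = min(margin, 0.98 * disk_y - abs(layout.ramp_y_mm))
    if margin <= layout.ramp_width_mm:
        raise ValueError("ramp not localized: no room for a baseline band inside the disk")
    y0, _ = layout.mm_to_px(layout.ramp_y_mm - margin, 0.0, shape)
    y1, _ = layout.mm_to_px(layout.ramp_y_mm + margin, 0.0, shape)
    _, x0 = layout.mm_to_px(0.0, -layout.ramp_half_length_mm * 0.8, shape)
    _, x1 = layout.mm_to_px(0.0, layout.ramp_half_length_mm * 0.8, shape)
    ys = slice(max(int(np.floor(y0)), 0), int(np.ceil(y1)) + 1)
    xs = slice(max(int(np.floor(x0)), 0), int(np.ceil(x1)) + 1)

    widths = []
    for k in range(n_slices):
        roi = data[k, ys, xs]
        profile = roi.mean(axis=1)
        baseline = np.median(np.concatenate([profile[:3], profile[-3:]]))
        widths.append(_profile_equivalent_width(profile - baseline, px_y))
    thickness = float(np.mean(widths) * tan_a)

    # Rod ROI: band of rows around the rod track, full plausible x extent.
    track_half = (n_slices / 2.0) * nominal.slice_spacing_mm / tan_a + 3 * layout.DOT_SIZE_MM
    ry0, _ = layout.mm_to_px(layout.rod_y_mm - 1.5 * layout.DOT_SIZE_MM, 0.0, shape)
    ry1, _ = layout.mm_to_px(layout.rod_y_mm + 1.5 * layout.DOT_SIZE_MM, 0.0, shape)
    _, rx0 = layout.mm_to_px(0.0, -track_half, shape)
    _, rx1 = layout.mm_to_px(0.0, track_half, shape)
    rys = slice(max(int(np.floor(ry0)), 0), int(np.ceil(ry1)) + 1)
    rxs = slice(max(int(np.floor(rx0)), 0), int(np.ceil(rx1)) + 1)

    xcents = []
    for k in range(n_slices):
        roi = data[k, rys, rxs]
        w = roi - np.median(roi)
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            raise ValueError(f"rod not localized in slice {k}")
        cols = np.arange(roi.shape[1])
        xcents.append(float((w.sum(axis=0) * cols).sum() / w.sum()))
    dx_px = np.abs(np.diff(xcents))
    increment = float(np.mean(dx_px) * px_x * tan_a)
    return thickness, increment


def measure_contrast_detectability(
    image, nominal: QaNominal, threshold: float = MODULATION_THRESHOLD
) -> tuple[float, float, float]:
    """(high_contrast_plcm, snr, noise_percent) from the line-pair slice.

    High-contrast detectability is the highest line-pair frequency whose
    column-profile modulation (peak-trough)/(peak+trough) reaches the
    threshold; 0.0 if no group resolves.  SNR and noise% come from the
    layout's uniform ROI on the same slice.
    """
    img = _as_2d(image)
    layout = QaLayout(nominal)
    shape = img.shape
    best = 0.0
    for gi, freq in enumerate(nominal.linepair_groups_plcm):
        yc = layout.linepair_group_center_y_mm(gi)
        half_h = layout.LINEPAIR_GROUP_HEIGHT_MM / 2.0
        half_w = layout.linepair_group_width_mm(gi) / 2.0
        period_mm = 10.0 / freq
        y0, _ = layout.mm_to_px(yc - 0.6 * half_h, 0.0, shape)
        y1, _ = layout.mm_to_px(yc + 0.6 * half_h, 0.0, shape)
        # Trim half a period off each side: the partially covered boundary
        # columns of the block would otherwise mimic a deep trough.
        _, x0 = layout.mm_to_px(0.0, -half_w + period_mm / 2.0, shape)
        _, x1 = layout.mm_to_px(0.0, half_w - period_mm / 2.0, shape)
        c0, c1 = int(np.ceil(x0)), int(np.floor(x1))
        roi = img[int(np.round(y0)) : int(np.round(y1)) + 1, c0 : c1 + 1]
        if int(np.round(y0)) < 0 or roi.shape[0] == 0:
            raise ValueError(f"line-pair group {freq} pl/cm region missing from image")
        if roi.shape[1] < 2:
            continue  # group narrower than the raster can express: unresolved
        profile = roi.mean(axis=0)
        peak, trough = profile.max(), profile.min()
        if peak + trough > 0 and (peak - trough) / (peak + trough) >= threshold:
            best = max(best, freq)

    y0, y1, x0, x1 = layout.snr_roi_mm()
    r0, _ = layout.mm_to_px(y0, 0.0, shape)
    r1, _ = layout.mm_to_px(y1, 0.0, shape)
    _, c0 = layout.mm_to_px(0.0, x0, shape)
    _, c1 = layout.mm_to_px(0.0, x1, shape)
    roi = img[int(np.round(r0)) : int(np.round(r1)) + 1, int(np.round(c0)) : int(np.round(c1)) + 1]
    mean, sd = float(roi.mean()), float(roi.std(ddof=1))
    snr = mean / sd if sd > 0 else float("inf")
    noise = 100.0 * sd / mean if mean != 0 else float("nan")
    return float(best), snr, noise


def measure_uniformity(image, nominal: QaNominal) -> float:
    """Integral uniformity (%) over the central 75%-area ROI.

    The image is smoothed with a 3x3 mean filter, then
    100 * (1 - (Smax - Smin)/(Smax + Smin)) is evaluated over the circular
    ROI whose area is 75% of the nominal phantom area.
    """
    img = _as_2d(image)
    layout = QaLayout(nominal)
    roi_radius = np.sqrt(UNIFORMITY_ROI_AREA_FRACTION) * layout.radius_mm
    px_x, px_y = nominal.pixel_size_mm
    cy, cx = (img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    r2 = ((yy - cy) * px_y) ** 2 + ((xx - cx) * px_x) ** 2
    roi = r2 <= roi_radius**2
    disk = img > 0
    if np.any(roi & ~disk):
        raise ValueError("uniformity ROI extends beyond the phantom")
    smoothed = ndimage.uniform_filter(img, size=3)
    smax, smin = float(smoothed[roi].max()), float(smoothed[roi].min())
    if smax + smin == 0:
        raise ValueError("uniformity ROI contains no signal")
    return 100.0 * (1.0 - (smax - smin) / (smax + smin))


def compute_qa_report(stack, nominal: QaNominal) -> QaReport:
    """Full QA battery from a standard-layout phantom stack.

    Slice roles follow the generator's convention: slice 0 carries only the
    uniform disk (plus peripheral ramp/rod), slice 1 the landmark grid,
    slice 2 the line-pair block.
    """
    data = np.asarray(getattr(stack, "data", stack), dtype=float)
    if data.ndim != 3 or data.shape[0] < 3:
        raise ValueError("QA stack must have at least 3 slices (uniform, grid, line pairs)")
    diameter, distortion = measure_diameter(data[0], nominal)
    linearity = measure_spatial_linearity(data[1], nominal)
    px = measure_pixel_size(data[1], nominal)
    thickness, increment = measure_slice_geometry(data, nominal)
    plcm, snr, noise = measure_contrast_detectability(data[2], nominal)
    uniformity = measure_uniformity(data[0], nominal)
    return QaReport(
        mean_diameter_mm=diameter,
        distortion_percent=distortion,
        spatial_linearity_percent=linearity,
        pixel_size_mm=px,
        slice_increment_mm=increment,
        slice_thickness_mm=thickness,
        high_contrast_plcm=plcm,
        snr=snr,
        noise_percent=noise,
        uniformity_percent=uniformity,
    )
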