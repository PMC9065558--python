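"""Closed-form relaxometry forward models.

Three pulse-sequence signal equations are implemented, each returning
magnitude signal in arbitrary units as a function of the intrinsic tissue
parameters (T1, T2, proton density) and the acquisition protocol:

* :func:`spgr_signal` — spoiled gradient echo, the model behind
  variable-flip-angle (VFA / DESPOT1) T1 mapping.
* :func:`mese_signal` — multi-echo spin echo, mono-exponential T2 decay with
  saturation-limited amplitude.
* :func:`magic_signal` — multispectral saturation-recovery turbo-spin-echo
  (QRAPMASTER / MAGiC family), sampling both a saturation delay TI and an
  echo time TE so that T1, T2 and PD are jointly encoded.

All times are milliseconds, all angles are accepted in degrees at the API
boundary and converted internally.  Every function accepts scalars or numpy
arrays for the tissue parameters and broadcasts; vectorized evaluation is
bit-identical to a voxel-wise scalar loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TissueParams",
    "VfaProtocol",
    "MeseProtocol",
    "MagicProtocol",
    "B1Scale",
    "NumericDegeneracyError",
    "spgr_signal",
    "mese_signal",
    "magic_signal",
]


class NumericDegeneracyError(ValueError):
    """The model denominator vanished for the given (angles, TR, T1)."""


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class TissueParams:
    """Intrinsic voxel/region parameters.

    t1_ms, t2_ms : relaxation times in ms, strictly positive.
    pd : proton density in arbitrary units, non-negative.
    t2_star_ms : optional effective transverse relaxation time; when unset the
        gradient-echo TE decay factor is treated as unity (absorbed into the
        effective amplitude).

    T2 > T1 is physically pathological but deliberately *not* rejected, so
    that degenerate inputs can be exercised; :meth:`validate` flags it.
    """

    t1_ms: float | np.ndarray
    t2_ms: float | np.ndarray
    pd: float | np.ndarray = 1.0
    t2_star_ms: float | np.ndarray | None = None

    def __post_init__(self):
        for name in ("t1_ms", "t2_ms"):
            v = _as_array(getattr(self, name))
            if np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(_as_array(self.pd) < 0):
            raise ValueError("pd must be non-negative")
        if self.t2_star_ms is not None and np.any(_as_array(self.t2_star_ms) <= 0):
            raise ValueError("t2_star_ms must be strictly positive when set")

    def validate(self) -> list[str]:
        """Return human-readable warnings for physically suspect values."""
        issues = []
        if np.any(_as_array(self.t2_ms) > _as_array(self.t1_ms)):
            issues.append("t2_ms exceeds t1_ms (physically implausible)")
        return issues


@dataclass
class VfaProtocol:
    """Spoiled gradient-echo variable-flip-angle protocol.

    Defaults follow the study acquisition: TR=8 ms, TE=2.2 ms,
    flip angles 3/10/20/30 degrees.
    """

    tr_ms: float = 8.0
    te_ms: float = 2.2
    flip_angles_deg: Sequence[float] = (3.0, 10.0, 20.0, 30.0)
    scale_k: float = 1.0

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.te_ms < 0:
            raise ValueError("te_ms must be non-negative")
        if self.scale_k <= 0:
            raise ValueError("scale_k must be positive")
        angles = tuple(float(a) for a in self.flip_angles_deg)
        if any(not (0.0 < a < 180.0) for a in angles):
            raise ValueError("flip angles must lie in (0, 180) degrees")
        self.flip_angles_deg = angles

    @property
    def n_frames(self) -> int:
        return len(self.flip_angles_deg)


@dataclass
class MeseProtocol:
    """Multi-echo spin-echo protocol (TR=1000 ms, 8 echoes 8.1-64.5 ms)."""

    tr_ms: float = 1000.0
    te_list_ms: Sequence[float] = (8.1, 16.2, 24.3, 32.2, 40.3, 48.4, 56.4, 64.5)
    scale_k: float = 1.0

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.scale_k <= 0:
            raise ValueError("scale_k must be positive")
        tes = tuple(float(t) for t in self.te_list_ms)
        if any(t < 0 for t in tes):
            raise ValueError("echo times must be non-negative")
        if any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValueError("te_list_ms must be strictly increasing")
        self.te_list_ms = tes

    @property
    def n_frames(self) -> int:
        return len(self.te_list_ms)


@dataclass
class MagicProtocol:
    """Multi-delay multi-echo saturation-recovery protocol.

    TR, the two echo times and the 120/90 degree saturation/excitation angles
    follow the study acquisition.  The saturation delays are not part of the
    published protocol; the defaults span the TR and are fully configurable.
    """

    tr_ms: float = 4000.0
    te_list_ms: Sequence[float] = (21.8, 87.1)
    sat_delays_ms: Sequence[float] = (170.0, 620.0, 1970.0, 3720.0)
    sat_flip_deg: float = 120.0
    exc_flip_deg: float = 90.0
    scale_k: float = 1.0

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.scale_k <= 0:
            raise ValueError("scale_k must be positive")
        tes = tuple(float(t) for t in self.te_list_ms)
        if any(t < 0 for t in tes):
            raise ValueError("echo times must be non-negative")
        self.te_list_ms = tes
        tis = tuple(float(t) for t in self.sat_delays_ms)
        if len(tis) < 2:
            raise ValueError("at least 2 saturation delays are required")
        if any(not (0.0 < t < self.tr_ms) for t in tis):
            raise ValueError("saturation delays must lie in (0, TR)")
        self.sat_delays_ms = tis

    @property
    def n_frames(self) -> int:
        return len(self.sat_delays_ms) * len(self.te_list_ms)


@dataclass
class B1Scale:
    """Dimensionless multiplicative factor on nominal flip angles.

    Scalar or per-voxel map; nominal transmit field is 1.0.
    """

    b1: float | np.ndarray = 1.0

    def __post_init__(self):
        v = _as_array(self.b1)
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("b1 must be finite and positive")

    def scaled_rad(self, flip_deg: float) -> np.ndarray | float:
        return np.deg2rad(flip_deg) * _as_array(self.b1)


def spgr_signal(
    params: TissueParams,
    protocol: VfaProtocol,
    flip_deg: float,
    b1: B1Scale | None = None,
) -> np.ndarray | float:
    """Spoiled gradient-echo signal at one flip angle.

    S = K * pd * sin(B1*theta) * (1 - E1) * exp(-TE/T2*) / (1 - cos(B1*theta) * E1)

    with E1 = exp(-TR/T1).  When ``t2_star_ms`` is unset the TE decay factor
    is unity (folded into the effective amplitude, as for a single-TE
    acquisition where it cannot be separated).
    """
    if b1 is None:
        b1 = B1Scale()
    t1 = _as_array(params.t1_ms)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    theta = b1.scaled_rad(flip_deg)
    e1 = np.exp(-protocol.tr_ms / t1)
    te_factor = 1.0
    if params.t2_star_ms is not None:
        te_factor = np.exp(-protocol.te_ms / _as_array(params.t2_star_ms))
    s = (
        protocol.scale_k
        * _as_array(params.pd)
        * np.sin(theta)
        * (1.0 - e1)
        * te_factor
        / (1.0 - np.cos(theta) * e1)
    )
    return s if isinstance(s, np.ndarray) and s.ndim else float(s)


def mese_signal(
    params: TissueParams,
    protocol: MeseProtocol,
    te_ms: float,
) -> np.ndarray | float:
    """Spin-echo signal: S = K * pd * (1 - exp(-TR/T1)) * exp(-TE/T2)."""
    if te_ms < 0:
        raise ValueError("te_ms must be non-negative")
    t1 = _as_array(params.t1_ms)
    t2 = _as_array(params.t2_ms)
    if np.any(t2 <= 0):
        raise ValueError("t2_ms must be positive")
    s = (
        protocol.scale_k
        * _as_array(params.pd)
        * (1.0 - np.exp(-protocol.tr_ms / t1))
        * np.exp(-te_ms / t2)
    )
    return s if isinstance(s, np.ndarray) and s.ndim else float(s)


def magic_recovery_term(
    t1_ms: np.ndarray | float,
    protocol: MagicProtocol,
    ti_ms: float,
    b1: B1Scale | None = None,
    check: bool = True,
) -> np.ndarray | float:
    """Saturation-recovery longitudinal term of the multispectral model.

    R(TI, T1) = (1 - [1 - cos(B1*theta)] * exp(-TI/T1) - cos(B1*theta) * exp(-TR/T1))
                / (1 - cos(B1*alpha) - cos(B1*theta) * exp(-TR/T1))

    Exposed separately because the map fitter projects the TE-decay factor
    out and fits this term alone against the saturation delays.
    """
    if b1 is None:
        b1 = B1Scale()
    t1 = _as_array(t1_ms)
    cos_theta = np.cos(b1.scaled_rad(protocol.sat_flip_deg))
    cos_alpha = np.cos(b1.scaled_rad(protocol.exc_flip_deg))
    e_tr = np.exp(-protocol.tr_ms / t1)
    denom = 1.0 - cos_alpha - cos_theta * e_tr
    if check and np.any(np.abs(denom) < 1e-12):
        raise NumericDegeneracyError(
            "saturation-recovery denominator vanished for "
            f"theta={protocol.sat_flip_deg} deg, alpha={protocol.exc_flip_deg} deg, "
            f"TR={protocol.tr_ms} ms, T1={t1_ms!r} ms"
        )
    num = 1.0 - (1.0 - cos_theta) * np.exp(-ti_ms / t1) - cos_theta * e_tr
    return num / denom


def magic_signal(
    params: TissueParams,
    protocol: MagicProtocol,
    ti_ms: float,
    te_ms: float,
    b1: B1Scale | None = None,
) -> np.ndarray | float:
    """Multispectral saturation-recovery signal at one (TI, TE) sample.

    S = K * pd * exp(-TE/T2) * R(TI, T1)  with the recovery term R of
    :func:`magic_recovery_term`.
    """
    if not (0.0 < ti_ms < protocol.tr_ms):
        raise ValueError("ti_ms must lie in (0, TR)")
    if te_ms < 0:
        raise ValueError("te_ms must be non-negative")
    t2 = _as_array(params.t2_ms)
    if np.any(t2 <= 0):
        raise ValueError("t2_ms must be positive")
    r = magic_recovery_term(params.t1_ms, protocol, ti_ms, b1=b1)
    s = protocol.scale_k * _as_array(params.pd) * np.exp(-te_ms / t2) * r
    return s if isinstance(s, np.ndarray) and s.ndim else float(s)
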