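"""Synthetic weighted-image generation from fitted parameter maps.

Given T1, T2 and PD maps, a weighted image at arbitrary (TE, TR) is computed
with the spin-echo signal equation

    S = PD * (1 - exp(-TR/T1)) * exp(-TE/T2)

so the operator can dial contrast after the fact instead of re-acquiring.
The two named presets are the study's synthetic sequences: T1-weighted at
TE=25/TR=600 ms and T2-weighted at TE=65/TR=1900 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .map_fitting import ParameterMap

__all__ = ["SynthSpec", "T1W_PRESET", "T2W_PRESET", "synthesize"]


@dataclass(frozen=True)
class SynthSpec:
    """Echo/repetition time and scaling for one synthetic contrast."""

    te_ms: float
    tr_ms: float
    weighting_tag: str = "custom"
    output_scaling: str = "none"  # none | max-normalized

    def __post_init__(self):
        if self.te_ms < 0:
            raise ValueError("te_ms must be non-negative")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if self.output_scaling not in ("none", "max-normalized"):
            raise ValueError(f"unknown output_scaling {self.output_scaling!r}")


T1W_PRESET = SynthSpec(te_ms=25.0, tr_ms=600.0, weighting_tag="T1w")
T2W_PRESET = SynthSpec(te_ms=65.0, tr_ms=1900.0, weighting_tag="T2w")


def synthesize(
    t1_map: ParameterMap,
    t2_map: ParameterMap,
    pd_map: ParameterMap,
    spec: SynthSpec,
) -> np.ndarray:
    """Spin-echo weighted image from parameter maps at the spec's (TE, TR).

    Voxels outside the joint validity mask are set to 0.  With
    ``output_scaling="max-normalized"`` the image is scaled to [0, 1].
    """
    shapes = {m.values.shape for m in (t1_map, t2_map, pd_map)}
    if len(shapes) != 1:
        raise ValueError(f"map shapes differ: {sorted(shapes)}")
    mask = t1_map.mask & t2_map.mask & pd_map.mask
    t1 = np.where(mask & (t1_map.values > 0), t1_map.values, 1.0)
    t2 = np.where(mask & (t2_map.values > 0), t2_map.values, 1.0)
    img = pd_map.values * (1.0 - np.exp(-spec.tr_ms / t1)) * np.exp(-spec.te_ms / t2)
    img = np.where(mask, img, 0.0)
    if spec.output_scaling == "max-normalized":
        peak = img.max()
        if peak > 0:
            img = img / peak
    return img
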