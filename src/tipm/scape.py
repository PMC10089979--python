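"""Per-pixel volumetric directionality maps and geometric corrections.

Fast oblique volumetric imaging (5 volumes/s) trades single-soma ROIs for
per-pixel analysis: each pixel's ΔF/F is the mean of the first second
(5 volumes) of each stimulus response relative to the initial 15-s
baseline, averaged across repeats, and a per-pixel directionality index
pseudocolors the volume by preferred direction.  The oblique acquisition
geometry is corrected for display by a 90° rotation about the Y axis
followed by a fixed affine shear; per-pixel statistics default to the raw
(uncorrected) volumes, mirroring the raw-coordinates rule used for soma
topography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .protocols import StimulusProtocol
from .responses import directionality_index, first_second_frames, phase_windows

__all__ = [
    "VolumeSeries",
    "DirectionalityMap",
    "SHEAR_MATRIX",
    "pixel_dff",
    "pixel_di_map",
    "oblique_correction",
    "transform_points",
]

#: Printed oblique-correction shear, acting on column homogeneous
#: coordinates ordered (x, y, z, 1).
SHEAR_MATRIX = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 0.707, 0.0, 0.0],
        [0.0, -0.707, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


@dataclass
class VolumeSeries:
    """One trial's volumetric recording: (time, z, y, x) intensities."""

    data: np.ndarray
    volume_rate: float  # volumes/s
    voxel_pitch_um: tuple[float, float, float] = (3.0, 1.0, 1.0)  # (z, y, x)
    direction_order: tuple[str, str] = ("nose_down", "nose_up")  # per-trial, randomized

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (time, z, y, x)")
        if self.volume_rate <= 0:
            raise ValueError("volume_rate must be positive")
        if (self.data < 0).any():
            raise ValueError("intensities must be non-negative")


def pixel_dff(
    trials: list[VolumeSeries], protocol: StimulusProtocol
) -> dict[str, np.ndarray]:
    """Per-pixel mean ΔF/F for each tilt direction, averaged over repeats.

    Per trial and pixel: (mean of the first second of the direction's
    response window − baseline mean)/baseline mean, with the baseline taken
    over the protocol's initial horizontal window.  Direction order is
    randomized per trial, so each trial's own ``direction_order`` maps the
    protocol's first/second response windows onto directions.  Pixels with
    non-positive baseline are masked NaN, never propagated as infinities.
    """
    if not trials:
        raise ValueError("need at least one trial")
    base_ep = protocol.epoch("baseline")
    b_lo, b_hi = protocol.frame_window(base_ep.start_s, base_ep.end_s)
    k = first_second_frames(protocol.frame_rate)
    # protocol windows are labelled by the canonical (down, up) order;
    # per-trial order metadata reassigns them
    canonical = ("nose_down", "nose_up") if "nose_down" == protocol.epochs[1].label.removesuffix(
        "_step"
    ) else ("nose_up", "nose_down")
    windows = {phase: phase_windows(protocol, phase)[1] for phase in canonical}

    sums = {"nose_down": None, "nose_up": None}
    for tr in trials:
        vol = tr.data
        base = vol[b_lo:b_hi].mean(axis=0)
        valid = base > 0
        for slot, direction in enumerate(tr.direction_order):
            r_lo, _ = windows[canonical[slot]]
            resp = vol[r_lo : r_lo + k].mean(axis=0)
            dff = np.full(base.shape, np.nan)
            dff[valid] = (resp[valid] - base[valid]) / base[valid]
            sums[direction] = dff if sums[direction] is None else sums[direction] + dff
    n = len(trials)
    return {d: s / n for d, s in sums.items()}


@dataclass
class DirectionalityMap:
    di: np.ndarray  # per-pixel DI in [-1, 1], NaN where undefined
    dff_up: np.ndarray
    dff_down: np.ndarray
    intensity: np.ndarray  # |DI| / max |DI| within the pixel's sign class


def pixel_di_map(dff_up: np.ndarray, dff_down: np.ndarray) -> DirectionalityMap:
    """Per-pixel directionality index map with subtype-scaled intensity.

    Shares the ROI-level DI definition: magnitudes floored at 0,
    DI = (up − down)/(up + down), NaN where both are 0.  Intensity is
    |DI| normalized by the maximum |DI| within that pixel's sign class
    (nose-up pixels scale to the strongest nose-up pixel, likewise down).
    """
    up = np.maximum(np.asarray(dff_up, dtype=float), 0.0)
    down = np.maximum(np.asarray(dff_down, dtype=float), 0.0)
    if up.shape != down.shape:
        raise ValueError("maps must be aligned")
    total = up + down
    di = np.full(up.shape, np.nan)
    defined = np.isfinite(total) & (total > 0)
    di[defined] = (up[defined] - down[defined]) / total[defined]
    intensity = np.zeros_like(up)
    for mask in (defined & (di > 0), defined & (di < 0)):
        if mask.any():
            peak = np.abs(di[mask]).max()
            if peak > 0:
                intensity[mask] = np.abs(di[mask]) / peak
    return DirectionalityMap(di, np.asarray(dff_up, float), np.asarray(dff_down, float), intensity)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def transform_points(points_xyz: np.ndarray, matrix4: np.ndarray = SHEAR_MATRIX) -> np.ndarray:
    """Apply a 4×4 homogeneous transform to (n, 3) points ordered (x, y, z)."""
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    hom = np.hstack([pts, np.ones((len(pts), 1))])
    out = (matrix4 @ hom.T).T
    return out[:, :3] / out[:, 3:4]


def _y_rotation_90() -> np.ndarray:
    """+90° rotation about the Y axis in homogeneous (x, y, z, 1) form."""
    return np.array(
        [
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [-1.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def oblique_correction(
    volume: np.ndarray,
    matrix4: np.ndarray | None = None,
    *,
    rotate_y: bool = True,
    order: int = 1,
) -> np.ndarray:
    """Rotate 90° about Y, then apply the printed shear, with interpolation.

    The transform acts on voxel coordinates ordered (x, y, z); the array is
    indexed (z, y, x) (a leading time axis is mapped frame-by-frame).  The
    output bounding box is expanded to contain the transformed volume.
    """
    matrix4 = SHEAR_MATRIX if matrix4 is None else np.asarray(matrix4, dtype=float)
    if abs(np.linalg.det(matrix4)) < 1e-12:
        raise ValueError("transformation matrix is not invertible")
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 4:
        frames = [oblique_correction(f, matrix4, rotate_y=rotate_y, order=order) for f in vol]
        return np.stack(frames)
    if vol.ndim != 3:
        raise ValueError("volume must be 3-D (z, y, x) or 4-D (t, z, y, x)")

    M = matrix4 @ _y_rotation_90() if rotate_y else matrix4
    A = M[:3, :3]
    b = M[:3, 3]
    nz, ny, nx = vol.shape
    corners = np.array(
        [(x, y, z) for x in (0, nx - 1) for y in (0, ny - 1) for z in (0, nz - 1)], dtype=float
    )
    tc = transform_points(corners, M)
    lo = np.floor(tc.min(axis=0))
    hi = np.ceil(tc.max(axis=0))
    out_shape_xyz = (hi - lo + 1).astype(int)

    # ndimage maps output index -> input index; indices are (z, y, x)
    P = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])  # xyz <-> zyx swap
    A_inv = np.linalg.inv(A)
    M_idx = P @ A_inv @ P
    offset_idx = P @ (A_inv @ (lo - b))
    out_shape = tuple(int(s) for s in out_shape_xyz[::-1])
    return ndimage.affine_transform(
        vol, M_idx, offset=offset_idx, output_shape=out_shape, order=order, mode="constant", cval=0.0
    )
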