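"""Ratio normalization of MPRAGE by a co-registered reference GRE.

Dividing the MPRAGE magnitude by a steady-state GRE magnitude acquired with
the same receive chain cancels receive sensitivity, proton density, and T2*
weighting voxelwise, leaving a purely T1-and-transmit-field weighted image.
The same pair can also be combined into the bounded ratio-product image
S_MP*S_GRE/(S_MP^2+S_GRE^2) used for lookup-table T1 estimation.

Co-registration is assumed done externally; these functions refuse inputs
on different grids rather than resampling silently.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage

from .lut import combine
from .volume import Mask, Volume

__all__ = [
    "rescale_stored",
    "upsample_reference",
    "normalize_mprage",
    "combined_image",
]

# Default division floor: fraction of the masked reference median.
DEFAULT_FLOOR_FRACTION = 0.05


def rescale_stored(vol: Volume, slope: float | None = None,
                   intercept: float | None = None,
                   divisor: float = 1000.0) -> Volume:
    """Convert stored integer values to the floating-point 0-1000 display
    convention: true = (slope*stored + intercept) / divisor.

    When reading through :func:`mpragekit.volume.read_volume` the header
    slope/intercept are already applied; pass ``slope=1, intercept=0`` then
    (the default) and only the divisor is applied.
    """
    if slope is None or intercept is None:
        raise ValueError(
            "scaling metadata missing: pass explicit slope and intercept "
            "(slope=1, intercept=0 if the loader already applied them)")
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    data = (slope * vol.data.astype(float) + intercept) / divisor
    return vol.like(data, units="a.u./%g" % divisor)


def _check_same_grid(a: Volume, b) -> None:
    shape_b = b.data.shape
    if a.data.shape != shape_b:
        raise ValueError(f"grid mismatch: {a.data.shape} vs {shape_b}")


def upsample_reference(gre: Volume, target: Volume,
                       method: str = "fourier_zerofill") -> Volume:
    """Bring a coarse reference GRE onto the target grid.

    ``fourier_zerofill`` pads the centered discrete spectrum symmetrically,
    matching a scanner's zero-filled reconstruction; ``trilinear`` is the
    fallback for non-integer grid ratios.  The field of view is assumed
    shared (co-registered inputs); a voxel-size/grid combination implying a
    different FOV is rejected.
    """
    if gre.shape == target.shape:
        return gre.like(gre.data.copy())
    if any(g > t for g, t in zip(gre.shape, target.shape)):
        raise ValueError("reference grid is finer than the target grid")
    fov_gre = [s * v for s, v in zip(gre.shape, gre.voxel_size)]
    fov_tgt = [s * v for s, v in zip(target.shape, target.voxel_size)]
    if not np.allclose(fov_gre, fov_tgt, rtol=0.05):
        raise ValueError(
            f"inconsistent field of view: {fov_gre} vs {fov_tgt}")

    if method == "fourier_zerofill":
        spec = np.fft.fftshift(np.fft.fftn(gre.data))
        padded = np.zeros(target.shape, dtype=complex)
        slices_src, slices_dst = [], []
        for n_old, n_new in zip(gre.shape, target.shape):
            start = (n_new - n_old) // 2
            slices_dst.append(slice(start, start + n_old))
            slices_src.append(slice(0, n_old))
        padded[tuple(slices_dst)] = spec[tuple(slices_src)]
        scale = np.prod(target.shape) / np.prod(gre.shape)
        up = np.fft.ifftn(np.fft.ifftshift(padded)).real * scale
    elif method == "trilinear":
        zoom = [t / g for g, t in zip(gre.shape, target.shape)]
        up = scipy.ndimage.zoom(gre.data.astype(float), zoom, order=1,
                                mode="nearest", grid_mode=True)
    else:
        raise ValueError(f"unknown upsampling method {method!r}")
    return Volume(data=up, voxel_size=target.voxel_size,
                  affine=target.affine.copy(), units=gre.units)


def normalize_mprage(mp: Volume, gre: Volume, mask: Mask | None = None,
                     floor: float | None = None):
    """Voxelwise ratio mp/gre inside the mask, with a division floor.

    Voxels where the reference falls below ``floor`` (default 5% of the
    masked reference median) are set to 0 and flagged.  Returns
    ``(ratio, flags)`` where ``flags`` is a uint8 Volume (1 = floored or
    outside mask).
    """
    _check_same_grid(mp, gre)
    if mask is None:
        mask = Mask.full(mp.shape)
    _check_same_grid(mp, mask)

    gre_data = gre.data.astype(float)
    if floor is None:
        inside = mask.data & np.isfinite(gre_data)
        med = np.median(np.abs(gre_data[inside])) if inside.any() else 0.0
        floor = DEFAULT_FLOOR_FRACTION * med
    if floor <= 0:
        raise ValueError("division floor must be positive")

    valid = mask.data & (gre_data > floor)
    ratio = np.zeros(mp.shape, dtype=float)
    np.divide(mp.data, gre_data, out=ratio, where=valid)
    flags = (~valid).astype(np.uint8)
    return mp.like(ratio, units=""), mp.like(flags, units="flags")


def combined_image(mp: Volume, gre: Volume, mask: Mask | None = None) -> Volume:
    """Voxelwise ratio-product combination of the two magnitudes inside the
    mask; values lie in [0, 0.5] and 0 outside the mask."""
    _check_same_grid(mp, gre)
    if mask is None:
        mask = Mask.full(mp.shape)
    _check_same_grid(mp, mask)
    comb = combine(np.abs(mp.data), np.abs(gre.data))
    comb[~mask.data] = 0.0
    return mp.like(comb, units="")
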