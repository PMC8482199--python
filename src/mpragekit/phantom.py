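"""Synthetic brain phantom: MPRAGE/GRE pairs with known ground truth.

The phantom is three nested ellipsoids emulating a CSF rim, a GM shell and
a WM core, each with its own T1, proton density, and R2*.  Smooth
multiplicative transmit (fT) and receive (fR) fields, an optional depressed-
fT lobe mimicking failed adiabatic inversion, and Rician magnitude noise
make every pipeline stage testable without scanner data.  The forward model
is exactly the signal equations of :mod:`mpragekit.signal_models`:

    S_MP  = fR * PD * Mz_MP(fT*a_MP, T1, TI) * sin(fT*a_MP) * exp(-TE*R2*)
    S_GRE = fR * PD * M0*(fT*a_GRE, T1)      * sin(fT*a_GRE) * exp(-TE*R2*)

so the ratio S_MP/S_GRE depends only on T1 and fT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.special

from .signal_models import (
    SequenceParams,
    TissueParams,
    driven_equilibrium,
    mprage_mz_at_center,
)
from .volume import Mask, Volume

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "PhantomTruth",
    "make_bias_field",
    "render_phantom",
    "make_sessions",
    "rician_mean",
]

# Default tissue parameters: WM / GM / CSF T1 of 1.2 / 1.8 / 4.0 s; the PD
# values are plausible round numbers, not measured quantities.
DEFAULT_TISSUES = (
    ("csf", TissueParams(t1=4.0, pd=1.0, r2_star=2.0)),
    ("gm", TissueParams(t1=1.8, pd=0.8, r2_star=15.0)),
    ("wm", TissueParams(t1=1.2, pd=0.7, r2_star=20.0)),
)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in normalized grid coordinates [-1, 1]^3."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    semi_axes: tuple[float, float, float] = (0.8, 0.8, 0.8)

    def contains(self, coords) -> np.ndarray:
        acc = 0.0
        for x, c, a in zip(coords, self.center, self.semi_axes):
            acc = acc + ((x - c) / a) ** 2
        return acc <= 1.0


@dataclass
class PhantomSpec:
    """Geometry, tissue parameters, fields and noise of one phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tissues: tuple = DEFAULT_TISSUES
    # outermost to innermost shells; painted in order, so later entries
    # overwrite earlier ones
    geometry: tuple = (
        Ellipsoid(semi_axes=(0.9, 0.9, 0.9)),
        Ellipsoid(semi_axes=(0.75, 0.75, 0.75)),
        Ellipsoid(semi_axes=(0.5, 0.5, 0.5)),
    )
    ft_family: str = "polynomial"
    ft_amplitude: float = 0.3
    ft_quantum: float = 0.01  # snap fT to the LUT's fT resolution
    fr_family: str = "gaussian"
    fr_amplitude: float = 0.4
    adiabatic_lobe: Ellipsoid | None = None  # depressed-fT region, fT ~ 0.3
    noise_sigma: float = 0.0  # Rician scale relative to mean WM MPRAGE signal
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.tissues) != len(self.geometry):
            raise ValueError("one geometry primitive per tissue required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class PhantomTruth:
    """Ground-truth maps aligned to the phantom grid."""

    label_map: Volume   # 0 = background, 1.. = tissue order in spec
    t1_map: Volume      # seconds
    pd_map: Volume
    ft_map: Volume
    fr_map: Volume
    labels: dict = field(default_factory=dict)  # name -> integer label

    def mask_of(self, name: str) -> Mask:
        return Mask(self.label_map.data == self.labels[name])


def _norm_coords(shape):
    return np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij")


def make_bias_field(shape, family: str = "polynomial",
                    amplitude: float = 0.3, seed: int = 0) -> np.ndarray:
    """Smooth positive multiplicative field with mean 1.

    ``polynomial`` draws a random second-order polynomial over the grid;
    ``gaussian`` a broad off-center Gaussian bump.  ``amplitude`` is the
    maximum absolute deviation from 1 and must stay below 1 so the field
    never crosses zero.  Deterministic for a fixed seed.
    """
    if amplitude >= 1.0:
        raise ValueError("amplitude must be < 1 (field would cross zero)")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0.0:
        return np.ones(shape)
    rng = np.random.default_rng(seed)
    coords = _norm_coords(shape)
    if family == "polynomial":
        f = np.zeros(shape)
        for x in coords:
            c1, c2 = rng.uniform(-1, 1, size=2)
            f = f + c1 * x + c2 * x * x
        for i in range(3):
            for j in range(i + 1, 3):
                f = f + rng.uniform(-1, 1) * coords[i] * coords[j]
    elif family == "gaussian":
        center = rng.uniform(-0.5, 0.5, size=3)
        width = rng.uniform(0.6, 1.2)
        r2 = sum(((x - c) / width) ** 2 for x, c in zip(coords, center))
        f = np.exp(-0.5 * r2)
    else:
        raise ValueError(f"unknown bias-field family {family!r}")
    f = f - f.mean()
    peak = np.max(np.abs(f))
    if peak > 0:
        f = f * (amplitude / peak)
    return 1.0 + f


def _paint_maps(spec: PhantomSpec):
    coords = _norm_coords(spec.shape)
    label = np.zeros(spec.shape, dtype=np.int16)
    t1 = np.full(spec.shape, 1.0)   # placeholder T1 where PD = 0
    pd = np.zeros(spec.shape)
    r2s = np.zeros(spec.shape)
    labels = {}
    for k, ((name, tp), geom) in enumerate(zip(spec.tissues, spec.geometry),
                                           start=1):
        inside = geom.contains(coords)
        label[inside] = k
        t1[inside] = tp.t1
        pd[inside] = tp.pd
        r2s[inside] = tp.r2_star
        labels[name] = k
    return coords, label, t1, pd, r2s, labels


def _block_average_inplane(data: np.ndarray, factor: int) -> np.ndarray:
    """Emulate a coarser acquisition voxel: block-average the first two
    axes by ``factor`` then linearly resample back to the original grid."""
    small = scipy.ndimage.zoom(data, (1.0 / factor, 1.0 / factor, 1.0),
                               order=1, mode="nearest", grid_mode=True)
    return scipy.ndimage.zoom(small, (data.shape[0] / small.shape[0],
                                      data.shape[1] / small.shape[1], 1.0),
                              order=1, mode="nearest", grid_mode=True)


def render_phantom(spec: PhantomSpec, seq: SequenceParams,
                   gre_voxel_factor: int = 1):
    """Render a noise-controlled MPRAGE/GRE pair with ground truth.

    Returns ``(mp, gre, truth)``.  ``gre_voxel_factor`` > 1 emulates a
    reference acquired at enlarged in-plane voxels (block-averaged, then
    resampled back).
    """
    coords, label, t1, pd, r2s, labels = _paint_maps(spec)
    rng = np.random.default_rng(spec.seed)

    ft = make_bias_field(spec.shape, spec.ft_family, spec.ft_amplitude,
                         seed=spec.seed + 1)
    if spec.adiabatic_lobe is not None:
        ft = np.where(spec.adiabatic_lobe.contains(coords), 0.3, ft)
    if spec.ft_quantum > 0:
        ft = np.round(ft / spec.ft_quantum) * spec.ft_quantum
    fr = make_bias_field(spec.shape, spec.fr_family, spec.fr_amplitude,
                         seed=spec.seed + 2)

    a_mp = np.deg2rad(ft * seq.alpha_mp)
    a_gre = np.deg2rad(ft * seq.alpha_gre)
    t2s_decay = np.exp(-seq.te * r2s)
    mz_mp = mprage_mz_at_center(seq, t1, ft)
    mz_gre = driven_equilibrium(1.0 / t1, ft * seq.alpha_gre, seq.tr)
    mp_clean = fr * pd * mz_mp * np.sin(a_mp) * t2s_decay
    gre_clean = fr * pd * mz_gre * np.sin(a_gre) * t2s_decay

    if gre_voxel_factor > 1:
        gre_clean = _block_average_inplane(gre_clean, gre_voxel_factor)

    wm_label = labels.get("wm")
    if spec.noise_sigma > 0 and wm_label is not None:
        sigma = spec.noise_sigma * np.abs(mp_clean[label == wm_label]).mean()
        mp_data = _rician(np.abs(mp_clean), sigma, rng)
        gre_data = _rician(np.abs(gre_clean), sigma, rng)
    else:
        mp_data = np.abs(mp_clean)
        gre_data = np.abs(gre_clean)

    vx = spec.voxel_size
    mp = Volume(mp_data, voxel_size=vx, units="a.u.")
    gre = Volume(gre_data, voxel_size=vx, units="a.u.")
    truth = PhantomTruth(
        label_map=Volume(label.astype(float), voxel_size=vx),
        t1_map=Volume(t1, voxel_size=vx, units="s"),
        pd_map=Volume(pd, voxel_size=vx),
        ft_map=Volume(ft, voxel_size=vx),
        fr_map=Volume(fr, voxel_size=vx),
        labels=labels,
    )
    return mp, gre, truth


def _rician(magnitude: np.ndarray, sigma: float,
            rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex Gaussian around the noise-free signal."""
    re = magnitude + rng.normal(0.0, sigma, magnitude.shape)
    im = rng.normal(0.0, sigma, magnitude.shape)
    return np.hypot(re, im)


def rician_mean(nu, sigma):
    """Expected value of a Rician variable with location ``nu`` and scale
    ``sigma`` (closed form via exponentially scaled Bessel functions)."""
    nu = np.asarray(nu, dtype=float)
    x = nu * nu / (4.0 * sigma * sigma)
    # L_{1/2}(-2x) = e^{-x} [(1+2x) I0(x) + 2x I1(x)]; ive = e^{-x} Iv
    l_half = ((1.0 + 2.0 * x) * scipy.special.ive(0, x)
              + 2.0 * x * scipy.special.ive(1, x))
    return sigma * np.sqrt(np.pi / 2.0) * l_half


def make_sessions(spec: PhantomSpec, seq: SequenceParams, n_sessions: int,
                  field_jitter: float = 0.5, seed: int | None = None,
                  gre_voxel_factor: int = 1):
    """Repeated sessions of the same anatomy with session-varying fields.

    Each session blends the base transmit/receive fields with independent
    realizations: field_s = base * (1 + jitter*(indep - 1)), so
    ``field_jitter = 0`` reproduces the base session exactly.  Per-session
    noise and field seeds derive deterministically from the master seed.

    Returns ``(pairs, truth)`` with ``pairs`` a list of (mp, gre) Volumes;
    ``truth`` holds the base-session fields.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    session_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(n_sessions)]

    coords, label, t1, pd, r2s, labels = _paint_maps(spec)
    base_ft = make_bias_field(spec.shape, spec.ft_family, spec.ft_amplitude,
                              seed=spec.seed + 1)
    base_fr = make_bias_field(spec.shape, spec.fr_family, spec.fr_amplitude,
                              seed=spec.seed + 2)

    pairs = []
    truth = None
    for s_idx, s_seed in enumerate(session_seeds):
        rng = np.random.default_rng(s_seed)
        if field_jitter > 0:
            ft_i = make_bias_field(spec.shape, spec.ft_family,
                                   spec.ft_amplitude, seed=s_seed + 1)
            fr_i = make_bias_field(spec.shape, spec.fr_family,
                                   spec.fr_amplitude, seed=s_seed + 2)
            ft = base_ft * (1.0 + field_jitter * (ft_i - 1.0))
            fr = base_fr * (1.0 + field_jitter * (fr_i - 1.0))
        else:
            ft, fr = base_ft, base_fr
        if spec.ft_quantum > 0:
            ft = np.round(ft / spec.ft_quantum) * spec.ft_quantum

        a_mp = np.deg2rad(ft * seq.alpha_mp)
        a_gre = np.deg2rad(ft * seq.alpha_gre)
        t2s_decay = np.exp(-seq.te * r2s)
        mz_mp = mprage_mz_at_center(seq, t1, ft)
        mz_gre = driven_equilibrium(1.0 / t1, ft * seq.alpha_gre, seq.tr)
        mp_clean = np.abs(fr * pd * mz_mp * np.sin(a_mp) * t2s_decay)
        gre_clean = np.abs(fr * pd * mz_gre * np.sin(a_gre) * t2s_decay)
        if gre_voxel_factor > 1:
            gre_clean = _block_average_inplane(gre_clean, gre_voxel_factor)

        wm = labels.get("wm")
        if spec.noise_sigma > 0 and wm is not None:
            sigma = spec.noise_sigma * mp_clean[label == wm].mean()
            mp_data = _rician(mp_clean, sigma, rng)
            gre_data = _rician(gre_clean, sigma, rng)
        else:
            mp_data, gre_data = mp_clean, gre_clean

        vx = spec.voxel_size
        pairs.append((Volume(mp_data, voxel_size=vx, units="a.u."),
                      Volume(gre_data, voxel_size=vx, units="a.u.")))
        if s_idx == 0:
            truth = PhantomTruth(
                label_map=Volume(label.astype(float), voxel_size=vx),
                t1_map=Volume(t1, voxel_size=vx, units="s"),
                pd_map=Volume(pd, voxel_size=vx),
                ft_map=Volume(ft, voxel_size=vx),
                fr_map=Volume(fr, voxel_size=vx),
                labels=labels,
            )
    return pairs, truth
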