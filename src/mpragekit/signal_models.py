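"""Closed-form and simulated signal models for MPRAGE and steady-state GRE.

The MPRAGE sequence applies an adiabatic inversion pulse every ``t_cycle``
seconds, followed (after a delay) by a train of ``tf`` low-flip-angle readout
pulses spaced ``tr`` apart, with the central k-space line acquired at the
inversion time ``ti``.  During the readout train the longitudinal
magnetization relaxes toward a *driven equilibrium* M0* with an apparent rate

    R1* = R1 - ln(cos(alpha_loc)) / TR,

where ``alpha_loc = fT * alpha`` is the local flip angle under a relative
transmit-field factor ``fT``.  Outside the train it relaxes normally toward
the thermal equilibrium (normalized to 1).  The reference GRE runs without
inversion and sits in the steady state M0*(fT*alpha_gre, T1) throughout.

All angles are degrees at the public interfaces and radians internally; all
times are seconds.  Magnetization is expressed per unit proton density
(M0 = 1), so every returned signal is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SequenceParams",
    "TissueParams",
    "MzTrajectory",
    "apparent_rate",
    "driven_equilibrium",
    "gre_steady_state_signal",
    "ernst_angle",
    "simulate_mprage_cycle",
    "mprage_signal",
    "scale_reference_signal",
    "elliptical_speedup",
]

# Maximum fixed-point iterations / tolerance for the outer-loop steady state.
_SS_MAX_CYCLES = 50
_SS_TOL = 1e-9


@dataclass(frozen=True)
class SequenceParams:
    """Pulse-sequence constants of a sequential MPRAGE + reference GRE protocol.

    Parameters
    ----------
    alpha_mp : float
        Excitation flip angle of the MPRAGE readout, degrees.
    alpha_gre : float
        Excitation flip angle of the reference GRE, degrees.
    tr : float
        Repetition time between readout pulses, seconds.
    ti : float
        Inversion time: delay from the inversion pulse to the central
        k-space line, seconds.
    tf : int
        Turbo factor, number of readout pulses per inversion cycle.
    t_cycle : float
        Time between successive inversion pulses, seconds.
    f_inv : float
        Inversion efficiency in [0, 1]; 1 means perfect inversion.
    te : float
        Echo time, seconds.  Carried for the phantom forward model only;
        it cancels in the normalized ratio.
    """

    alpha_mp: float = 8.0
    alpha_gre: float = 3.0
    tr: float = 0.008
    ti: float = 1.2
    tf: int = 288
    t_cycle: float = 3.5
    f_inv: float = 0.96
    te: float = 0.00197

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not (0 < self.ti < self.t_cycle):
            raise ValueError("ti must lie in (0, t_cycle)")
        if self.tf < 1:
            raise ValueError("tf must be at least 1")
        if self.tf * self.tr > self.t_cycle + 1e-12:
            raise ValueError("readout train (tf*tr) does not fit in t_cycle")
        if not (0.0 <= self.f_inv <= 1.0):
            raise ValueError("f_inv must lie in [0, 1]")
        for name in ("alpha_mp", "alpha_gre"):
            a = getattr(self, name)
            if not (0.0 < a < 90.0):
                raise ValueError(f"{name} must lie in (0, 90) degrees")

    @property
    def train_start(self) -> float:
        """Start of the readout train: linear phase encoding places the
        centre line (pulse index tf//2, 0-based) at ``ti``."""
        return self.ti - (self.tf // 2) * self.tr

    @property
    def train_duration(self) -> float:
        return self.tf * self.tr

    def validate_train(self) -> None:
        """Check the readout train fits inside the cycle."""
        if self.train_start < 0:
            raise ValueError(
                f"readout train starts before the inversion "
                f"(train_start={self.train_start:.4f} s < 0)"
            )
        if self.train_start + self.train_duration > self.t_cycle + 1e-12:
            raise ValueError("readout train extends past t_cycle")


@dataclass(frozen=True)
class TissueParams:
    """Relaxation and density parameters of one tissue class."""

    t1: float  # longitudinal relaxation time, s
    pd: float = 1.0  # proton density, arbitrary units
    r2_star: float = 0.0  # effective transverse rate 1/T2*, 1/s

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if self.pd < 0:
            raise ValueError("pd must be non-negative")
        if self.r2_star < 0:
            raise ValueError("r2_star must be non-negative")

    @property
    def r1(self) -> float:
        return 1.0 / self.t1


@dataclass
class MzTrajectory:
    """Longitudinal magnetization (per unit PD) sampled over one cycle."""

    times: np.ndarray
    mz: np.ndarray
    mz_at_center: float
    seq: SequenceParams = field(repr=False, default=None)


def _check_local_angle(alpha_deg) -> np.ndarray:
    a = np.asarray(alpha_deg, dtype=float)
    if np.any(a < 0) or np.any(a >= 90.0):
        raise ValueError("local flip angle must lie in [0, 90) degrees")
    return a


def apparent_rate(r1, alpha_loc, tr):
    """Apparent longitudinal rate R1* = R1 - ln(cos(alpha_loc))/TR under
    rapid pulsing at local flip angle ``alpha_loc`` (degrees)."""
    a = np.deg2rad(_check_local_angle(alpha_loc))
    r1 = np.asarray(r1, dtype=float)
    if np.any(r1 <= 0) or tr <= 0:
        raise ValueError("r1 and tr must be positive")
    return r1 - np.log(np.cos(a)) / tr


def driven_equilibrium(r1, alpha_loc, tr):
    """Driven-equilibrium magnetization M0*/M0 = (1-e^{-R1 TR})/(1-e^{-R1* TR}).

    Equals 1 at zero flip angle and decreases toward 0 as the readout
    saturates the longitudinal magnetization.
    """
    r1 = np.asarray(r1, dtype=float)
    r1s = apparent_rate(r1, alpha_loc, tr)
    return -np.expm1(-r1 * tr) / -np.expm1(-r1s * tr)


def gre_steady_state_signal(t1, alpha_gre, f_t, tr):
    """Steady-state spoiled-GRE signal M0*(fT*alpha, T1) * sin(fT*alpha),
    per unit PD and without T2* decay."""
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    a_loc = np.asarray(f_t, dtype=float) * alpha_gre
    return driven_equilibrium(1.0 / t1, a_loc, tr) * np.sin(np.deg2rad(a_loc))


def ernst_angle(tr, t1):
    """Flip angle (degrees) maximizing the steady-state GRE signal:
    arccos(exp(-TR/T1))."""
    if np.any(np.asarray(tr) <= 0) or np.any(np.asarray(t1) <= 0):
        raise ValueError("tr and t1 must be positive")
    return np.rad2deg(np.arccos(np.exp(-np.asarray(tr, float) / np.asarray(t1, float))))


def elliptical_speedup() -> float:
    """Acquisition-time reduction factor of elliptical k-space phase
    encoding relative to full rectangular sampling: area ratio 4/pi."""
    return 4.0 / math.pi


def _cycle_coefficients(seq: SequenceParams, t1, f_t):
    """Per-cycle propagation pieces for the piecewise-exponential Mz model.

    Returns (r1, r1s, m0s, e_pre, e_train, e_post, e_center) where the e_*
    are the exponential decay factors over the pre-train gap, the full
    train, the post-train gap, and the train portion up to the centre line.
    """
    seq.validate_train()
    t1 = np.asarray(t1, dtype=float)
    f_t = np.asarray(f_t, dtype=float)
    r1 = 1.0 / t1
    a_loc = f_t * seq.alpha_mp
    r1s = apparent_rate(r1, a_loc, seq.tr)
    m0s = driven_equilibrium(r1, a_loc, seq.tr)
    t_start = seq.train_start
    t_train = seq.train_duration
    t_post = seq.t_cycle - t_start - t_train
    e_pre = np.exp(-r1 * t_start)
    e_train = np.exp(-r1s * t_train)
    e_post = np.exp(-r1 * t_post)
    e_center = np.exp(-r1s * ((seq.tf // 2) * seq.tr))
    return r1, r1s, m0s, e_pre, e_train, e_post, e_center


def _steady_state_mz_end(seq: SequenceParams, t1, f_t):
    """Mz just before the inversion pulse in the outer-loop steady state,
    found by fixed-point iteration of the one-cycle map from Mz = +1."""
    r1, r1s, m0s, e_pre, e_train, e_post, _ = _cycle_coefficients(seq, t1, f_t)
    shape = np.broadcast(r1, m0s).shape
    mz_end = np.ones(shape) if shape else 1.0
    for _ in range(_SS_MAX_CYCLES):
        mz0 = -seq.f_inv * mz_end
        m_ts = 1.0 + (mz0 - 1.0) * e_pre
        m_te = m0s + (m_ts - m0s) * e_train
        new = 1.0 + (m_te - 1.0) * e_post
        if np.max(np.abs(new - mz_end)) < _SS_TOL:
            mz_end = new
            break
        mz_end = new
    return mz_end


def mprage_mz_at_center(seq: SequenceParams, t1, f_t):
    """Longitudinal magnetization (per unit PD) at the central k-space line
    of the cycle-periodic MPRAGE acquisition.  Vectorized over t1 and f_t."""
    _, _, m0s, e_pre, _, _, e_center = _cycle_coefficients(seq, t1, f_t)
    mz_end = _steady_state_mz_end(seq, t1, f_t)
    mz0 = -seq.f_inv * mz_end
    m_ts = 1.0 + (mz0 - 1.0) * e_pre
    return m0s + (m_ts - m0s) * e_center


def mprage_signal(seq: SequenceParams, t1, f_t):
    """Signed MPRAGE model signal: Mz at the centre line times sin(fT*alpha_mp).

    Negative values mean the magnetization has not yet crossed zero at TI;
    magnitude handling is the caller's concern.
    """
    a_loc = np.asarray(f_t, dtype=float) * seq.alpha_mp
    return mprage_mz_at_center(seq, t1, f_t) * np.sin(np.deg2rad(a_loc))


def simulate_mprage_cycle(seq: SequenceParams, t1: float, f_t: float = 1.0,
                          dt: float = 0.001) -> MzTrajectory:
    """Simulate the cycle-periodic Mz trajectory over one inversion cycle.

    Instantaneous inversion at t = 0 (Mz -> -f_inv * Mz), free relaxation
    toward +1 at rate R1 outside the readout train, relaxation toward the
    driven equilibrium M0* at rate R1* inside it.  The outer-loop steady
    state is reached by fixed-point iteration before sampling.
    """
    if dt > seq.tr:
        raise ValueError("dt must not exceed tr")
    r1, r1s, m0s, e_pre, e_train, _, _ = _cycle_coefficients(seq, t1, f_t)
    mz_end = _steady_state_mz_end(seq, t1, f_t)
    mz0 = -seq.f_inv * mz_end

    t_start = seq.train_start
    t_end = t_start + seq.train_duration
    times = np.arange(0.0, seq.t_cycle + dt / 2, dt)
    times = np.unique(np.concatenate([times, [t_start, seq.ti, t_end, seq.t_cycle]]))

    m_ts = 1.0 + (mz0 - 1.0) * np.exp(-r1 * t_start)
    m_te = m0s + (m_ts - m0s) * e_train

    mz = np.empty_like(times)
    pre = times <= t_start
    mz[pre] = 1.0 + (mz0 - 1.0) * np.exp(-r1 * times[pre])
    train = (times > t_start) & (times <= t_end)
    mz[train] = m0s + (m_ts - m0s) * np.exp(-r1s * (times[train] - t_start))
    post = times > t_end
    mz[post] = 1.0 + (m_te - 1.0) * np.exp(-r1 * (times[post] - t_end))

    center = float(m0s + (m_ts - m0s) * np.exp(-r1s * (seq.ti - t_start)))
    return MzTrajectory(times=times, mz=mz, mz_at_center=center, seq=seq)


def scale_reference_signal(s, alpha_i, alpha_ref, r1=0.83, tr=0.008):
    """Rescale a small-flip-angle GRE signal acquired at ``alpha_i`` to be
    comparable with one acquired at ``alpha_ref``.

    Uses the small-angle approximation of the Ernst steady state,
    S(alpha) ~ alpha / (alpha^2/2 + R1*TR), with a single representative R1
    (default 0.83 1/s, white-matter T1 of about 1.2 s).  The input is
    divided by the ratio S(alpha_i)/S(alpha_ref).
    """
    ai = math.radians(alpha_i)
    ar = math.radians(alpha_ref)
    if ai <= 0 or ar <= 0:
        raise ZeroDivisionError("flip angles must be positive")
    ratio = (ai * (0.5 * ar * ar + r1 * tr)) / (ar * (0.5 * ai * ai + r1 * tr))
    return np.asarray(s, dtype=float) / ratio
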