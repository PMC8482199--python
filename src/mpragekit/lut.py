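"""Lookup-table construction, identifiability analysis, and T1 inversion.

The combined signal

    S = S_MP * S_GRE / (S_MP^2 + S_GRE^2)

is invariant to any common positive scaling of its two inputs, which is the
algebraic reason receive sensitivity and proton density cancel.  It is
bounded by 0.5 (attained at equal inputs).  A 2D table of S over a (T1, fT)
grid is inverted pixelwise: for a measured S and a transmit-field factor fT,
the T1 grid point minimizing |S - S_LUT| on the uniquely invertible branch
of the nearest fT column is returned.

Because sequentially measured magnitudes carry no relative phase, the model
MPRAGE signal is truncated to its non-negative part before combination; the
resulting column folds both at short T1 (combined maximum of 0.5) and,
where the signed MPRAGE signal crosses zero within the grid, at long T1.
``identifiability_limits`` reports the bounds of the invertible branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .signal_models import (
    SequenceParams,
    gre_steady_state_signal,
    mprage_signal,
)

__all__ = [
    "LookupTable",
    "combine",
    "build_lut",
    "identifiability_limits",
    "invert_t1",
    "save_lut",
    "load_lut",
    "FLAG_CLAMPED_SIGNAL",
    "FLAG_FT_OUT_OF_GRID",
    "FLAG_BRANCH_ENDPOINT",
]

# Validity-flag bits returned by invert_t1.
FLAG_CLAMPED_SIGNAL = 1   # measured value outside [0, 0.5], clamped
FLAG_FT_OUT_OF_GRID = 2   # fT outside the table grid, clamped to the edge
FLAG_BRANCH_ENDPOINT = 4  # match landed on an endpoint of the unique branch

# Strict-monotonicity tolerance on consecutive differences of a column.
_MONO_TOL = 1e-12

# Default grids: 1 ms steps over 1 ms - 5 s (5000 points) and fT 0.4 - 1.6
# in steps of 0.01 (121 points).  The sub-second T1 coverage is required to
# resolve the short-T1 fold of high-fT columns.
DEFAULT_T1_RANGE = (0.001, 5.0)
DEFAULT_T1_STEP = 0.001
DEFAULT_FT_RANGE = (0.4, 1.6)
DEFAULT_FT_STEP = 0.01


def combine(s_mp, s_gre):
    """Ratio-product combination S_MP*S_GRE/(S_MP^2+S_GRE^2).

    Returns 0 where both inputs are 0 (documented convention); the result
    magnitude never exceeds 0.5.
    """
    s_mp = np.asarray(s_mp, dtype=float)
    s_gre = np.asarray(s_gre, dtype=float)
    den = s_mp * s_mp + s_gre * s_gre
    safe = np.where(den > 0, den, 1.0)
    return np.where(den > 0, s_mp * s_gre / safe, 0.0)


@dataclass
class LookupTable:
    """Combined-signal table over a (T1, fT) grid with per-column limits.

    ``limits[j] = (t1_min_unique, t1_max_unique)`` bounds the uniquely
    invertible branch of column j (seconds).
    """

    t1_grid: np.ndarray          # ascending, seconds
    ft_grid: np.ndarray          # ascending, dimensionless
    s_mp: np.ndarray             # signed model MPRAGE signal, (nT1, nFt)
    s_gre: np.ndarray            # model GRE signal, (nT1, nFt)
    s_comb: np.ndarray           # combined signal of the clipped magnitudes
    limits: np.ndarray           # (nFt, 2) seconds
    seq: SequenceParams

    @property
    def t1_step(self) -> float:
        return float(self.t1_grid[1] - self.t1_grid[0])

    def column(self, f_t: float) -> tuple[int, np.ndarray]:
        """Index and combined-signal column nearest to ``f_t``."""
        j = int(np.argmin(np.abs(self.ft_grid - f_t)))
        return j, self.s_comb[:, j]


def _monotonic_branch(column: np.ndarray, anchor: int) -> tuple[int, int]:
    """Index bounds (inclusive) of the largest contiguous strictly
    monotonic run of ``column`` containing ``anchor``."""
    d = np.diff(column)
    if anchor >= d.size:
        anchor = d.size - 1
    s_anchor = np.sign(d[anchor]) if abs(d[anchor]) > _MONO_TOL else 0.0
    if s_anchor == 0.0:
        raise ValueError("column is flat at the anchor; no monotonic branch")
    strict = (np.sign(d) == s_anchor) & (np.abs(d) > _MONO_TOL)
    i = anchor
    while i > 0 and strict[i - 1]:
        i -= 1
    j = anchor
    while j < d.size - 1 and strict[j + 1]:
        j += 1
    return i, j + 1


def identifiability_limits(column: np.ndarray, t1_grid: np.ndarray,
                           s_mp_signed: np.ndarray | None = None,
                           s_gre: np.ndarray | None = None,
                           ft_value: float | None = None):
    """Bounds (t1_min_unique, t1_max_unique), in seconds, of the uniquely
    invertible T1 range of one combined-signal column.

    The branch is the largest contiguous strictly monotonic run containing
    the grid midpoint (the tissue regime), which excludes the short-T1 fold
    where the combined signal attains its 0.5 maximum.

    If the signed MPRAGE signal ``s_mp_signed`` (with its matching
    ``s_gre``) is supplied and crosses zero inside the grid, measured
    magnitudes from longer T1 re-enter the branch's value range; the upper
    limit is then tightened to the T1 at which the branch value falls to
    the maximum of the magnitude-combined tail beyond the crossing, which
    is where uniqueness of the measured (magnitude) signal actually ends.
    """
    column = np.asarray(column, dtype=float)
    t1_grid = np.asarray(t1_grid, dtype=float)
    anchor = t1_grid.size // 2
    if s_mp_signed is None:
        try:
            i, j = _monotonic_branch(column, anchor)
        except ValueError as exc:
            ft_txt = f" at fT={ft_value}" if ft_value is not None else ""
            raise ValueError(f"non-monotonic column{ft_txt}: {exc}") from exc
        return float(t1_grid[i]), float(t1_grid[j])
    return _column_limits(column, np.asarray(s_mp_signed, float),
                          np.asarray(s_gre, float), t1_grid, anchor,
                          ft_value)


def build_lut(seq: SequenceParams,
              t1_range=DEFAULT_T1_RANGE, t1_step=DEFAULT_T1_STEP,
              ft_range=DEFAULT_FT_RANGE, ft_step=DEFAULT_FT_STEP,
              alpha_gre_lut: float | None = None) -> LookupTable:
    """Build the combined-signal lookup table on a (T1, fT) grid.

    ``alpha_gre_lut`` is the flip angle used for the model GRE column
    (defaults to ``seq.alpha_gre``).  The MPRAGE model signal is signed;
    the combination uses its non-negative part, matching magnitude-only
    measured data.
    """
    if t1_range[0] <= 0 or t1_range[1] <= t1_range[0] or t1_step <= 0:
        raise ValueError("invalid T1 range/step")
    if ft_range[1] <= ft_range[0] or ft_step <= 0:
        raise ValueError("invalid fT range/step")
    alpha_gre = seq.alpha_gre if alpha_gre_lut is None else alpha_gre_lut

    n_t1 = int(round((t1_range[1] - t1_range[0]) / t1_step)) + 1
    n_ft = int(round((ft_range[1] - ft_range[0]) / ft_step)) + 1
    t1_grid = t1_range[0] + t1_step * np.arange(n_t1)
    ft_grid = ft_range[0] + ft_step * np.arange(n_ft)

    t1_col = t1_grid[:, None]
    ft_row = ft_grid[None, :]
    s_mp = mprage_signal(seq, t1_col, ft_row)
    s_gre = gre_steady_state_signal(t1_col, alpha_gre, ft_row, seq.tr)
    s_comb = combine(np.clip(s_mp, 0.0, None), s_gre)

    limits = np.empty((n_ft, 2))
    anchor = n_t1 // 2
    for j in range(n_ft):
        limits[j] = _column_limits(
            s_comb[:, j], s_mp[:, j], s_gre[:, j], t1_grid, anchor,
            float(ft_grid[j]),
        )
    return LookupTable(t1_grid=t1_grid, ft_grid=ft_grid, s_mp=s_mp,
                       s_gre=s_gre, s_comb=s_comb, limits=limits, seq=seq)


def _column_limits(s_comb_col, s_mp_col, s_gre_col, t1_grid, anchor,
                   ft_value) -> tuple[float, float]:
    """Identifiability limits of one column, tightening the upper bound by
    the magnitude-fold criterion when the signed MPRAGE signal crosses
    zero inside the grid (measured magnitudes from beyond the crossing
    collide with the branch)."""
    try:
        i, j = _monotonic_branch(s_comb_col, anchor)
    except ValueError as exc:
        raise ValueError(f"non-monotonic LUT column at fT={ft_value}") from exc
    if s_mp_col[anchor] > 0 > s_mp_col[-1]:
        izc = int(np.argmin(np.abs(s_mp_col)))
        tail = combine(np.abs(s_mp_col[izc:]), s_gre_col[izc:])
        tail_max = float(tail.max())
        if tail_max > 0:
            branch = s_comb_col[i:izc]
            above = np.nonzero(branch >= tail_max)[0]
            if above.size:
                j = min(j, i + int(above[-1]))
    return float(t1_grid[i]), float(t1_grid[j])


def invert_t1(s_measured, f_t, lut: LookupTable):
    """Invert measured combined signals to T1 (seconds) with validity flags.

    For each element the fT column nearest to ``f_t`` is selected and the
    T1 grid value minimizing |s - S_LUT| on the column's unique branch is
    returned; argmin ties break toward shorter T1.  Inputs outside [0, 0.5]
    are clamped and flagged; fT outside the grid is clamped to the nearest
    edge and flagged; matches at a branch endpoint are flagged.

    Parameters may be scalars or arrays of a common shape.  Returns
    ``(t1, flags)`` with ``flags`` a bitmask of FLAG_* constants.
    """
    s = np.asarray(s_measured, dtype=float)
    ft = np.broadcast_to(np.asarray(f_t, dtype=float), s.shape).copy()
    scalar = s.ndim == 0
    s = np.atleast_1d(s).astype(float).copy()
    ft = np.atleast_1d(ft)

    flags = np.zeros(s.shape, dtype=np.uint8)
    out_of_range = (s < 0.0) | (s > 0.5)
    flags[out_of_range] |= FLAG_CLAMPED_SIGNAL
    np.clip(s, 0.0, 0.5, out=s)

    ft_lo, ft_hi = lut.ft_grid[0], lut.ft_grid[-1]
    ft_out = (ft < ft_lo) | (ft > ft_hi)
    flags[ft_out] |= FLAG_FT_OUT_OF_GRID
    ft = np.clip(ft, ft_lo, ft_hi)

    ft_step = lut.ft_grid[1] - lut.ft_grid[0]
    cols = np.rint((ft - ft_lo) / ft_step).astype(int)
    cols = np.clip(cols, 0, lut.ft_grid.size - 1)

    t1 = np.empty(s.shape)
    for j in np.unique(cols):
        sel = cols == j
        lo, hi = lut.limits[j]
        i0 = int(np.argmin(np.abs(lut.t1_grid - lo)))
        i1 = int(np.argmin(np.abs(lut.t1_grid - hi)))
        branch = lut.s_comb[i0:i1 + 1, j]
        vals = s[sel]
        # branch is strictly monotonic; search on the sorted orientation
        if branch[0] < branch[-1]:
            idx = _nearest_sorted(branch, vals)
        else:
            idx = branch.size - 1 - _nearest_sorted(branch[::-1], vals)
        t1[sel] = lut.t1_grid[i0 + idx]
        endpoint = (idx == 0) | (idx == branch.size - 1)
        f = flags[sel]
        f[endpoint] |= FLAG_BRANCH_ENDPOINT
        flags[sel] = f

    if scalar:
        return float(t1[0]), int(flags[0])
    return t1, flags


def _nearest_sorted(sorted_vals: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Indices of the nearest entries of an ascending array; ties toward
    the lower index."""
    pos = np.searchsorted(sorted_vals, queries)
    pos = np.clip(pos, 1, sorted_vals.size - 1)
    left = sorted_vals[pos - 1]
    right = sorted_vals[pos]
    take_right = (queries - left) > (right - queries)
    return np.where(take_right, pos, pos - 1).astype(int)


def save_lut(lut: LookupTable, path) -> None:
    """Persist a lookup table as .npz with a JSON sidecar recording the
    grids, sequence parameters, and limits."""
    path = Path(path)
    np.savez(path, t1_grid=lut.t1_grid, ft_grid=lut.ft_grid,
             s_mp=lut.s_mp, s_gre=lut.s_gre, s_comb=lut.s_comb,
             limits=lut.limits)
    sidecar = {
        "seq": asdict(lut.seq),
        "t1_grid": [float(lut.t1_grid[0]), float(lut.t1_grid[-1]),
                    lut.t1_step, int(lut.t1_grid.size)],
        "ft_grid": [float(lut.ft_grid[0]), float(lut.ft_grid[-1]),
                    float(lut.ft_grid[1] - lut.ft_grid[0]),
                    int(lut.ft_grid.size)],
        "limits_s": lut.limits.tolist(),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_lut(path) -> LookupTable:
    path = Path(path)
    arrays = np.load(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    seq = SequenceParams(**sidecar["seq"])
    return LookupTable(t1_grid=arrays["t1_grid"], ft_grid=arrays["ft_grid"],
                       s_mp=arrays["s_mp"], s_gre=arrays["s_gre"],
                       s_comb=arrays["s_comb"], limits=arrays["limits"],
                       seq=seq)
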