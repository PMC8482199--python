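"""Build the (T1, fT) lookup table and report the invertible T1 range.

The combined signal S_MP*S_GRE/(S_MP^2+S_GRE^2) folds at short T1 (where
it attains its 0.5 maximum) and, at very weak transmit fields, also at
long T1 (where the MPRAGE signal crosses zero and magnitude data become
ambiguous).  The table below shows the uniquely measurable T1 window per
relative transmit-field factor fT.
"""

from mpragekit import SequenceParams, build_lut

lut = build_lut(SequenceParams())
print(f"LUT: {lut.t1_grid.size} T1 points x {lut.ft_grid.size} fT columns")
print(" fT    T1 window (ms)")
for ft in (0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6):
    j, _ = lut.column(ft)
    lo, hi = lut.limits[j] * 1000
    hi_txt = f"{hi:5.0f}" if hi < 4999 else " (grid max)"
    print(f" {ft:.1f}   {lo:5.0f} - {hi_txt}")
# T1 below the lower bound cannot be distinguished from a longer T1 with
# the same combined signal; at fT = 0.4 very long T1 is ambiguous too.
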