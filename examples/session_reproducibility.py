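"""Scan-rescan reproducibility before and after ratio normalization.

Simulates five sessions of the same anatomy whose transmit/receive bias
fields drift between sessions (plus Rician noise), then compares the
per-tissue coefficient of variation of the raw MPRAGE stack against the
GRE-normalized stack.  Normalization removes the shared receive field and
most of the transmit-related signal drift.
"""

from mpragekit import (
    Mask, PhantomSpec, SequenceParams, cv_map, make_sessions,
    normalize_mprage,
)

seq = SequenceParams()
spec = PhantomSpec(shape=(32, 32, 32), noise_sigma=0.01, seed=0)
pairs, truth = make_sessions(spec, seq, n_sessions=5, field_jitter=0.5)
mask = Mask(truth.pd_map.data > 0)

raw_cv, _ = cv_map([mp for mp, _ in pairs], mask)
ratios = [normalize_mprage(mp, gre, mask)[0] for mp, gre in pairs]
norm_cv, _ = cv_map(ratios, mask)

print("tissue   CV raw    CV normalized")
for name in ("wm", "gm", "csf"):
    m = truth.label_map.data == truth.labels[name]
    print(f"{name.upper():6s} {100*raw_cv.data[m].mean():7.1f}%"
          f" {100*norm_cv.data[m].mean():10.1f}%")
# The normalized CV is dominated by noise and residual transmit effects;
# the raw CV additionally carries the full session-to-session field drift.
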