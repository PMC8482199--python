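"""End-to-end T1 mapping on a synthetic phantom with known truth.

Renders a noisy MPRAGE/GRE pair (WM SNR 50) over a three-shell phantom
with smooth transmit and receive bias fields, combines the magnitudes,
inverts the lookup table per voxel with the true fT map supplied, and
reports the T1 error per tissue.
"""

import numpy as np

from mpragekit import (
    Mask, PhantomSpec, SequenceParams, build_lut, combined_image,
    invert_t1, render_phantom,
)

seq = SequenceParams()
lut = build_lut(seq)
spec = PhantomSpec(shape=(64, 64, 64), noise_sigma=0.02, seed=0)
mp, gre, truth = render_phantom(spec, seq)

comb = combined_image(mp, gre, Mask(truth.pd_map.data > 0))
est, flags = invert_t1(comb.data, truth.ft_map.data, lut)

err_ms = np.abs(est - truth.t1_map.data) * 1000
for name in ("wm", "gm", "csf"):
    m = truth.label_map.data == truth.labels[name]
    print(f"{name.upper():3s}: true T1 = "
          f"{truth.t1_map.data[m].mean()*1000:4.0f} ms, "
          f"median estimate = {np.median(est[m])*1000:4.0f} ms, "
          f"median |error| = {np.median(err_ms[m]):5.1f} ms "
          f"({m.sum()} voxels)")
# WM/GM errors are tens of ms at this SNR; CSF (T1 = 4 s) sits where the
# combined signal is flat in T1, so its noise sensitivity is much larger.
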