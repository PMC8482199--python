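# mpragekit

Bias-corrected structural brain MRI and quantitative T1 mapping from a
**sequential MPRAGE + reference GRE** acquisition.

High-field T1-weighted MPRAGE images are corrupted by smooth multiplicative
intensity fields: receive-coil sensitivity (f<sub>R</sub>) and the transmit
field (B1<sup>+</sup>, expressed as the relative flip-angle factor
f<sub>T</sub>). Dividing the MPRAGE magnitude S<sub>MP</sub> by a quick
steady-state spoiled-GRE magnitude S<sub>GRE</sub> acquired with the same
receive chain cancels f<sub>R</sub>, proton density and T2\* voxelwise:

```
S_MP/GRE = S_MP / S_GRE = Mz_MP(fT·α_MP, T1, TI) · sin(fT·α_MP)
                          ─────────────────────────────────────
                          M0*(fT·α_GRE, T1)      · sin(fT·α_GRE)
```

leaving a purely T1- (and residually fT-) weighted image. The same pair,
combined as S<sub>MP</sub>·S<sub>GRE</sub>/(S<sub>MP</sub>² + S<sub>GRE</sub>²)
— a quantity bounded by 0.5 and invariant to any common scaling of its
inputs — is inverted through a simulated (T1 × f<sub>T</sub>) lookup table
to a quantitative T1 map, with per-voxel B1<sup>+</sup> correction when a
flip-angle map is available.

The toolkit is aimed at MR physicists and neuroimaging methods developers:
it provides the forward signal models (driven equilibrium
M0\* = M0·(1−e^(−R1·TR))/(1−e^(−R1\*·TR)) with apparent rate
R1\* = R1 − ln cos(f<sub>T</sub>α)/TR, and the cycle-periodic MPRAGE
Mz evolution), the normalization and combination steps, LUT construction
and inversion with identifiability analysis, reproducibility metrics
(WM–GM contrast, CV maps), and a fully synthetic three-shell brain phantom
so that every stage is testable without scanner data.

## Worked example

`examples/build_lut_limits.py` builds the lookup table of the finalized
protocol (α_MP = 8°, α_GRE = 3°, TR = 8 ms, TI = 1200 ms, TF = 288,
T_cycle = 3.5 s, inversion efficiency 0.96) and prints the uniquely
invertible T1 window per transmit-field factor:

```
LUT: 5000 T1 points x 121 fT columns
 fT    T1 window (ms)
 0.4    1123 -  3226
 0.6    1158 -  (grid max)
 0.8    1184 -  (grid max)
 1.0    1173 -  (grid max)
 1.2    1100 -  (grid max)
 1.4     968 -  (grid max)
 1.6     810 -  (grid max)
```

Below the lower bound the combined signal folds back (two T1 values share
one signal), so T1 around 1.1–1.2 s is the shortest measurable value at
nominal transmit field; at f<sub>T</sub> = 0.4 very long T1 is ambiguous
too. `examples/t1_map_phantom.py` runs the full pipeline on a noisy
64³ phantom (white-matter SNR 50):

```
WM : true T1 = 1200 ms, median estimate = 1211 ms, median |error| =  16.0 ms (16368 voxels)
GM : true T1 = 1800 ms, median estimate = 1800 ms, median |error| =  46.0 ms (38824 voxels)
CSF: true T1 = 4000 ms, median estimate = 3992 ms, median |error| = 207.0 ms (40192 voxels)
```

and `examples/session_reproducibility.py` shows the scan-rescan CV per
tissue dropping roughly three-fold after normalization (e.g. WM
3.9% → 1.3% across five sessions with drifting bias fields).

## Command line

A thin CLI wraps the library for shell pipelines
(`mpragekit COMMAND --help` for options):

```sh
mpragekit build-lut --config seq.yaml --out lut.npz
mpragekit phantom  --config seq.yaml --out-dir ph/ --shape 64 --noise-sigma 0.02
mpragekit normalize --mp ph/mp.nii.gz --gre ph/gre.nii.gz --out ratio.nii.gz
mpragekit t1map --lut lut.npz --mp ph/mp.nii.gz --gre ph/gre.nii.gz \
    --b1 ph/truth_ft.nii.gz --out t1.nii.gz     # T1 written in ms
mpragekit cv --stack r1.nii.gz --stack r2.nii.gz --out report.tsv
```

Every command writes a JSON manifest (parameters, seeds, input checksums)
next to its outputs.

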