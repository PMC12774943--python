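# verdictmri

Three-compartment microstructure modelling of kidney diffusion MRI, with a
self-supervised neural fitting engine and a dual-network method for
shortening the acquisition protocol.

Renal tumours are hard to subtype on imaging: the apparent diffusion
coefficient (ADC) conflates cellularity, extracellular space and blood
flow into one number.  This package implements the VERDICT-style
(Vascular, Extracellular and Restricted Diffusion for Cytometry in
Tumours) decomposition of the pulsed-gradient spin-echo (PGSE) signal for
kidney:

    S = f_VASC · S_VASC(d_VASC, b) + f_IC · S_IC(d_IC, R, b, Δ, δ) + f_EES · S_EES(d_EES, b)

where the intracellular pool is an impermeable sphere of radius R
(Gaussian-phase-distribution attenuation), the vascular pool is randomly
oriented sticks with pseudo-diffusivity d_VASC = 50 µm²/ms, and the
extracellular-extravascular space is a Gaussian ball; d_IC = d_EES =
2 µm²/ms are fixed and f_VASC = 1 − f_IC − f_EES.  Three free parameters
(f_IC, f_EES ∈ [0,1], R ∈ [0,15] µm) are estimated per voxel, either by
classical multi-start least squares or by a small self-supervised network
whose loss is the reconstruction error of the forward model — no training
labels needed.

It is intended for researchers in quantitative diffusion MRI who want a
reproducible, dependency-light reference implementation of the full
analysis chain: acquisition-scheme handling, forward models with
independent numerical oracles, both fitting engines, IVIM/ADC baselines,
a synthetic renal phantom generator (no patient data ships or is needed),
the dual-network b-value selector, and rank-based group statistics.

## Worked example

`examples/02_simulate_and_fit.py` simulates a three-class renal phantom
(normal parenchyma, cancerous tumour, benign oncocytoma) at b0 SNR 50 on
the full 9-b-value kidney protocol and fits it with the self-supervised
engine:

```text
trained 400 epochs, final reconstruction loss 1.62e-04, converged=False

         class  true f_IC  fitted f_IC  fitted R (um)
 normal_kidney      0.122        0.149           7.66
        cancer      0.321        0.311           8.51
    oncocytoma      0.170        0.161           7.67
```

The fitted intracellular volume fraction recovers the generating
contrast: cancerous tissue is roughly 2.5× more "cellular" than normal
parenchyma, with the benign oncocytoma in between — the contrast that
makes f_IC a candidate imaging biomarker.  (`converged=False` means the
loss was still improving at the epoch cap, not that the fit failed.)

`examples/04_protocol_reduction.py` trains the dual-network selector on a
synthetic cohort: a scoring network (27 → 64 → 27, sigmoid) ranks the 27
direction-resolved measurements, a prediction network reconstructs all 27
from the 12 highest-scoring, and the cohort-averaged scores — aggregated
per b-value triplet — yield a reduced, acquirable 4-b-value protocol
(12 measurements in 3 directions, matched b0s retained).  The other
examples cover the forward models, the VERDICT/IVIM/ADC model comparison
by mean squared error, and the vascular vs non-vascular group test.

A thin CLI wraps the same functions:

```bash
verdictmri scheme show
verdictmri simulate --out sim/ --snr 50
verdictmri fit --selfsupervised --scheme sim/scheme.txt --dwi sim/dwi.nii.gz --out maps/
verdictmri optimize-protocol --scheme sim/scheme.txt --out reduced.scheme
```

## Layout

```
src/verdictmri/   scheme, models, classical, selfsup, protocol,
                  synthetic, datasets, io, stats, cli
examples/         one short narrative script per capability
docs/methods.md   model assumptions, numerical choices, limitations
tests/            unit, property and acceptance tests
```
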