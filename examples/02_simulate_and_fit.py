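"""Simulate a small renal phantom at b0 SNR 50 and fit it with the
self-supervised network; print ROI means against the ground truth."""

import numpy as np

import verdictmri as v

scheme = v.kidney_full_protocol()
# a few thousand masked voxels give the self-supervised fit enough gradient
# updates per epoch; tiny datasets train slowly at the fixed learning rate
spec = v.PhantomSpec(shape=(24, 24, 3), snr=50.0, seed=3)
phantom = v.make_phantom(spec)
dataset = v.simulate_signals(phantom, scheme)

maps = v.fit_selfsupervised(dataset, scheme, v.TrainConfig(seed=1))
print(
    f"trained {len(maps.loss_trace)} epochs, final reconstruction loss "
    f"{maps.loss_trace[-1]:.2e}, converged={maps.converged}\n"
)

coords = tuple(dataset.coords.T)
print(f"{'class':>14} {'true f_IC':>10} {'fitted f_IC':>12} {'fitted R (um)':>14}")
for cid, cls in enumerate(phantom.classes):
    sel = dataset.mask_id == cid
    true_fic = phantom.maps["f_ic"][coords][sel].mean()
    fic = maps["f_ic"][coords][sel].mean()
    rad = maps["radius"][coords][sel].mean()
    print(f"{cls.name:>14} {true_fic:10.3f} {fic:12.3f} {rad:14.2f}")

print(
    "\nPer-class means of the fitted intracellular volume fraction should "
    "track the\ngenerating values: cancerous tissue is markedly more "
    "cellular (higher f_IC)\nthan normal parenchyma, with oncocytoma in "
    "between."
)
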