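"""Rank-based group comparison of vascular volume fraction between vascular
and non-vascular tumour groups, with the figure-style star coding."""

import numpy as np

import verdictmri as v

# subject-level ROI means drawn from the reported group distributions:
# vascular tumours f_VASC 0.29 +/- 0.05, non-vascular 0.13 +/- 0.02
rng = np.random.default_rng(0)
vascular = {"f_vasc": rng.normal(0.29, 0.05, 10)}
nonvascular = {"f_vasc": rng.normal(0.13, 0.02, 10)}

table = v.compare_groups(vascular, nonvascular, names=("vascular", "non-vascular"))
print(table.to_string(index=False))
print(
    "\nThe rank-sum test compares subject-level ROI means; stars code the "
    "p-value band\n(0.01-0.05 -> *, 0.001-0.01 -> **, ...). A vascular "
    "fraction contrast of this size\nis reliably detectable with 10 subjects "
    "per group."
)
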