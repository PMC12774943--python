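"""Synthetic renal phantoms and cohorts.

No imaging data ships with this package; every fitting and selection module is
exercised on phantoms that emulate the study conditions: a 9-b-value PGSE
protocol acquired in three orthogonal directions with a matched b0 per combo,
Rician magnitude noise, spherical averaging and matched-b0 normalisation.

Tissue classes carry the intracellular and vascular volume-fraction contrasts
reported for renal tissue: normal parenchyma f_IC ~ 0.12, cancerous tumour
~ 0.32, benign oncocytoma ~ 0.17; vascular tumours f_VASC ~ 0.29 +/- 0.05
against 0.13 +/- 0.02 for non-vascular ones.  Cell radii are not reported for
these tissues, so the defaults are plausible values inside the model's
[0, 15] um range (documented as package choices, not measured values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import models
from .datasets import ParameterMaps, VoxelDataset, volume_layout
from .scheme import AcquisitionScheme, expand_measurements

__all__ = [
    "TissueClassSpec",
    "PhantomSpec",
    "Phantom",
    "CLASS_TABLE",
    "make_phantom",
    "simulate_signals",
    "make_cohort",
]


@dataclass(frozen=True)
class TissueClassSpec:
    """Mean/SD of the tissue parameters for one class of voxels."""

    name: str
    f_ic: float
    f_ic_sd: float
    f_vasc: float
    f_vasc_sd: float
    radius: float
    radius_sd: float
    vascular: bool
    t2: float = 80.0  # ms, only used when the T2 channel is enabled

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_ic <= 1.0 and 0.0 <= self.f_vasc <= 1.0):
            raise ValueError("class mean fractions must lie in [0, 1]")
        if self.f_ic + self.f_vasc > 1.0:
            raise ValueError("class mean fractions must leave room for f_EES")
        if not (0.0 <= self.radius <= models.R_MAX):
            raise ValueError("class mean radius outside [0, 15] um")
        if min(self.f_ic_sd, self.f_vasc_sd, self.radius_sd) < 0:
            raise ValueError("SDs must be >= 0")


# volume-fraction means follow the reported group contrasts; radii and the
# normal-parenchyma vascular fraction are package defaults (not reported)
CLASS_TABLE: dict[str, TissueClassSpec] = {
    c.name: c
    for c in [
        TissueClassSpec("normal_kidney", 0.12, 0.03, 0.20, 0.04, 6.0, 0.5, False),
        TissueClassSpec("cancer", 0.32, 0.07, 0.20, 0.05, 9.0, 0.5, True),
        TissueClassSpec("ccRCC", 0.21, 0.07, 0.29, 0.05, 8.0, 0.5, True),
        TissueClassSpec("pRCC", 0.55, 0.05, 0.13, 0.02, 9.0, 0.5, False),
        TissueClassSpec("chRCC", 0.21, 0.07, 0.29, 0.05, 8.0, 0.5, True),
        TissueClassSpec("oncocytoma", 0.17, 0.03, 0.29, 0.05, 8.0, 0.5, True),
        TissueClassSpec("uRCC", 0.59, 0.05, 0.13, 0.02, 10.0, 0.5, False),
        TissueClassSpec("cyst", 0.02, 0.01, 0.02, 0.01, 5.0, 0.5, False),
    ]
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue classes and noise model of a synthetic phantom.

    Classes occupy disjoint equal slabs along the first grid axis (or
    explicit ``regions`` masks).  ``snr`` is the b0 signal-to-noise ratio of
    the Rician noise model; None disables noise.  ``with_t2`` scales each
    combo's signals by exp(-TE/T2_class) before noise, which matched-b0
    normalisation cancels again.
    """

    shape: tuple[int, int, int] = (32, 32, 4)
    classes: tuple[TissueClassSpec, ...] = (
        CLASS_TABLE["normal_kidney"],
        CLASS_TABLE["cancer"],
        CLASS_TABLE["oncocytoma"],
    )
    snr: float | None = 50.0
    with_t2: bool = False
    seed: int = 0
    regions: tuple[np.ndarray, ...] | None = None

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be > 0")
        if len(self.classes) == 0:
            raise ValueError("at least one tissue class required")

    def region_masks(self) -> list[np.ndarray]:
        if self.regions is not None:
            masks = [np.asarray(r, bool) for r in self.regions]
            if any(m.shape != self.shape for m in masks):
                raise ValueError("region masks must match phantom shape")
            total = np.zeros(self.shape, dtype=int)
            for m in masks:
                total += m
            if total.max() > 1:
                raise ValueError("overlapping regions")
            return masks
        nx = self.shape[0]
        edges = np.linspace(0, nx, len(self.classes) + 1).astype(int)
        masks = []
        for i in range(len(self.classes)):
            m = np.zeros(self.shape, dtype=bool)
            m[edges[i] : edges[i + 1]] = True
            masks.append(m)
        return masks


@dataclass
class Phantom:
    """Ground-truth parameter maps plus per-voxel class labels."""

    maps: ParameterMaps
    class_ids: np.ndarray  # int volume, -1 outside any region
    classes: tuple[TissueClassSpec, ...]
    spec: PhantomSpec


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Truncated-normal draws by resampling (SDs are small relative to bounds)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Draw voxelwise ground-truth parameters per tissue class (seeded)."""
    rng = np.random.default_rng(spec.seed)
    masks = spec.region_masks()
    shape = spec.shape
    f_ic = np.full(shape, np.nan)
    f_vasc = np.full(shape, np.nan)
    radius = np.full(shape, np.nan)
    class_ids = np.full(shape, -1, dtype=int)

    for cid, (cls, mask) in enumerate(zip(spec.classes, masks)):
        n = int(mask.sum())
        if n == 0:
            continue
        fic = _truncnorm(rng, cls.f_ic, cls.f_ic_sd, 0.0, 1.0, n)
        fv = _truncnorm(rng, cls.f_vasc, cls.f_vasc_sd, 0.0, 1.0, n)
        # keep the simplex: shrink both fractions where they would overflow
        s = fic + fv
        over = s > 0.99
        fic[over] *= 0.99 / s[over]
        fv[over] *= 0.99 / s[over]
        r = _truncnorm(rng, cls.radius, cls.radius_sd, 0.0, models.R_MAX, n)
        f_ic[mask] = fic
        f_vasc[mask] = fv
        radius[mask] = r
        class_ids[mask] = cid

    in_any = class_ids >= 0
    f_ees = 1.0 - f_ic - f_vasc
    maps = ParameterMaps(
        maps={"f_ic": f_ic, "f_ees": f_ees, "f_vasc": f_vasc, "radius": radius},
        mask=in_any,
    )
    return Phantom(maps=maps, class_ids=class_ids, classes=tuple(spec.classes), spec=spec)


def _noiseless_combo_signals(
    phantom: Phantom, scheme: AcquisitionScheme
) -> tuple[np.ndarray, np.ndarray]:
    """(coords (n,3), signals (n, n_combos)) for all in-mask voxels."""
    mask = phantom.maps.mask
    coords = np.argwhere(mask)
    f_ic = phantom.maps["f_ic"][mask]
    f_ees = phantom.maps["f_ees"][mask]
    radius = phantom.maps["radius"][mask]
    a = models.sphere_attenuation(
        radius, models.D_IC, scheme.b_values, scheme.deltas, scheme.Deltas
    )
    s_ees = models.signal_ball(scheme.b_values, models.D_EES)
    s_vasc = models.signal_astrosticks(scheme.b_values, models.D_VASC)
    f_vasc = 1.0 - f_ic - f_ees
    sig = (
        f_vasc[:, None] * s_vasc + f_ic[:, None] * a + f_ees[:, None] * s_ees
    )
    return coords, sig


def simulate_signals(
    phantom: Phantom,
    scheme: AcquisitionScheme,
    seed: int | None = None,
) -> VoxelDataset:
    """Simulate the acquisition on a phantom.

    Per voxel and combo: the isotropic model signal is replicated over the
    three gradient directions, independent Rician noise is applied to every
    direction-resolved measurement and to each matched b0, the directions are
    spherically averaged, and everything is divided by the matched noisy b0.
    When the T2 channel is on, signals and noise amplitude are both scaled by
    exp(-TE/T2) (SNR is defined at each combo's b0), so normalised data are
    identical to the T2-off simulation under the same seed.

    Returns a dataset carrying both the matched-b0-normalised volume vectors
    (for fitting) and the direction-resolved normalised DW table (for
    protocol selection).
    """
    spec = phantom.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    coords, sig = _noiseless_combo_signals(phantom, scheme)
    n, n_combos = sig.shape
    n_dir = scheme.n_directions

    if spec.with_t2:
        t2 = np.array([c.t2 for c in phantom.classes])
        cls = phantom.class_ids[phantom.maps.mask]
        amp = np.exp(-scheme.tes[None, :] / t2[cls][:, None])  # (n, n_combos)
    else:
        amp = np.ones((n, n_combos))

    if spec.snr is None:
        dw_avg = sig
        b0 = np.ones((n, n_combos))
        dw_dirs = np.repeat(sig, n_dir, axis=1)
    else:
        inv_snr = 1.0 / spec.snr
        # unit-scale complex noise, scaled by the TE-dependent amplitude so
        # that matched-b0 division cancels T2 exactly under one seed
        zr = rng.normal(size=(n, n_combos, n_dir))
        zi = rng.normal(size=(n, n_combos, n_dir))
        dirs = amp[:, :, None] * np.sqrt(
            (sig[:, :, None] + inv_snr * zr) ** 2 + (inv_snr * zi) ** 2
        )
        zr0 = rng.normal(size=(n, n_combos))
        zi0 = rng.normal(size=(n, n_combos))
        b0 = amp * np.sqrt((1.0 + inv_snr * zr0) ** 2 + (inv_snr * zi0) ** 2)
        dw_avg = dirs.mean(axis=2) / b0
        dw_dirs = (dirs / b0[:, :, None]).reshape(n, n_combos * n_dir)

    b0_idx, dw_idx = volume_layout(scheme)
    signals = np.ones((n, scheme.n_volumes))
    signals[:, dw_idx] = dw_avg

    mask_id = phantom.class_ids[phantom.maps.mask]
    return VoxelDataset(
        signals=signals,
        coords=coords,
        shape=spec.shape,
        mask_id=mask_id,
        dw_directions=dw_dirs,
    )


def make_cohort(
    spec: PhantomSpec,
    n_subjects: int = 14,
    seed: int = 0,
    scheme: AcquisitionScheme | None = None,
    jitter_f_ic: float = 0.03,
    jitter_f_vasc: float = 0.02,
    jitter_radius: float = 0.5,
) -> list[VoxelDataset]:
    """Independent subjects with subject-level jitter on the class means.

    The f_IC jitter default matches the reported between-patient spread of
    normal-parenchyma f_IC (SD 0.03).  Each subject gets its own phantom seed
    derived from ``seed``; ``n_subjects=1`` with zero jitter reproduces
    ``simulate_signals(make_phantom(spec), scheme)`` for the derived seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]
    scheme_cohort: list[VoxelDataset] = []
    if scheme is None:
        from .scheme import kidney_full_protocol

        scheme = kidney_full_protocol()
    for s_seed in subject_seeds:
        rng = np.random.default_rng(s_seed)
        jittered = []
        for cls in spec.classes:
            f_ic = float(np.clip(cls.f_ic + rng.normal(0, jitter_f_ic), 0.0, 0.95))
            f_vasc = float(np.clip(cls.f_vasc + rng.normal(0, jitter_f_vasc), 0.0, 0.95))
            if f_ic + f_vasc > 0.99:
                scale = 0.99 / (f_ic + f_vasc)
                f_ic, f_vasc = f_ic * scale, f_vasc * scale
            radius = float(
                np.clip(cls.radius + rng.normal(0, jitter_radius), 0.0, models.R_MAX)
            )
            jittered.append(replace(cls, f_ic=f_ic, f_vasc=f_vasc, radius=radius))
        sub_spec = replace(spec, classes=tuple(jittered), seed=s_seed)
        phantom = make_phantom(sub_spec)
        scheme_cohort.append(simulate_signals(phantom, scheme, seed=s_seed + 1))
    return scheme_cohort
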