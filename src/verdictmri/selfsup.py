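"""Self-supervised fitting of the three-compartment model.

A small fully connected network (input width = number of image volumes, three
hidden layers of 18 units) maps each voxel's measurement vector — standardised
per feature for conditioning — to the three free tissue parameters
(f_IC, f_EES, R).  The parameters are pushed
through the forward model to reconstruct the signal, and the training loss is
the mean squared error between reconstruction and input — no labels are
needed, and training and inference run on the same masked dataset.

Network outputs are constrained by hard clamping into their physical ranges
([0,1], [0,1], [0,15] um); when the clamped fractions leave the unit simplex
they are renormalised proportionally so that f_VASC = 1 - f_IC - f_EES stays
in [0,1].  Gradients flow through the forward model analytically for the
fractions (the signal is affine in them) and by central finite differences
for the sphere radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from ._nn import Adam, Dense, Dropout, ELU, Sequential
from .datasets import ParameterMaps, VoxelDataset, volume_layout
from .scheme import AcquisitionScheme

__all__ = ["TrainConfig", "fit_selfsupervised"]

_R_FD_STEP = 1e-3  # um, central-difference step for dS/dR


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration for the self-supervised fitter.

    Defaults follow the fitting recipe this package implements: three hidden
    layers of 18 units, Adam with learning rate 1e-4, dropout p=0.5 during
    training, hard clamping of outputs, early stopping on the training loss.
    """

    hidden_layers: int = 3
    hidden_width: int = 18
    learning_rate: float = 1e-4
    dropout_p: float = 0.5
    patience: int = 50
    min_delta: float = 1e-7
    max_epochs: int = 400
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("network size must be positive")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be positive")


def _build_net(n_in: int, cfg: TrainConfig, rng: np.random.Generator) -> Sequential:
    layers: list = []
    width = n_in
    for _ in range(cfg.hidden_layers):
        layers += [Dense(width, cfg.hidden_width, rng), ELU(),
                   Dropout(cfg.dropout_p, rng)]
        width = cfg.hidden_width
    head = Dense(width, 3, rng)
    # start the raw outputs mid-range so the hard clamp is not saturated at init
    head.b[:] = (0.3, 0.4, 7.5)
    head.w *= 0.1
    layers.append(head)
    return Sequential(*layers)


def _constrain(raw: np.ndarray) -> tuple[np.ndarray, dict]:
    """Clamp raw outputs into range and renormalise off-simplex fractions.

    Returns (params, cache) where params[:, 0:3] = (f_ic, f_ees, radius) and
    cache holds what the backward pass needs.
    """
    lo = np.array([0.0, 0.0, 0.0])
    hi = np.array([1.0, 1.0, models.R_MAX])
    clamped = np.clip(raw, lo, hi)
    interior = (raw > lo) & (raw < hi)  # hard clamp: zero gradient outside

    f_ic, f_ees = clamped[:, 0], clamped[:, 1]
    s = f_ic + f_ees
    over = s > 1.0
    out = clamped.copy()
    safe_s = np.where(over, s, 1.0)
    out[:, 0] = np.where(over, f_ic / safe_s, f_ic)
    out[:, 1] = np.where(over, f_ees / safe_s, f_ees)
    cache = {"interior": interior, "over": over, "s": safe_s,
             "f_ic": f_ic, "f_ees": f_ees}
    return out, cache


def _constrain_backward(grad_out: np.ndarray, cache: dict) -> np.ndarray:
    """Chain rule through renormalisation and clamping."""
    over = cache["over"]
    s = cache["s"]
    f_ic, f_ees = cache["f_ic"], cache["f_ees"]
    g = grad_out.copy()
    if over.any():
        g_ic, g_ees = grad_out[:, 0], grad_out[:, 1]
        # d(f_ic/s)/df_ic = f_ees/s^2 ; d(f_ic/s)/df_ees = -f_ic/s^2 ; symmetric
        d_ic = np.where(over, (g_ic * f_ees - g_ees * f_ees) / s**2, g_ic)
        d_ees = np.where(over, (g_ees * f_ic - g_ic * f_ic) / s**2, g_ees)
        g[:, 0] = d_ic
        g[:, 1] = d_ees
    return g * cache["interior"]


class _ForwardModel:
    """Batch forward model and parameter-gradient evaluation over a scheme."""

    def __init__(self, scheme: AcquisitionScheme):
        self.scheme = scheme
        self.s_ees = models.signal_ball(scheme.b_values, models.D_EES)
        self.s_vasc = models.signal_astrosticks(scheme.b_values, models.D_VASC)

    def _sphere(self, radius: np.ndarray) -> np.ndarray:
        sch = self.scheme
        return models.sphere_attenuation(
            radius, models.D_IC, sch.b_values, sch.deltas, sch.Deltas
        )

    def signal(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (signal (batch, n_combos), sphere signal for reuse)."""
        f_ic, f_ees, radius = params[:, 0:1], params[:, 1:2], params[:, 2]
        a = self._sphere(radius)
        f_vasc = 1.0 - f_ic - f_ees
        return f_vasc * self.s_vasc + f_ic * a + f_ees * self.s_ees, a

    def param_grad(
        self, params: np.ndarray, a: np.ndarray, grad_sig: np.ndarray
    ) -> np.ndarray:
        """d(loss)/d(f_ic, f_ees, radius) given d(loss)/d(signal)."""
        radius = params[:, 2]
        h = _R_FD_STEP
        a_plus = self._sphere(np.clip(radius + h, 0.0, models.R_MAX))
        a_minus = self._sphere(np.clip(radius - h, 0.0, models.R_MAX))
        da_dr = (a_plus - a_minus) / (2.0 * h)
        g = np.empty_like(params)
        g[:, 0] = np.sum(grad_sig * (a - self.s_vasc), axis=1)
        g[:, 1] = np.sum(grad_sig * (self.s_ees - self.s_vasc), axis=1)
        g[:, 2] = np.sum(grad_sig * params[:, 0:1] * da_dr, axis=1)
        return g


def _predict_params(net: Sequential, signals: np.ndarray) -> np.ndarray:
    raw = net.forward(signals, train=False)
    params, _ = _constrain(raw)
    return params


def fit_selfsupervised(
    dataset: VoxelDataset,
    scheme: AcquisitionScheme,
    config: TrainConfig | None = None,
) -> ParameterMaps:
    """Fit the three-compartment model to every masked voxel.

    Returns parameter maps (f_ic, f_ees, f_vasc, radius) on the dataset grid
    with the per-epoch training-loss trace attached; ``converged`` is False if
    early stopping never triggered within ``max_epochs`` (the result is still
    returned).
    """
    cfg = config or TrainConfig()
    if dataset.n_voxels == 0:
        raise ValueError("empty mask: no voxels to fit")
    dataset.validate_against(scheme)

    b0_idx, dw_idx = volume_layout(scheme)
    x = dataset.signals  # (n, n_volumes), b0 slots already 1
    n, n_vol = x.shape
    # the network sees per-feature standardised signals (removes the common
    # mode that otherwise creates a long constant-output saddle); the
    # reconstruction loss is always computed against the raw signals
    x_net = (x - x.mean(axis=0)) / (x.std(axis=0) + 1e-8)

    rng = np.random.default_rng(cfg.seed)
    net = _build_net(n_vol, cfg, rng)
    fwd = _ForwardModel(scheme)
    opt = Adam([net], lr=cfg.learning_rate)

    best_loss = np.inf
    best_state = net.state()
    best_epoch = -1
    trace: list[float] = []
    converged = False

    def monitored_loss() -> float:
        # deterministic (dropout-off) reconstruction loss over the full dataset;
        # smooth enough for a patience/min-delta stopping rule
        params = _predict_params(net, x_net)
        sig, _ = fwd.signal(params)
        resid = sig - x[:, dw_idx]
        return float(np.sum(resid**2) / (n * n_vol))

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x[idx]
            opt.zero_grad()
            raw = net.forward(x_net[idx], train=True)
            params, cache = _constrain(raw)
            sig, a = fwd.signal(params)
            # reconstruction over all volumes; b0 slots reconstruct exactly 1
            recon = np.ones((len(idx), n_vol))
            recon[:, dw_idx] = sig
            resid = recon - xb
            grad_sig = 2.0 * resid[:, dw_idx] / resid.size
            gparams = fwd.param_grad(params, a, grad_sig)
            net.backward(_constrain_backward(gparams, cache))
            opt.step()
        epoch_loss = monitored_loss()
        trace.append(epoch_loss)
        if epoch_loss < best_loss - cfg.min_delta:
            best_loss = epoch_loss
            best_state = net.state()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            converged = True
            break

    net.load_state(best_state)
    params = _predict_params(net, x_net)
    f_ic, f_ees, radius = params[:, 0], params[:, 1], params[:, 2]
    f_vasc = np.clip(1.0 - f_ic - f_ees, 0.0, 1.0)
    return ParameterMaps.from_voxels(
        {"f_ic": f_ic, "f_ees": f_ees, "f_vasc": f_vasc, "radius": radius},
        dataset.coords,
        dataset.shape,
        loss_trace=np.asarray(trace),
        converged=converged,
    )
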