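"""Dual-network b-value selection for protocol economisation.

Two small networks are trained in tandem on the 27 direction-resolved DW
measurements of each subject (non-DW volumes are excluded from candidacy —
each retained combo keeps its matched b0 automatically):

* a feature-scoring network (27 -> 64 rectified units with batch
  normalisation -> 27 sigmoid outputs) produces an importance score in [0,1]
  per measurement;
* the 12 highest-scoring measurements, weighted by their scores, feed a
  prediction network (12 -> 64 rectified units -> 27) that reconstructs the
  full measurement vector; the loss is the MSE of that reconstruction.

Each subject's measurement matrix is standardised per feature (zero mean,
unit variance over voxels) before training, so every measurement competes on
an equal footing regardless of its raw signal level.  Gradients reach the
scoring network through the retained features only (the score multiplies the
selected measurement).  One network pair is trained per subject; importance
scores are averaged across subjects, aggregated per b-value over each
direction triplet, and the top four b-values form the reduced protocol —
whole triplets, so the result is an acquirable scheme.

All subjects' network pairs are advanced in lock-step as stacked weight
tensors, which keeps desk-scale cohort training fast without changing the
per-subject mathematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import VoxelDataset
from .scheme import AcquisitionScheme, kidney_full_protocol

__all__ = [
    "SelectionConfig",
    "ImportanceScores",
    "SelectedProtocol",
    "train_dual_network",
    "select_protocol",
    "reduce_scheme",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Architecture and training settings for the dual-network selector."""

    n_features_in: int = 27
    k_selected: int = 12
    hidden_width: int = 64
    epochs: int = 100
    learning_rate: float = 1e-5
    dropout_p: float = 0.2
    batch_size: int = 8
    n_directions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_selected < self.n_features_in:
            raise ValueError("k_selected must be < n_features_in")
        if self.k_selected % self.n_directions != 0:
            raise ValueError("k_selected must be divisible by n_directions")
        if self.n_features_in % self.n_directions != 0:
            raise ValueError("n_features_in must be divisible by n_directions")


@dataclass(frozen=True)
class ImportanceScores:
    """Sigmoid importance scores per DW measurement.

    per_subject : (n_subjects, n_features) array of per-subject mean scores.
    cohort : (n_features,) cohort average.
    """

    per_subject: np.ndarray
    cohort: np.ndarray
    loss_traces: tuple[np.ndarray, ...] = ()

    def __post_init__(self) -> None:
        if np.any(self.cohort < 0) or np.any(self.cohort > 1):
            raise ValueError("scores must lie in [0, 1]")


@dataclass(frozen=True)
class SelectedProtocol:
    """Outcome of the selection stage: retained measurements and b-values."""

    measurement_indices: tuple[int, ...]
    b_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.measurement_indices)) != len(self.measurement_indices):
            raise ValueError("retained measurement indices must be unique")


def _subject_matrix(subject, n_features: int) -> np.ndarray:
    """Extract and standardise one subject's (n_voxels, n_features) DW matrix."""
    if isinstance(subject, VoxelDataset):
        if subject.dw_directions is None:
            raise ValueError("dataset has no direction-resolved DW table")
        x = subject.dw_directions
    else:
        x = np.atleast_2d(np.asarray(subject, dtype=float))
    if x.ndim != 2 or x.shape[1] != n_features:
        raise ValueError(
            f"each subject needs {n_features} DW measurements per voxel, "
            f"got shape {x.shape}"
        )
    return (x - x.mean(axis=0)) / (x.std(axis=0) + 1e-8)


class _DualNetStack:
    """S independent scorer/predictor pairs advanced in lock-step.

    Weights are stacked along a leading subject axis; every operation is a
    batched matmul, so the per-subject forward/backward mathematics is the
    same as training each pair on its own.
    """

    def __init__(self, n_subj: int, cfg: SelectionConfig, rng: np.random.Generator):
        f, h, k = cfg.n_features_in, cfg.hidden_width, cfg.k_selected
        self.cfg = cfg
        self.rng = rng

        def dense(n_in, n_out):
            scale = np.sqrt(2.0 / n_in)
            return (
                rng.normal(0.0, scale, size=(n_subj, n_in, n_out)),
                np.zeros((n_subj, n_out)),
            )

        self.sw1, self.sb1 = dense(f, h)          # scoring hidden
        self.bn_gamma = np.ones((n_subj, h))      # batch norm on scoring hidden
        self.bn_beta = np.zeros((n_subj, h))
        self.bn_mean = np.zeros((n_subj, h))
        self.bn_var = np.ones((n_subj, h))
        self.sw2, self.sb2 = dense(h, f)          # scoring output (sigmoid)
        self.pw1, self.pb1 = dense(k, h)          # prediction hidden
        self.pw2, self.pb2 = dense(h, f)          # prediction output
        self._params = [
            self.sw1, self.sb1, self.bn_gamma, self.bn_beta,
            self.sw2, self.sb2, self.pw1, self.pb1, self.pw2, self.pb2,
        ]
        self._m = [np.zeros_like(p) for p in self._params]
        self._v = [np.zeros_like(p) for p in self._params]
        self._t = 0

    # --- scoring network -------------------------------------------------
    def scores(self, x: np.ndarray, train: bool):
        """x: (S, B, F) -> sigmoid scores (S, B, F) with cached intermediates."""
        cfg = self.cfg
        h_lin = x @ self.sw1 + self.sb1[:, None, :]
        if train:
            mean = h_lin.mean(axis=1)
            var = h_lin.var(axis=1)
            self.bn_mean = 0.9 * self.bn_mean + 0.1 * mean
            self.bn_var = 0.9 * self.bn_var + 0.1 * var
        else:
            mean, var = self.bn_mean, self.bn_var
        std = np.sqrt(var + 1e-5)
        xhat = (h_lin - mean[:, None, :]) / std[:, None, :]
        h_bn = self.bn_gamma[:, None, :] * xhat + self.bn_beta[:, None, :]
        relu_mask = h_bn > 0
        h_act = h_bn * relu_mask
        if train and cfg.dropout_p > 0:
            keep = 1.0 - cfg.dropout_p
            drop = (self.rng.random(h_act.shape) < keep) / keep
        else:
            drop = None
        h_drop = h_act if drop is None else h_act * drop
        logits = h_drop @ self.sw2 + self.sb2[:, None, :]
        s = 1.0 / (1.0 + np.exp(-logits))
        cache = (x, xhat, std, relu_mask, drop, h_drop, s, train)
        return s, cache

    def scores_backward(self, gs: np.ndarray, cache) -> None:
        x, xhat, std, relu_mask, drop, h_drop, s, train = cache
        g_logit = gs * s * (1.0 - s)
        self.g_sw2 += np.swapaxes(h_drop, 1, 2) @ g_logit
        self.g_sb2 += g_logit.sum(axis=1)
        g_h = g_logit @ np.swapaxes(self.sw2, 1, 2)
        if drop is not None:
            g_h = g_h * drop
        g_h = g_h * relu_mask
        self.g_bn_gamma += (g_h * xhat).sum(axis=1)
        self.g_bn_beta += g_h.sum(axis=1)
        g_xhat = g_h * self.bn_gamma[:, None, :]
        if train and g_h.shape[1] > 1:
            g_lin = (
                g_xhat
                - g_xhat.mean(axis=1, keepdims=True)
                - xhat * (g_xhat * xhat).mean(axis=1, keepdims=True)
            ) / std[:, None, :]
        else:
            g_lin = g_xhat / std[:, None, :]
        self.g_sw1 += np.swapaxes(x, 1, 2) @ g_lin
        self.g_sb1 += g_lin.sum(axis=1)

    # --- prediction network ----------------------------------------------
    def predict(self, z: np.ndarray, train: bool):
        cfg = self.cfg
        h_lin = z @ self.pw1 + self.pb1[:, None, :]
        relu_mask = h_lin > 0
        h_act = h_lin * relu_mask
        if train and cfg.dropout_p > 0:
            keep = 1.0 - cfg.dropout_p
            drop = (self.rng.random(h_act.shape) < keep) / keep
        else:
            drop = None
        h_drop = h_act if drop is None else h_act * drop
        out = h_drop @ self.pw2 + self.pb2[:, None, :]
        cache = (z, relu_mask, drop, h_drop)
        return out, cache

    def predict_backward(self, g_out: np.ndarray, cache) -> np.ndarray:
        z, relu_mask, drop, h_drop = cache
        self.g_pw2 += np.swapaxes(h_drop, 1, 2) @ g_out
        self.g_pb2 += g_out.sum(axis=1)
        g_h = g_out @ np.swapaxes(self.pw2, 1, 2)
        if drop is not None:
            g_h = g_h * drop
        g_h = g_h * relu_mask
        self.g_pw1 += np.swapaxes(z, 1, 2) @ g_h
        self.g_pb1 += g_h.sum(axis=1)
        return g_h @ np.swapaxes(self.pw1, 1, 2)

    # --- optimisation ------------------------------------------------------
    def zero_grad(self) -> None:
        (self.g_sw1, self.g_sb1, self.g_bn_gamma, self.g_bn_beta, self.g_sw2,
         self.g_sb2, self.g_pw1, self.g_pb1, self.g_pw2, self.g_pb2) = (
            np.zeros_like(p) for p in self._params
        )

    def _grads(self):
        return [self.g_sw1, self.g_sb1, self.g_bn_gamma, self.g_bn_beta,
                self.g_sw2, self.g_sb2, self.g_pw1, self.g_pb1, self.g_pw2,
                self.g_pb2]

    def adam_step(self) -> None:
        self._t += 1
        lr, b1, b2, eps = self.cfg.learning_rate, 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(self._params, self._grads())):
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1**self._t)
            vhat = self._v[i] / (1 - b2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


def _topk_per_net(sbar: np.ndarray, k: int) -> np.ndarray:
    """Top-k feature indices per net, ties towards the lower index; sorted."""
    order = np.argsort(-sbar, axis=1, kind="stable")[:, :k]
    return np.sort(order, axis=1)


def _train_stack(
    xs: np.ndarray, cfg: SelectionConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Train S subject network pairs on xs (S, N, F).

    Returns (per-subject mean eval-mode scores (S, F), loss traces (S, epochs)).
    """
    n_subj, n_vox, n_feat = xs.shape
    rng = np.random.default_rng(seed)
    stack = _DualNetStack(n_subj, cfg, rng)
    k = cfg.k_selected
    traces = np.zeros((n_subj, cfg.epochs))

    for epoch in range(cfg.epochs):
        perm = np.stack([rng.permutation(n_vox) for _ in range(n_subj)])
        epoch_sse = np.zeros(n_subj)
        for start in range(0, n_vox, cfg.batch_size):
            idx = perm[:, start : start + cfg.batch_size]
            xb = xs[np.arange(n_subj)[:, None], idx]  # (S, B, F)
            stack.zero_grad()
            s, s_cache = stack.scores(xb, train=True)
            sbar = s.mean(axis=1)
            top = _topk_per_net(sbar, k)  # (S, k)
            top_b = top[:, None, :]
            x_sel = np.take_along_axis(xb, np.broadcast_to(top_b, xb.shape[:2] + (k,)), axis=2)
            s_sel = np.take_along_axis(s, np.broadcast_to(top_b, s.shape[:2] + (k,)), axis=2)
            z = x_sel * s_sel
            pred, p_cache = stack.predict(z, train=True)
            resid = pred - xb
            per_net_size = resid.shape[1] * resid.shape[2]
            epoch_sse += (resid**2).mean(axis=(1, 2)) * resid.shape[1]
            g_out = 2.0 * resid / per_net_size
            gz = stack.predict_backward(g_out, p_cache)
            gs = np.zeros_like(s)
            np.put_along_axis(
                gs, np.broadcast_to(top_b, s.shape[:2] + (k,)), gz * x_sel, axis=2
            )
            stack.scores_backward(gs, s_cache)
            stack.adam_step()
        traces[:, epoch] = epoch_sse / n_vox
    final, _ = stack.scores(xs, train=False)
    return final.mean(axis=1), traces


def train_dual_network(
    cohort, config: SelectionConfig | None = None
) -> ImportanceScores:
    """Train one scorer/predictor pair per subject and average the scores.

    ``cohort`` is a list of per-subject inputs: a ``VoxelDataset`` carrying a
    direction-resolved DW table, or an array of shape (n_voxels, 27) (a single
    27-vector is accepted as one voxel).  Subjects with equal voxel counts are
    trained in lock-step; determinism is guaranteed for a fixed seed and
    cohort.
    """
    cfg = config or SelectionConfig()
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    mats = [_subject_matrix(s, cfg.n_features_in) for s in cohort]
    ss = np.random.SeedSequence(cfg.seed)
    group_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(mats))]

    # group subjects by voxel count so each group can train as one stack
    per_subject = np.zeros((len(mats), cfg.n_features_in))
    traces: list[np.ndarray] = [None] * len(mats)  # type: ignore[list-item]
    sizes = {}
    for i, m in enumerate(mats):
        sizes.setdefault(m.shape[0], []).append(i)
    for n_vox, members in sizes.items():
        xs = np.stack([mats[i] for i in members])
        scores, trace = _train_stack(xs, cfg, group_seeds[members[0]])
        for j, i in enumerate(members):
            per_subject[i] = scores[j]
            traces[i] = trace[j]
    return ImportanceScores(
        per_subject=per_subject,
        cohort=per_subject.mean(axis=0),
        loss_traces=tuple(traces),
    )


def select_protocol(
    scores: ImportanceScores,
    config: SelectionConfig | None = None,
    scheme: AcquisitionScheme | None = None,
) -> SelectedProtocol:
    """Aggregate cohort scores per b-value and retain the top triplets.

    Scores are averaged over each b-value's direction triplet; the
    ``k_selected / n_directions`` best b-values are kept, yielding complete
    triplets (an acquirable protocol).  Ties break towards the lower b-value.
    """
    cfg = config or SelectionConfig()
    scheme = scheme or kidney_full_protocol()
    n_dir = cfg.n_directions
    cohort = np.asarray(scores.cohort, dtype=float)
    if cohort.shape != (cfg.n_features_in,):
        raise ValueError(
            f"expected {cfg.n_features_in} cohort scores, got {cohort.shape}"
        )
    n_combos = cfg.n_features_in // n_dir
    if scheme.n_combos != n_combos:
        raise ValueError(
            f"scheme has {scheme.n_combos} combos but scores imply {n_combos}"
        )
    k_combos = cfg.k_selected // n_dir
    if n_combos < k_combos:
        raise ValueError(f"fewer than {k_combos} distinct b-values available")

    per_b = cohort.reshape(n_combos, n_dir).mean(axis=1)
    # combos are ordered by ascending b, so a stable sort on the negated
    # aggregate breaks ties towards lower b
    kept_combos = np.sort(np.argsort(-per_b, kind="stable")[:k_combos])
    indices = tuple(
        int(c * n_dir + d) for c in kept_combos for d in range(n_dir)
    )
    b_values = tuple(float(scheme.b_values[c]) for c in kept_combos)
    return SelectedProtocol(measurement_indices=indices, b_values=b_values)


def reduce_scheme(
    scheme: AcquisitionScheme, selected: SelectedProtocol
) -> AcquisitionScheme:
    """Sub-scheme restricted to the selected b-values; matched b0s retained."""
    return scheme.subset(selected.b_values)
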