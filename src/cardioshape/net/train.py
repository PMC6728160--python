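"""SGD training loop for the multi-task network."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from ..core import AugmentSpec, LabelMap, LandmarkSet, Volume, augment
from ..errors import TrainingError
from .losses import dice_loss, landmark_loss, rasterise_landmarks, total_loss
from .model import NetConfig, SSLLNModel

__all__ = ["train"]


def train(
    model: SSLLNModel,
    dataset: list[tuple[Volume, LabelMap, LandmarkSet]],
    cfg: NetConfig | None = None,
    log_path: str | Path | None = None,
    augment_spec: AugmentSpec | None = None,
) -> SSLLNModel:
    """Minimise the combined Dice + balanced-cross-entropy + weight-decay
    objective with stochastic gradient descent (momentum).

    Augmentation (random in-plane translation, isotropic scale, rotation
    about one axis, intensity gain) is applied on-the-fly per iteration.
    Deterministic per ``cfg.rng_seed``.  Raises :class:`TrainingError` with
    the step index if the loss goes non-finite.

    When ``cfg.lm_probe_epoch`` is set, a held-in landmark sanity probe runs
    at that epoch; if localisation has collapsed (a known mirror-swap local
    optimum of the landmark task), training restarts from a deterministically
    derived seed (up to ``cfg.max_restarts`` times).  The returned model may
    therefore be a different object from the one passed in.
    """
    cfg = cfg or model.cfg
    for attempt in range(cfg.max_restarts + 1):
        probe = cfg.lm_probe_epoch is not None and attempt < cfg.max_restarts
        try:
            return _train_once(model, dataset, cfg, log_path, augment_spec, probe)
        except _DegenerateLandmarks:
            # re-initialise from a seed derived deterministically from the
            # original one and try again
            from dataclasses import replace as _replace

            from .model import build_network
            cfg = _replace(cfg, rng_seed=cfg.rng_seed + 101)
            model = build_network(cfg)
    raise AssertionError("unreachable")


class _DegenerateLandmarks(Exception):
    """Raised when the early probe finds landmark localisation collapsed."""


def _probe_landmarks(model, dataset, n_probe: int = 4) -> float:
    from ..metrics import landmark_error
    from .infer import predict
    errs = []
    for vol, _lab, lm in dataset[:n_probe]:
        _, plm, _ = predict(model, vol)
        e = landmark_error(plm, lm)
        if e["n_absent"] > 0 or not np.isfinite(e["mean"]):
            return float("inf")
        errs.append(e["mean"])
    return float(np.mean(errs))


def _train_once(model, dataset, cfg, log_path, augment_spec, probe=False):
    rng = np.random.default_rng(cfg.rng_seed + 1)
    velocity = [np.zeros_like(p) for p, _ in model.params()]
    second = [np.zeros_like(p) for p, _ in model.params()]  # adam second moment
    aug_spec = augment_spec or AugmentSpec(translate_vox=5.0, rotate_deg=10.0)
    log_rows = []
    step = 0
    for epoch in range(cfg.epochs):
        frac = epoch / max(cfg.epochs - 1, 1)
        lr = cfg.lr * (1.0 + (cfg.lr_decay - 1.0) * frac)
        order = rng.permutation(len(dataset))
        for bstart in range(0, len(order), cfg.batch_size):
            batch = order[bstart:bstart + cfg.batch_size]
            model.zero_grad()
            seg_l = lm_l = 0.0
            for idx in batch:
                vol, lab, lm = dataset[idx]
                if cfg.augment:
                    vol, lab, lm = augment(vol, lab, lm,
                                           rng_seed=int(rng.integers(0, 2**31 - 1)),
                                           spec=aug_spec)
                lm_grid = rasterise_landmarks(lm, lab.shape, dilation=cfg.lm_dilation)
                p_seg, p_lm = model.forward(vol.data)
                ld, gd = dice_loss(p_seg, lab.data, eps=cfg.eps, return_grad=True,
                                   per_class=cfg.dice_per_class)
                ll, gl = landmark_loss(p_lm, lm_grid, return_grad=True)
                model.backward(gd / len(batch), cfg.alpha * gl / len(batch))
                seg_l += ld / len(batch)
                lm_l += ll / len(batch)
            loss = total_loss(seg_l, lm_l, model.weights_sqnorm(), cfg.alpha, cfg.beta)
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged (non-finite) at step {step}")
            for (p, g), v, s in zip(model.params(), velocity, second):
                if p.ndim > 1:  # weight decay on kernels only
                    g = g + 2.0 * cfg.beta * p
                if cfg.optimizer == "adam":
                    v *= 0.9
                    v += 0.1 * g
                    s *= 0.999
                    s += 0.001 * g * g
                    t = step + 1
                    vhat = v / (1 - 0.9 ** t)
                    shat = s / (1 - 0.999 ** t)
                    p -= lr * vhat / (np.sqrt(shat) + 1e-8)
                else:
                    v *= cfg.momentum
                    v -= lr * g
                    p += v
            log_rows.append([step, epoch, seg_l, lm_l, loss])
            step += 1
        if probe and epoch == cfg.lm_probe_epoch - 1:
            # landmark localisation occasionally falls into a mirror-swap
            # local optimum visible early; a held-in probe catches it
            if _probe_landmarks(model, dataset) > cfg.lm_probe_threshold_mm:
                raise _DegenerateLandmarks
    if log_path is not None:
        with open(log_path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["step", "epoch", "L_D", "L_L", "total"])
            w.writerows(log_rows)
    model.train_log = log_rows
    return model
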