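"""Training objectives over q-frame predicted sequences.

Total loss  L = lambda_x * (lambda_MAE * L_MAE + L_GAN) + lambda_m * L_m with

* ``L_MAE``: mean absolute pixel error averaged over the q frames (the L1
  norm normalised per pixel and channel, which keeps ``lambda_MAE = 100`` on
  a scale comparable to the adversarial term);
* ``L_GAN``: least-squares generator term, the squared deviation of each
  frame's scalar discriminator score (mean of the patch map) from 1;
* ``L_m``: per-pixel softmax cross-entropy of the mask logits, accepting hard
  integer labels or soft probability targets (needed when pretraining on
  temporally mixed masks);
* the discriminator trains with the companion least-squares objective pushing
  real scores to 1 and generated scores to 0.

Weight defaults (lambda_x=1.5, lambda_m=1.0, lambda_MAE=100) are the
best-performing settings of the ablation sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, softmax_cross_entropy


@dataclass
class LossWeights:
    lambda_x: float = 1.5
    lambda_m: float = 1.0
    lambda_mae: float = 100.0

    def __post_init__(self):
        if min(self.lambda_x, self.lambda_m, self.lambda_mae) < 0:
            raise ValueError("loss weights must be non-negative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _frame_list(frames) -> list[Tensor]:
    if isinstance(frames, (list, tuple)):
        return [_as_tensor(f) for f in frames]
    t = _as_tensor(frames)  # leading axis = frame index
    return [t] if t.ndim == 0 else [Tensor(t.data[j]) for j in range(t.shape[0])]


def l_mae(pred, target) -> Tensor:
    """Mean over frames of the per-pixel mean absolute error."""
    preds, targets = _frame_list_pair(pred, target)
    total = None
    for pj, tj in zip(preds, targets):
        if pj.shape != tj.shape:
            raise ValueError(f"shape mismatch {pj.shape} vs {tj.shape}")
        term = (pj - tj).abs().mean()
        total = term if total is None else total + term
    return total * (1.0 / len(preds))


def _frame_list_pair(pred, target):
    preds = pred if isinstance(pred, (list, tuple)) else _frame_list(pred)
    targets = target if isinstance(target, (list, tuple)) else _frame_list(target)
    preds = [_as_tensor(p) for p in preds]
    targets = [_as_tensor(t) for t in targets]
    if len(preds) != len(targets):
        raise ValueError(f"{len(preds)} predicted vs {len(targets)} target frames")
    if not preds:
        raise ValueError("empty sequence")
    return preds, targets


def l_gan_generator(fake_scores) -> Tensor:
    """LSGAN generator term: (1/q) sum_j (Dis(x_hat_j) - 1)^2.

    Each element of ``fake_scores`` is a patch score map; its scalar score is
    the arithmetic mean of the map.
    """
    maps = fake_scores if isinstance(fake_scores, (list, tuple)) else [fake_scores]
    total = None
    for m in maps:
        term = (_as_tensor(m).mean() - 1.0) ** 2
        total = term if total is None else total + term
    return total * (1.0 / len(maps))


def l_discriminator(real_scores, fake_scores) -> Tensor:
    """LSGAN critic: (1/q) sum (Dis(x_j)-1)^2 + (1/q) sum Dis(x_hat_j)^2."""
    reals = real_scores if isinstance(real_scores, (list, tuple)) else [real_scores]
    fakes = fake_scores if isinstance(fake_scores, (list, tuple)) else [fake_scores]
    real_term = None
    for m in reals:
        term = (_as_tensor(m).mean() - 1.0) ** 2
        real_term = term if real_term is None else real_term + term
    fake_term = None
    for m in fakes:
        term = _as_tensor(m).mean() ** 2
        fake_term = term if fake_term is None else fake_term + term
    return real_term * (1.0 / len(reals)) + fake_term * (1.0 / len(fakes))


def l_mask(pred_logits, targets) -> Tensor:
    """Per-pixel cross-entropy of mask logits, averaged over pixels and frames.

    ``pred_logits``: q tensors of shape (N, C, H, W) (or one such tensor per
    frame list entry).  ``targets``: matching hard label arrays (N, H, W) or
    soft distributions (N, C, H, W); soft targets use sum_k t_k (-log p_k).
    """
    logits = pred_logits if isinstance(pred_logits, (list, tuple)) else [pred_logits]
    targs = targets if isinstance(targets, (list, tuple)) else [targets]
    if len(logits) != len(targs):
        raise ValueError(f"{len(logits)} logit frames vs {len(targs)} target frames")
    total = None
    for lg, tg in zip(logits, targs):
        lg = _as_tensor(lg)
        tg_arr = tg.data if isinstance(tg, Tensor) else np.asarray(tg)
        term = softmax_cross_entropy(lg, tg_arr, axis=1)
        total = term if total is None else total + term
    return total * (1.0 / len(logits))


def l_total(
    mae: Tensor | float,
    gan: Tensor | float,
    mask: Tensor | float,
    weights: LossWeights = LossWeights(),
) -> tuple[Tensor, dict[str, float]]:
    """Compose the full generator objective; returns (loss, breakdown)."""
    mae, gan, mask = _as_tensor(mae), _as_tensor(gan), _as_tensor(mask)
    for name, term in (("L_MAE", mae), ("L_GAN", gan), ("L_m", mask)):
        if not np.all(np.isfinite(term.data)):
            raise FloatingPointError(f"{name} is not finite")
    l_x = weights.lambda_mae * mae + gan
    total = weights.lambda_x * l_x + weights.lambda_m * mask
    breakdown = {
        "l_mae": float(mae.data),
        "l_gan": float(gan.data),
        "l_x": float(l_x.data),
        "l_mask": float(mask.data),
        "total": float(total.data),
    }
    return total, breakdown
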