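"""Training objectives: L1 latent reconstruction, hinge adversarial losses,
individualized cross-tissue L1, cycle consistency, and their weighted sum.

All L1 terms use mean reduction over both the batch and the feature
dimensions, which keeps the loss weights scale-free across gene counts.

Which networks each term updates (the training loop enforces this):
the generator adversarial term and the latent reconstruction update G and M;
the individualized and cycle terms update E and G; the discriminator hinge
term updates D only (its fake inputs are gradient-detached).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Tensor

__all__ = ["LossWeights", "recon_loss", "adv_loss_D", "adv_loss_G",
           "individualized_loss", "cycle_loss", "total_loss"]


@dataclasses.dataclass
class LossWeights:
    """Weights of the non-adversarial terms in the combined objective."""

    lambda_R: float = 1.0
    lambda_I: float = 10.0
    lambda_C: float = 1.0

    def __post_init__(self):
        for name in ("lambda_R", "lambda_I", "lambda_C"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def _l1(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a - b).abs().mean()


def recon_loss(model, c_tilde: Tensor, t) -> Tensor:
    """L1 between re-encoded generated profiles and the mapped codes:
    mean |E(G(c~|t)|t) - c~|."""
    x_fake = model.generate(c_tilde, t)
    c_back = model.encode(x_fake, t)
    return _l1(c_back, c_tilde)


def adv_loss_D(model, x_real, x_fake, t_real, t_fake=None) -> Tensor:
    """Hinge discriminator loss:
    mean max(0, 1 - D(x_real|t)) + mean max(0, 1 + D(x_fake|t)).

    ``x_fake`` must already be detached from the generator tape so the D
    update cannot alter G.
    """
    if t_fake is None:
        t_fake = t_real
    d_real = model.discriminate(x_real, t_real)
    d_fake = model.discriminate(x_fake, t_fake)
    real_term = (1.0 - d_real).relu().mean()
    fake_term = (1.0 + d_fake).relu().mean()
    return real_term + fake_term


def adv_loss_G(model, x_fake, t) -> Tensor:
    """Generator adversarial loss: -mean D(x_fake|t), gradients flowing
    through the generator."""
    return -(model.discriminate(x_fake, t).mean())


def individualized_loss(model, x_s, s, x_t, t) -> Tensor:
    """L1 between the cross-tissue prediction and the observed target
    profile of the same individual: mean |G(E(x_s|s)|t) - x_t|."""
    x_t = x_t if isinstance(x_t, Tensor) else Tensor(np.atleast_2d(x_t))
    pred = model.generate(model.encode(x_s, s), t)
    return _l1(pred, x_t.detach())


def cycle_loss(model, x_s, s, t) -> Tensor:
    """Cycle consistency: translate source -> target -> back to source and
    penalize the L1 residual, mean |G(E(G(E(x_s|s)|t)|t)|s) - x_s|."""
    x_s = x_s if isinstance(x_s, Tensor) else Tensor(np.atleast_2d(x_s))
    forward = model.generate(model.encode(x_s, s), t)
    back = model.generate(model.encode(forward, t), s)
    return _l1(back, x_s.detach())


def total_loss(adv_g, l_r, l_i, l_c, weights: LossWeights):
    """Combined generator-side objective:
    L = L_adv(G) + lambda_R L_R + lambda_I L_I + lambda_C L_C.

    Accepts Tensors (building a differentiable sum) or plain floats.
    Raises on non-finite parts, naming the offending term.
    """
    parts = {"L_adv(G)": adv_g, "L_R": l_r, "L_I": l_i, "L_C": l_c}
    for name, p in parts.items():
        v = p.item() if isinstance(p, Tensor) else float(p)
        if not np.isfinite(v):
            raise ValueError(f"non-finite loss term {name}: {v}")
    return (adv_g + weights.lambda_R * l_r + weights.lambda_I * l_i
            + weights.lambda_C * l_c)
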