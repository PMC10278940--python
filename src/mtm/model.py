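"""The four conditional networks: encoder E, generator G, discriminator D
and mapping network M, assembled from Tissue Conditioning Modules (TCM).

A TCM block is a shared fully connected layer followed by a learnable
instance-level affine transformation conditioned on the tissue label
(per-tissue scale gamma_t and shift beta_t, applied element-wise to each
sample) and a leaky ReLU.  The shared layer carries tissue-agnostic
structure; the affine pair is the only tissue-specific path, so setting all
gamma_t = 1 and beta_t = 0 makes every tissue condition produce identical
outputs.

E embeds standardized expression profiles into a shared latent space of
individualized codes; G (mirrored widths) maps codes back to tissue-specific
expression spaces; D scores profiles real-vs-generated under a tissue
condition; M maps Gaussian noise to latent codes to smooth the latent space.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._autograd import Tensor

__all__ = ["ModelConfig", "TCMBlock", "MTMModel",
           "save_model", "load_model"]

_CHECKPOINT_VERSION = 1


@dataclasses.dataclass
class ModelConfig:
    gene_dim: int
    tissues: tuple                     # vocabulary, order fixed
    latent_dim: int = 128
    encoder_widths: tuple = (512, 256)  # hidden widths; G mirrors them
    noise_dim: int = 64
    mapper_widths: tuple = (128,)
    discriminator_widths: tuple = (512, 256)
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.tissues = tuple(self.tissues)
        if len(self.tissues) != len(set(self.tissues)):
            raise ValueError("duplicate tissue labels in vocabulary")
        if self.gene_dim < 1 or self.latent_dim < 1 or self.noise_dim < 1:
            raise ValueError("dimensions must be positive")


def _init_linear(rng: np.random.Generator, n_in: int, n_out: int):
    """Fan-in scaled normal initialization."""
    w = rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)
    b = np.zeros(n_out)
    return Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)


class Linear:
    def __init__(self, rng, n_in, n_out):
        self.W, self.b = _init_linear(rng, n_in, n_out)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class TCMBlock:
    """Shared dense layer + per-tissue affine + leaky ReLU."""

    def __init__(self, rng, n_in, n_out, n_tissues, slope=0.2,
                 activation=True):
        self.linear = Linear(rng, n_in, n_out)
        # identity affine at init: gamma=1, beta=0
        self.gamma = Tensor(np.ones((n_tissues, n_out)), requires_grad=True)
        self.beta = Tensor(np.zeros((n_tissues, n_out)), requires_grad=True)
        self.slope = slope
        self.activation = activation

    def __call__(self, x: Tensor, tissue_idx: np.ndarray) -> Tensor:
        h = self.linear(x)
        g = self.gamma.gather_rows(tissue_idx)
        b = self.beta.gather_rows(tissue_idx)
        h = h * g + b
        if self.activation:
            h = h.leaky_relu(self.slope)
        return h

    def parameters(self):
        return self.linear.parameters() + [self.gamma, self.beta]


class DenseBlock:
    """Unconditioned dense layer + optional leaky ReLU (used by M)."""

    def __init__(self, rng, n_in, n_out, slope=0.2, activation=True):
        self.linear = Linear(rng, n_in, n_out)
        self.slope = slope
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        h = self.linear(x)
        if self.activation:
            h = h.leaky_relu(self.slope)
        return h

    def parameters(self):
        return self.linear.parameters()


class MTMModel:
    """Encoder, generator, discriminator and mapping network.

    Generator widths are the reverse of the encoder's; the generator's and
    discriminator's final layers are plain linear maps (no affine, no
    activation) into gene space / a scalar score.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        nt = len(config.tissues)
        slope = config.leaky_slope
        self._tissue_index = {t: i for i, t in enumerate(config.tissues)}

        # encoder: gene_dim -> hidden... -> latent, all TCM blocks
        dims = [config.gene_dim, *config.encoder_widths, config.latent_dim]
        self.encoder = [TCMBlock(rng, dims[i], dims[i + 1], nt, slope)
                        for i in range(len(dims) - 1)]
        # generator: latent -> reversed hidden -> gene_dim; final layer linear
        gdims = [config.latent_dim, *reversed(config.encoder_widths)]
        self.generator = [TCMBlock(rng, gdims[i], gdims[i + 1], nt, slope)
                          for i in range(len(gdims) - 1)]
        self.generator_out = Linear(rng, gdims[-1], config.gene_dim)
        # discriminator: gene_dim -> hidden -> scalar; final layer linear
        ddims = [config.gene_dim, *config.discriminator_widths]
        self.discriminator = [TCMBlock(rng, ddims[i], ddims[i + 1], nt, slope)
                              for i in range(len(ddims) - 1)]
        self.discriminator_out = Linear(rng, ddims[-1], 1)
        # mapping network: unconditioned dense stack, linear final layer
        mdims = [config.noise_dim, *config.mapper_widths, config.latent_dim]
        self.mapper = [DenseBlock(rng, mdims[i], mdims[i + 1], slope,
                                  activation=(i < len(mdims) - 2))
                       for i in range(len(mdims) - 1)]

    # -- parameter groups --------------------------------------------------

    def encoder_parameters(self):
        return [p for blk in self.encoder for p in blk.parameters()]

    def generator_parameters(self):
        return ([p for blk in self.generator for p in blk.parameters()]
                + self.generator_out.parameters())

    def discriminator_parameters(self):
        return ([p for blk in self.discriminator for p in blk.parameters()]
                + self.discriminator_out.parameters())

    def mapper_parameters(self):
        return [p for blk in self.mapper for p in blk.parameters()]

    def parameters(self):
        return (self.encoder_parameters() + self.generator_parameters()
                + self.discriminator_parameters() + self.mapper_parameters())

    # -- forward passes ----------------------------------------------------

    def tissue_indices(self, labels) -> np.ndarray:
        try:
            return np.asarray([self._tissue_index[t] for t in labels],
                              dtype=np.intp)
        except KeyError as exc:
            raise ValueError(
                f"unknown tissue label {exc.args[0]!r}; declared tissues: "
                f"{list(self.config.tissues)}") from None

    def _as_tensor(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        return x

    def encode(self, x, s) -> Tensor:
        """Embed profiles x (batch × gene_dim) under source tissues s."""
        x = self._as_tensor(x)
        if x.shape[1] != self.config.gene_dim:
            raise ValueError(f"expected {self.config.gene_dim} genes, "
                             f"got {x.shape[1]}")
        idx = self.tissue_indices(s)
        h = x
        for blk in self.encoder:
            h = blk(h, idx)
        return h

    def generate(self, c, t) -> Tensor:
        """Map latent codes c to standardized profiles of target tissues t."""
        c = self._as_tensor(c)
        if c.shape[1] != self.config.latent_dim:
            raise ValueError(f"expected latent dim {self.config.latent_dim}, "
                             f"got {c.shape[1]}")
        idx = self.tissue_indices(t)
        h = c
        for blk in self.generator:
            h = blk(h, idx)
        return self.generator_out(h)

    def discriminate(self, x, t) -> Tensor:
        """Real-vs-generated score (unbounded real, one per sample)."""
        x = self._as_tensor(x)
        idx = self.tissue_indices(t)
        h = x
        for blk in self.discriminator:
            h = blk(h, idx)
        return self.discriminator_out(h)

    def map_noise(self, z) -> Tensor:
        """Transform Gaussian noise into latent codes."""
        z = self._as_tensor(z)
        if z.shape[1] != self.config.noise_dim:
            raise ValueError(f"expected noise dim {self.config.noise_dim}, "
                             f"got {z.shape[1]}")
        h = z
        for blk in self.mapper:
            h = blk(h)
        return h

    def collect_activations(self, c, t) -> list:
        """Per-layer generator activations (the decoding path).

        The last element equals ``generate(c, t)`` exactly.
        """
        c = self._as_tensor(c)
        idx = self.tissue_indices(t)
        h = c
        acts = []
        for blk in self.generator:
            h = blk(h, idx)
            acts.append(h.data.copy())
        h = self.generator_out(h)
        acts.append(h.data.copy())
        return acts


# ---------------------------------------------------------------------------
# checkpointing: a single JSON file (float64 round-trips exactly through
# repr-precision JSON floats), holding weights, config and the tissue
# vocabulary; the fitted TissueScalers frame may be embedded for
# de-standardization at prediction time.


def _weights_doc(model: MTMModel) -> list:
    return [p.data.tolist() for p in model.parameters()]


def save_model(model: MTMModel, path, scalers=None) -> None:
    doc = {
        "version": _CHECKPOINT_VERSION,
        "config": {**dataclasses.asdict(model.config),
                   "tissues": list(model.config.tissues),
                   "encoder_widths": list(model.config.encoder_widths),
                   "mapper_widths": list(model.config.mapper_widths),
                   "discriminator_widths":
                       list(model.config.discriminator_widths)},
        "weights": _weights_doc(model),
    }
    if scalers is not None:
        doc["scalers"] = {
            "ddof": scalers.ddof,
            "tissues": list(scalers.means.index),
            "genes": list(scalers.means.columns),
            "means": scalers.means.to_numpy().tolist(),
            "sds": scalers.sds.to_numpy().tolist(),
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    """Load a checkpoint; returns (model, scalers-or-None)."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise ValueError(f"unreadable checkpoint {path}: {exc}")
    if doc.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version "
                         f"{doc.get('version')!r}")
    cfg = doc["config"]
    cfg["tissues"] = tuple(cfg["tissues"])
    cfg["encoder_widths"] = tuple(cfg["encoder_widths"])
    cfg["mapper_widths"] = tuple(cfg["mapper_widths"])
    cfg["discriminator_widths"] = tuple(cfg["discriminator_widths"])
    model = MTMModel(ModelConfig(**cfg))
    params = model.parameters()
    if len(doc["weights"]) != len(params):
        raise ValueError("checkpoint weight count does not match "
                         "architecture")
    for p, w in zip(params, doc["weights"]):
        arr = np.asarray(w, dtype=np.float64)
        if arr.shape != p.data.shape:
            raise ValueError(f"weight shape mismatch: {arr.shape} vs "
                             f"{p.data.shape}")
        p.data = arr
    scalers = None
    if "scalers" in doc:
        import pandas as pd
        from .preprocessing import TissueScalers
        s = doc["scalers"]
        scalers = TissueScalers(
            means=pd.DataFrame(s["means"], index=s["tissues"],
                               columns=s["genes"]),
            sds=pd.DataFrame(s["sds"], index=s["tissues"],
                             columns=s["genes"]),
            ddof=s["ddof"])
    return model, scalers
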