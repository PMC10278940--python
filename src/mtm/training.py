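"""End-to-end training: the multi-task model, a per-tissue MLP baseline, and
simplified linear baselines (per-gene Bayesian ridge, LASSO on principal
components).

Training data are organized as ordered tissue pairs within the same
individual: one sample is the input, the other the prediction target, both
directions included, so the model learns the mapping between any two tissue
types.  Each optimization step updates the discriminator on the hinge loss
(with gradient-detached fakes), then the generator side on the combined
objective, with terms routed to the networks they update: the adversarial
generator term and the latent reconstruction to G and M, the individualized
and cycle terms to E and G.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import BayesianRidge, Lasso

from ._autograd import Adam, Tensor
from .model import DenseBlock, Linear, ModelConfig, MTMModel
from .objectives import (LossWeights, adv_loss_D, adv_loss_G, cycle_loss,
                         individualized_loss, recon_loss)
from .preprocessing import (apply_scalers, build_tissue_pairs, fit_scalers,
                            inverse_scalers, log_transform)

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "train_mtm", "predict",
           "train_s3_baseline", "predict_s3",
           "train_linear_baselines", "predict_linear",
           "standardize_cohort"]


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 256
    max_epochs: int = 200
    learning_rate: float = 5e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    seed: int = 0
    d_steps_per_g_step: int = 1
    validation_every: int = 10
    adv_weight: float = 1.0   # scales both adversarial terms; 0 disables GAN

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        for b in (self.adam_beta1, self.adam_beta2):
            if not (0.0 <= b < 1.0):
                raise ValueError("Adam betas must be in [0, 1)")


def standardize_cohort(expr: pd.DataFrame, meta: pd.DataFrame,
                       train_individuals, log: bool = True,
                       pseudocount: float = 1.0):
    """Default preprocessing pipeline: log2(TPM+1) then per-tissue Z-score
    with scalers fitted on training individuals only.

    With ``log=False`` the Z-scoring is applied to the raw values.
    Returns (standardized expression, fitted TissueScalers).
    """
    work = log_transform(expr, pseudocount) if log else expr
    scalers = fit_scalers(work, meta, train_individuals)
    return apply_scalers(work, meta, scalers), scalers


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _check_finite(name: str, value: float, step: int) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite loss {name}={value} at step {step}")


def _snapshot(model: MTMModel) -> list:
    return [p.data.copy() for p in model.parameters()]


def _restore(model: MTMModel, snap: list) -> None:
    for p, w in zip(model.parameters(), snap):
        p.data = w.copy()


def _mean_val_li(model, expr_std, pairs) -> float:
    """Validation individualized L1, computed without building a tape."""
    if pairs.empty:
        return np.nan
    xs = Tensor(expr_std.loc[pairs["source_sample"]].to_numpy())
    xt = expr_std.loc[pairs["target_sample"]].to_numpy()
    pred = model.generate(model.encode(xs, pairs["source_tissue"]),
                          pairs["target_tissue"])
    return float(np.abs(pred.data - xt).mean())


def train_mtm(expr_std: pd.DataFrame, meta: pd.DataFrame,
              train_individuals, val_individuals=None,
              model_config: ModelConfig | None = None,
              train_config: TrainConfig | None = None):
    """Train the multi-task model on standardized expression.

    Returns (model, history DataFrame).  The model keeps its last-epoch
    weights; the best-validation weights (by the individualized L1 on the
    validation pairs) are restored when validation individuals are given.
    """
    cfg = train_config or TrainConfig()
    tissues = tuple(sorted(meta["tissue"].unique()))
    if model_config is None:
        model_config = ModelConfig(gene_dim=expr_std.shape[1],
                                   tissues=tissues, seed=cfg.seed)
    model = MTMModel(model_config)
    pairs = build_tissue_pairs(meta, train_individuals)
    if pairs.empty:
        raise ValueError("empty tissue-pair set; check the training split")
    val_pairs = (build_tissue_pairs(meta, val_individuals)
                 if val_individuals is not None else pd.DataFrame())

    rng = np.random.default_rng(cfg.seed)
    betas = dict(beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    opt_d = Adam(model.discriminator_parameters(),
                 lr=cfg.learning_rate, **betas)
    egm_params = (model.encoder_parameters() + model.generator_parameters()
                  + model.mapper_parameters())
    opt_egm = Adam(egm_params, lr=cfg.learning_rate, **betas)

    w = cfg.weights
    history = []
    best_val, best_snap = np.inf, None
    step = 0
    src = expr_std.to_numpy()
    row_of = {s: i for i, s in enumerate(expr_std.index)}
    src_rows = pairs["source_sample"].map(row_of).to_numpy()
    tgt_rows = pairs["target_sample"].map(row_of).to_numpy()
    s_labels = pairs["source_tissue"].to_numpy()
    t_labels = pairs["target_tissue"].to_numpy()

    for epoch in range(cfg.max_epochs):
        for idx in _batches(len(pairs), cfg.batch_size, rng):
            x_s = Tensor(src[src_rows[idx]])
            x_t = Tensor(src[tgt_rows[idx]])
            s = s_labels[idx]
            t = t_labels[idx]
            z = rng.standard_normal((len(idx), model_config.noise_dim))

            # --- discriminator update(s): hinge loss, detached fakes
            l_adv_d = np.nan
            if cfg.adv_weight > 0:
                for _ in range(cfg.d_steps_per_g_step):
                    with np.errstate(over="raise"):
                        fake = model.generate(model.map_noise(Tensor(z)), t)
                        loss_d = adv_loss_D(model, x_t, fake.detach(), t)
                    l_adv_d = loss_d.item()
                    _check_finite("L_adv(D)", l_adv_d, step)
                    loss_d.backward()
                    opt_d.step()
                    opt_d.zero_grad()
                    for p in model.parameters():
                        p.grad = None

            # --- generator-side update
            # pass 1: adversarial + latent reconstruction -> G and M
            c_tilde = model.map_noise(Tensor(z))
            x_fake = model.generate(c_tilde, t)
            if cfg.adv_weight > 0:
                l_adv_g_t = adv_loss_G(model, x_fake, t)
                l_adv_g = l_adv_g_t.item()
            else:
                l_adv_g_t, l_adv_g = None, 0.0
            l_r_t = recon_loss(model, c_tilde, t)
            l_r = l_r_t.item()
            _check_finite("L_R", l_r, step)
            pass1 = w.lambda_R * l_r_t
            if l_adv_g_t is not None:
                _check_finite("L_adv(G)", l_adv_g, step)
                pass1 = pass1 + cfg.adv_weight * l_adv_g_t
            pass1.backward()
            # the reconstruction path crosses E, but only G and M own it
            for p in model.encoder_parameters():
                p.grad = None
            # pass 2: individualized + cycle -> E and G
            l_i_t = individualized_loss(model, x_s, s, x_t, t)
            l_c_t = cycle_loss(model, x_s, s, t)
            l_i, l_c = l_i_t.item(), l_c_t.item()
            _check_finite("L_I", l_i, step)
            _check_finite("L_C", l_c, step)
            (w.lambda_I * l_i_t + w.lambda_C * l_c_t).backward()
            opt_egm.step()
            opt_egm.zero_grad()
            for p in model.parameters():
                p.grad = None

            total = (cfg.adv_weight * l_adv_g + w.lambda_R * l_r
                     + w.lambda_I * l_i + w.lambda_C * l_c)
            history.append((step, epoch, l_adv_d, l_adv_g, l_r, l_i, l_c,
                            total, np.nan))
            step += 1

        if (not val_pairs.empty
                and (epoch + 1) % max(cfg.validation_every, 1) == 0):
            val_li = _mean_val_li(model, expr_std, val_pairs)
            history[-1] = history[-1][:-1] + (val_li,)
            if val_li < best_val:
                best_val, best_snap = val_li, _snapshot(model)

    if best_snap is not None:
        _restore(model, best_snap)
    hist = pd.DataFrame(history, columns=["step", "epoch", "L_adv_D",
                                          "L_adv_G", "L_R", "L_I", "L_C",
                                          "total", "val_L_I"])
    return model, hist


def predict(model: MTMModel, scalers, expr_source: pd.DataFrame,
            meta_source: pd.DataFrame, target_tissue: str,
            log: bool = True, destandardize: bool = False) -> pd.DataFrame:
    """Predict target-tissue profiles for each source sample.

    The source expression is given on the raw (TPM-like) scale; it is passed
    through the same transform the scalers were fitted on (log2(TPM+1) by
    default), standardized with the source tissue's recorded factors, encoded,
    and generated under the target tissue condition.  The output is in
    standardized space unless ``destandardize`` is set, in which case the
    target tissue's scalers are inverted.
    """
    if target_tissue not in model.config.tissues:
        raise ValueError(f"target tissue {target_tissue!r} not in model "
                         f"vocabulary {list(model.config.tissues)}")
    work = log_transform(expr_source) if log else expr_source
    x_std = apply_scalers(work, meta_source, scalers)
    s = meta_source.loc[x_std.index, "tissue"].to_numpy()
    codes = model.encode(Tensor(x_std.to_numpy()), s)
    pred = model.generate(codes, np.full(len(x_std), target_tissue))
    out = pd.DataFrame(pred.data, index=x_std.index, columns=x_std.columns)
    if destandardize:
        out = inverse_scalers(out, target_tissue, scalers)
    return out


# ---------------------------------------------------------------------------
# baseline S3: one independent MLP per target tissue, L1 loss


class _MLP:
    """Plain dense network with leaky ReLU hidden layers (linear output)."""

    def __init__(self, rng, dims, slope=0.2):
        self.blocks = [DenseBlock(rng, dims[i], dims[i + 1], slope)
                       for i in range(len(dims) - 2)]
        self.out = Linear(rng, dims[-2], dims[-1])

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for blk in self.blocks:
            h = blk(h)
        return self.out(h)

    def parameters(self):
        return [p for blk in self.blocks
                for p in blk.parameters()] + self.out.parameters()


@dataclasses.dataclass
class S3Config:
    hidden_widths: tuple = (256,)
    max_epochs: int = 1000
    batch_size: int = 256
    learning_rate: float = 5e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    seed: int = 0


def _paired_matrix(expr_std, meta, individuals, source_tissue, target_tissue):
    """Source/target row pairs for individuals sampled in both tissues."""
    sub = meta[meta["individual_id"].isin(set(individuals))]
    by_ind = {}
    for sample, row in sub.iterrows():
        by_ind.setdefault(row["individual_id"], {})[row["tissue"]] = sample
    xs, xt, inds = [], [], []
    for ind, tmap in sorted(by_ind.items()):
        if source_tissue in tmap and target_tissue in tmap:
            xs.append(expr_std.loc[tmap[source_tissue]].to_numpy())
            xt.append(expr_std.loc[tmap[target_tissue]].to_numpy())
            inds.append(ind)
    if not xs:
        return None, None, []
    return np.asarray(xs), np.asarray(xt), inds


def train_s3_baseline(expr_std: pd.DataFrame, meta: pd.DataFrame,
                      train_individuals, source_tissue: str,
                      config: S3Config | None = None) -> dict:
    """Train one MLP per target tissue (source tissue excluded)."""
    cfg = config or S3Config()
    tissues = sorted(meta["tissue"].unique())
    n_genes = expr_std.shape[1]
    models = {}
    for target in tissues:
        if target == source_tissue:
            continue
        xs, xt, inds = _paired_matrix(expr_std, meta, train_individuals,
                                      source_tissue, target)
        if xs is None or len(inds) < 2:
            logger.warning("S3: skipping tissue %s (<2 paired training "
                           "individuals)", target)
            continue
        rng = np.random.default_rng(cfg.seed)
        net = _MLP(rng, [n_genes, *cfg.hidden_widths, n_genes])
        opt = Adam(net.parameters(), lr=cfg.learning_rate,
                   beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        for _ in range(cfg.max_epochs):
            for idx in _batches(len(xs), cfg.batch_size, rng):
                pred = net(Tensor(xs[idx]))
                loss = (pred - Tensor(xt[idx])).abs().mean()
                loss.backward()
                opt.step()
                opt.zero_grad()
        models[target] = net
    return models


def predict_s3(models: dict, expr_source_std: pd.DataFrame,
               target_tissue: str) -> pd.DataFrame:
    net = models[target_tissue]
    pred = net(Tensor(expr_source_std.to_numpy()))
    return pd.DataFrame(pred.data, index=expr_source_std.index,
                        columns=expr_source_std.columns)


# ---------------------------------------------------------------------------
# simplified linear baselines


@dataclasses.dataclass
class LinearBaselineConfig:
    variant: str = "ridge-per-gene"   # or "lasso-on-pcs"
    top_k_features: int = 20          # ridge: source genes by |corr|
    n_components: int = 10            # lasso: leading PCs of source data
    lasso_alpha: float = 0.01
    seed: int = 0


def train_linear_baselines(expr_std: pd.DataFrame, meta: pd.DataFrame,
                           train_individuals, source_tissue: str,
                           config: LinearBaselineConfig | None = None) -> dict:
    """Per-tissue linear predictors fitted on training individuals only.

    "ridge-per-gene": Bayesian ridge per target gene on the top-k most
    correlated source genes.  "lasso-on-pcs": LASSO per target gene on the
    leading principal components of the source expression (PCA fitted on
    training samples; validation data are only ever projected).
    """
    cfg = config or LinearBaselineConfig()
    if cfg.variant not in ("ridge-per-gene", "lasso-on-pcs"):
        raise ValueError(f"unknown variant {cfg.variant!r}")
    tissues = sorted(meta["tissue"].unique())
    out = {"config": cfg}
    for target in tissues:
        if target == source_tissue:
            continue
        xs, xt, inds = _paired_matrix(expr_std, meta, train_individuals,
                                      source_tissue, target)
        if xs is None or len(inds) < 2:
            continue
        if cfg.variant == "lasso-on-pcs":
            n_comp = min(cfg.n_components, len(inds) - 1, xs.shape[1])
            pca = PCA(n_components=n_comp, random_state=cfg.seed)
            feats = pca.fit_transform(xs)
            fits = []
            for j in range(xt.shape[1]):
                y = xt[:, j]
                if np.allclose(y, y[0]):
                    fits.append(("const", float(y[0])))
                    continue
                m = Lasso(alpha=cfg.lasso_alpha, max_iter=5000)
                m.fit(feats, y)
                fits.append(("model", m))
            out[target] = {"kind": "lasso", "pca": pca, "fits": fits}
        else:
            xs_c = xs - xs.mean(axis=0)
            xt_c = xt - xt.mean(axis=0)
            xs_sd = xs.std(axis=0)
            xt_sd = xt.std(axis=0)
            denom = np.outer(xt_sd, xs_sd)
            denom[denom == 0] = np.inf
            corr = (xt_c.T @ xs_c) / len(xs) / denom
            fits = []
            k = min(cfg.top_k_features, xs.shape[1])
            for j in range(xt.shape[1]):
                y = xt[:, j]
                if np.allclose(y, y[0]):
                    fits.append(("const", float(y[0]), None))
                    continue
                top = np.argsort(-np.abs(corr[j]))[:k]
                m = BayesianRidge()
                m.fit(xs[:, top], y)
                fits.append(("model", m, top))
            out[target] = {"kind": "ridge", "fits": fits}
    return out


def predict_linear(models: dict, expr_source_std: pd.DataFrame,
                   target_tissue: str) -> pd.DataFrame:
    entry = models[target_tissue]
    X = expr_source_std.to_numpy()
    n = len(X)
    pred = np.zeros((n, expr_source_std.shape[1]))
    if entry["kind"] == "lasso":
        feats = entry["pca"].transform(X)
        for j, fit in enumerate(entry["fits"]):
            if fit[0] == "const":
                pred[:, j] = fit[1]
            else:
                pred[:, j] = fit[1].predict(feats)
    else:
        for j, fit in enumerate(entry["fits"]):
            if fit[0] == "const":
                pred[:, j] = fit[1]
            else:
                pred[:, j] = fit[1].predict(X[:, fit[2]])
    return pd.DataFrame(pred, index=expr_source_std.index,
                        columns=expr_source_std.columns)
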