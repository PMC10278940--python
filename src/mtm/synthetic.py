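"""Synthetic multi-tissue, multi-individual expression cohorts.

The generator emulates the statistical structure that cross-tissue expression
prediction relies on: every individual carries a latent vector that is shared
across all of their tissues (a static, genetics-like part plus a dynamic,
physiological-state part), and each tissue maps that vector into gene space
through its own loading matrix and intercept.  Gaussian noise is added on the
log-expression scale and a monotone transform produces non-negative TPM-like
values.  Trait-correlated genes and case/control dysregulated genes are
planted with known effect sizes so downstream analyses can be checked against
ground truth.

Generative model, per individual ``i`` and tissue ``k``::

    u_i ~ N(0, I)                          latent (static ⊕ dynamic)
    A_k = r_k * A_common + sqrt(1 - r_k^2) * A_k_own   loadings
    s_ik = A_k @ u_i + b_k + effects + noise           log2-scale signal
    TPM  = 2 ** (s_ik / tau)               ("exp" transform, default)

``r_k`` interpolates each tissue's loadings toward a shared matrix, which
induces a ground-truth tissue-similarity ordering.  With the "shifted-linear"
transform the signal is instead shifted to be non-negative and used directly,
giving a cohort that is exactly linear in the latent factors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort",
           "resample_expression", "write_cohort", "read_cohort"]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Counts must be positive, ``noise_sd`` strictly positive, and the planted
    gene sets must fit: ``n_trait_genes + n_deg <= n_genes``.
    """

    n_individuals: int = 60
    n_tissues: int = 4
    n_genes: int = 200
    latent_dim_static: int = 5
    latent_dim_dynamic: int = 3
    noise_sd: float = 1.0
    tissue_mean_scale: float = 2.0
    missing_rate: float = 0.0
    n_trait_genes: int = 20
    trait_effect: float = 1.0
    n_deg: int = 20
    deg_log2fc: float = 2.0
    case_fraction: float = 0.4
    seed: int = 0
    # shape of the non-negativity transform
    transform: str = "exp"          # "exp" or "shifted-linear"
    tau: float = 1.0                # TPM = 2**(signal/tau) for "exp"
    baseline_log_mean: float = 3.0  # mean of tissue intercepts (log2 TPM)
    loading_scale: float = 1.0      # sd of loading entries
    tissue_corr: tuple | None = None  # per-tissue r_k; default linspace(0.9, 0.1)

    def __post_init__(self):
        for field in ("n_individuals", "n_tissues", "n_genes",
                      "n_trait_genes", "n_deg"):
            if getattr(self, field) < 0 or (
                    field in ("n_individuals", "n_tissues", "n_genes")
                    and getattr(self, field) <= 0):
                raise ValueError(f"{field} must be positive, got "
                                 f"{getattr(self, field)}")
        if self.latent_dim_static < 0 or self.latent_dim_dynamic < 0:
            raise ValueError("latent dimensions must be non-negative")
        if self.latent_dim_static + self.latent_dim_dynamic < 1:
            raise ValueError("latent_dim_static + latent_dim_dynamic must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1), got "
                             f"{self.missing_rate}")
        if not (0.0 <= self.case_fraction <= 1.0):
            raise ValueError(f"case_fraction must be in [0, 1], got "
                             f"{self.case_fraction}")
        if self.n_trait_genes + self.n_deg > self.n_genes:
            raise ValueError("n_trait_genes + n_deg exceeds n_genes")
        if self.transform not in ("exp", "shifted-linear"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.n_tissues >= 2 and self.n_individuals < 1:
            raise ValueError("need at least one individual")


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort, kept for verification."""

    latents: pd.DataFrame            # individuals × latent dims
    loadings: dict                   # tissue -> (n_genes, latent_dim) array
    intercepts: dict                 # tissue -> (n_genes,) array
    trait_genes: list                # gene ids with planted trait effect
    deg_genes: dict                  # tissue -> list of planted DEG gene ids
    deg_direction: dict              # tissue -> {gene id: +1/-1}
    tissue_corr: dict                # tissue -> r_k used for its loadings


@dataclasses.dataclass
class SyntheticCohort:
    expression: pd.DataFrame         # samples × genes, TPM-like
    metadata: pd.DataFrame           # sample_id index; individual_id, tissue
    traits: pd.DataFrame             # individual_id index; trait, disease
    truth: SimulationTruth
    config: SimulationConfig

    def signal(self, sample_id: str) -> np.ndarray:
        """Noise-free linear predictor ``A_k @ u_i + b_k`` for a sample."""
        ind = self.metadata.loc[sample_id, "individual_id"]
        tissue = self.metadata.loc[sample_id, "tissue"]
        u = self.truth.latents.loc[ind].to_numpy()
        return self.truth.loadings[tissue] @ u + self.truth.intercepts[tissue]


def _tissue_names(n: int) -> list:
    return ["blood"] + [f"tissue_{k}" for k in range(1, n)]


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort from the generative model, deterministically."""
    rng = np.random.default_rng(config.seed)
    L = config.latent_dim_static + config.latent_dim_dynamic
    tissues = _tissue_names(config.n_tissues)
    individuals = [f"IND{i:04d}" for i in range(config.n_individuals)]
    genes = [f"G{j:04d}" for j in range(config.n_genes)]

    # latent vectors, shared across tissues of the same individual
    U = rng.standard_normal((config.n_individuals, L))
    latents = pd.DataFrame(U, index=individuals,
                           columns=[f"u{d}" for d in range(L)])

    # tissue loadings: interpolate toward a common matrix to induce a
    # ground-truth similarity ordering between tissues
    if config.tissue_corr is None:
        corr = np.linspace(0.9, 0.1, config.n_tissues)
    else:
        corr = np.asarray(config.tissue_corr, dtype=float)
        if corr.shape != (config.n_tissues,):
            raise ValueError("tissue_corr must have one entry per tissue")
    A_common = rng.standard_normal((config.n_genes, L)) * config.loading_scale
    loadings, intercepts, tissue_corr = {}, {}, {}
    for k, t in enumerate(tissues):
        own = rng.standard_normal((config.n_genes, L)) * config.loading_scale
        r = corr[k]
        loadings[t] = r * A_common + np.sqrt(1.0 - r * r) * own
        intercepts[t] = (config.baseline_log_mean
                         + rng.standard_normal(config.n_genes)
                         * config.tissue_mean_scale)
        tissue_corr[t] = float(r)

    # traits: age-like continuous (z-scaled) and a binary disease flag
    trait = rng.standard_normal(config.n_individuals)
    disease = (rng.random(config.n_individuals)
               < config.case_fraction).astype(int)
    traits = pd.DataFrame({"trait": trait, "disease": disease},
                          index=pd.Index(individuals, name="individual_id"))

    # planted gene sets: trait genes first, DEGs drawn per tissue from the rest
    trait_idx = np.arange(config.n_trait_genes)
    deg_pool = np.arange(config.n_trait_genes, config.n_genes)
    trait_genes = [genes[j] for j in trait_idx]
    deg_genes, deg_direction = {}, {}
    for t in tissues:
        chosen = rng.choice(deg_pool, size=config.n_deg, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.n_deg)
        deg_genes[t] = [genes[j] for j in chosen]
        deg_direction[t] = {genes[j]: float(s)
                            for j, s in zip(chosen, signs)}

    # assemble samples, honoring missingness but keeping >= 2 per individual
    keep = rng.random((config.n_individuals, config.n_tissues)) >= config.missing_rate
    for i in range(config.n_individuals):
        if keep[i].sum() < 2:
            forced = rng.choice(config.n_tissues, size=2, replace=False)
            keep[i, forced] = True

    sample_ids, meta_rows = [], []
    for i, ind in enumerate(individuals):
        for k, t in enumerate(tissues):
            if keep[i, k]:
                sample_ids.append(f"{ind}-{t}")
                meta_rows.append((ind, t))
    metadata = pd.DataFrame(meta_rows,
                            index=pd.Index(sample_ids, name="sample_id"),
                            columns=["individual_id", "tissue"])
    truth = SimulationTruth(latents=latents, loadings=loadings,
                            intercepts=intercepts, trait_genes=trait_genes,
                            deg_genes=deg_genes, deg_direction=deg_direction,
                            tissue_corr=tissue_corr)
    expression = _draw_expression(truth, metadata, traits, config, rng, genes)
    return SyntheticCohort(expression=expression, metadata=metadata,
                           traits=traits, truth=truth, config=config)


def _draw_expression(truth: SimulationTruth, metadata: pd.DataFrame,
                     traits: pd.DataFrame, config: SimulationConfig,
                     rng: np.random.Generator, genes: list) -> pd.DataFrame:
    """Noise-free signals from the truth plus fresh Gaussian noise, mapped
    through the configured non-negativity transform."""
    gene_pos = {g: j for j, g in enumerate(genes)}
    n_trait = len(truth.trait_genes)
    rows = []
    for sample_id, (ind, t) in metadata.iterrows():
        u = truth.latents.loc[ind].to_numpy()
        signal = truth.loadings[t] @ u + truth.intercepts[t]
        if n_trait:
            signal[:n_trait] += (config.trait_effect
                                 * traits.loc[ind, "trait"])
        if traits.loc[ind, "disease"]:
            for g, s in truth.deg_direction[t].items():
                signal[gene_pos[g]] += s * config.deg_log2fc
        signal += rng.standard_normal(config.n_genes) * config.noise_sd
        rows.append(signal)
    signal_mat = np.asarray(rows)
    if config.transform == "exp":
        values = np.power(2.0, signal_mat / config.tau)
    else:  # shifted-linear: shift each gene so the minimum is non-negative
        shift = np.minimum(signal_mat.min(axis=0), 0.0)
        values = signal_mat - shift
    return pd.DataFrame(values, index=metadata.index, columns=genes)


def resample_expression(cohort: SyntheticCohort, seed: int) -> SyntheticCohort:
    """A second expression realization: same truth, metadata and traits,
    fresh measurement noise.  Useful as an independent replicate when
    checking that planted signals are recoverable."""
    rng = np.random.default_rng(seed)
    genes = list(cohort.expression.columns)
    expression = _draw_expression(cohort.truth, cohort.metadata,
                                  cohort.traits, cohort.config, rng, genes)
    return SyntheticCohort(expression=expression, metadata=cohort.metadata,
                           traits=cohort.traits, truth=cohort.truth,
                           config=cohort.config)


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write a cohort as TSV files plus a JSON truth file.

    Returns the mapping of logical name -> written path.
    """
    if directory is None or str(directory) == "":
        raise ValueError("directory must be a non-empty path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "metadata": directory / "metadata.tsv",
        "traits": directory / "traits.tsv",
        "truth": directory / "truth.json",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t")
    cohort.metadata.to_csv(paths["metadata"], sep="\t")
    cohort.traits.to_csv(paths["traits"], sep="\t")
    t = cohort.truth
    truth_doc = {
        "latents": {"index": list(t.latents.index),
                    "columns": list(t.latents.columns),
                    "values": t.latents.to_numpy().tolist()},
        "loadings": {k: v.tolist() for k, v in t.loadings.items()},
        "intercepts": {k: v.tolist() for k, v in t.intercepts.items()},
        "trait_genes": t.trait_genes,
        "deg_genes": t.deg_genes,
        "deg_direction": t.deg_direction,
        "tissue_corr": t.tissue_corr,
        "config": dataclasses.asdict(cohort.config),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh)
    return paths


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    expression = pd.read_csv(directory / "expression.tsv", sep="\t",
                             index_col=0)
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t", index_col=0)
    traits = pd.read_csv(directory / "traits.tsv", sep="\t", index_col=0)
    with open(directory / "truth.json") as fh:
        doc = json.load(fh)
    cfg_doc = doc["config"]
    if cfg_doc.get("tissue_corr") is not None:
        cfg_doc["tissue_corr"] = tuple(cfg_doc["tissue_corr"])
    config = SimulationConfig(**cfg_doc)
    truth = SimulationTruth(
        latents=pd.DataFrame(doc["latents"]["values"],
                             index=doc["latents"]["index"],
                             columns=doc["latents"]["columns"]),
        loadings={k: np.asarray(v) for k, v in doc["loadings"].items()},
        intercepts={k: np.asarray(v) for k, v in doc["intercepts"].items()},
        trait_genes=doc["trait_genes"],
        deg_genes=doc["deg_genes"],
        deg_direction={k: {g: float(s) for g, s in v.items()}
                       for k, v in doc["deg_direction"].items()},
        tissue_corr=doc["tissue_corr"],
    )
    return SyntheticCohort(expression=expression, metadata=metadata,
                           traits=traits, truth=truth, config=config)
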