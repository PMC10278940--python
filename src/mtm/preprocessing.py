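"""Loading, filtering, splitting and per-tissue standardization.

Expression matrices are pandas DataFrames (samples × genes, sample IDs on the
index, gene IDs on the columns).  Sample metadata is a DataFrame indexed by
sample ID with ``individual_id`` and ``tissue`` columns.  All train/test
splitting is done at the individual level so that no person ever contributes
samples to both sides, and per-tissue Z-scoring is fitted on training samples
only — the recorded scaling factors are reused for validation data to prevent
information leakage.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression", "read_metadata", "read_traits", "validate_cohort",
    "filter_cohort", "split_by_individual", "make_cv_folds",
    "TissueScalers", "fit_scalers", "apply_scalers", "inverse_scalers",
    "log_transform", "build_tissue_pairs", "align_external",
]


def _read_table(path, **kwargs) -> pd.DataFrame:
    """Read a delimited table; tab for .tsv, comma for .csv, sniffed otherwise.

    gzip is handled transparently by pandas based on the file suffix.
    """
    name = Path(path).name.removesuffix(".gz")
    if name.endswith(".tsv") or name.endswith(".txt"):
        sep = "\t"
    elif name.endswith(".csv"):
        sep = ","
    else:
        sep = None  # let the python engine sniff
    return pd.read_csv(path, sep=sep, index_col=0,
                       engine="python" if sep is None else "c", **kwargs)


def read_expression(path) -> pd.DataFrame:
    """Read a samples × genes expression matrix from TSV/CSV (gzip ok)."""
    df = _read_table(path)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in expression: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in expression: {dups}")
    try:
        df = df.astype(np.float64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}")
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("expression contains non-finite values")
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, individual_id, tissue)."""
    df = _read_table(path)
    missing = {"individual_id", "tissue"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in metadata: {dups}")
    return df[["individual_id", "tissue"]].astype(str)


def read_traits(path) -> pd.DataFrame:
    """Read per-individual trait table keyed by individual_id."""
    return _read_table(path)


def validate_cohort(expr: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Check that every expression sample has exactly one metadata record."""
    missing = expr.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples missing from metadata: "
                         f"{missing.tolist()[:5]}")
    extra = meta.index.difference(expr.index)
    if len(extra):
        raise ValueError(f"metadata samples missing from expression: "
                         f"{extra.tolist()[:5]}")


def filter_cohort(expr: pd.DataFrame, meta: pd.DataFrame,
                  min_tissue_n: int = 51,
                  min_samples_per_individual: int = 2):
    """Drop small tissues, then under-sampled individuals, to a fixed point.

    Tissues must keep at least ``min_tissue_n`` samples (default 51, i.e.
    strictly more than 50) and individuals at least
    ``min_samples_per_individual`` samples (default 2).
    """
    validate_cohort(expr, meta)
    meta = meta.loc[expr.index]
    while True:
        tissue_counts = meta["tissue"].value_counts()
        bad_tissues = tissue_counts[tissue_counts < min_tissue_n].index
        keep = ~meta["tissue"].isin(bad_tissues)
        meta2 = meta[keep]
        ind_counts = meta2["individual_id"].value_counts()
        bad_inds = ind_counts[ind_counts < min_samples_per_individual].index
        meta2 = meta2[~meta2["individual_id"].isin(bad_inds)]
        if len(meta2) == len(meta):
            break
        meta = meta2
    if meta.empty:
        raise ValueError("no data after filtering")
    return expr.loc[meta.index], meta


def split_by_individual(meta: pd.DataFrame, train_fraction: float = 0.8,
                        seed: int = 0):
    """Randomly partition individual IDs into train / validation sets."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    individuals = np.array(sorted(meta["individual_id"].unique()))
    if len(individuals) < 2:
        raise ValueError("need at least 2 individuals to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(individuals))
    n_train = int(round(train_fraction * len(individuals)))
    n_train = min(max(n_train, 1), len(individuals) - 1)
    train = sorted(individuals[perm[:n_train]].tolist())
    val = sorted(individuals[perm[n_train:]].tolist())
    return train, val


def make_cv_folds(meta: pd.DataFrame, k: int = 5, seed: int = 0):
    """k-fold cross-validation partitions at the individual level."""
    individuals = np.array(sorted(meta["individual_id"].unique()))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(individuals):
        raise ValueError(f"k={k} exceeds {len(individuals)} individuals")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in kf.split(individuals):
        folds.append((sorted(individuals[train_idx].tolist()),
                      sorted(individuals[test_idx].tolist())))
    return folds


# ---------------------------------------------------------------------------
# per-tissue Z-scoring


@dataclasses.dataclass
class TissueScalers:
    """Per-(tissue, gene) mean and sd fitted on training samples only.

    ``ddof`` records the sd convention (sample sd, ddof=1, by default).
    Genes with zero variance in a tissue are listed in ``zero_sd``.
    """

    means: pd.DataFrame      # tissues × genes
    sds: pd.DataFrame        # tissues × genes
    ddof: int = 1

    @property
    def zero_sd(self) -> dict:
        out = {}
        for t in self.sds.index:
            genes = self.sds.columns[self.sds.loc[t] == 0.0].tolist()
            if genes:
                out[t] = genes
        return out

    def to_frame(self) -> pd.DataFrame:
        long = []
        for t in self.means.index:
            long.append(pd.DataFrame({
                "tissue": t, "gene": self.means.columns,
                "mean": self.means.loc[t].to_numpy(),
                "sd": self.sds.loc[t].to_numpy()}))
        return pd.concat(long, ignore_index=True)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path, ddof: int = 1) -> "TissueScalers":
        long = pd.read_csv(path, sep="\t")
        means = long.pivot(index="tissue", columns="gene", values="mean")
        sds = long.pivot(index="tissue", columns="gene", values="sd")
        return cls(means=means, sds=sds, ddof=ddof)


def fit_scalers(expr: pd.DataFrame, meta: pd.DataFrame,
                train_individuals, ddof: int = 1) -> TissueScalers:
    """Fit per-tissue per-gene mean/sd from training individuals' samples."""
    train_individuals = set(train_individuals)
    mask = meta["individual_id"].isin(train_individuals)
    sub_meta = meta[mask]
    tissues = sorted(meta["tissue"].unique())
    means, sds = {}, {}
    for t in tissues:
        samples = sub_meta.index[sub_meta["tissue"] == t]
        if len(samples) < 2:
            raise ValueError(f"tissue {t!r} has fewer than 2 training samples")
        # contiguous extraction keeps the reduction order independent of
        # the caller's memory layout (bit-stable refits)
        block = np.ascontiguousarray(expr.loc[samples].to_numpy())
        means[t] = pd.Series(block.mean(axis=0), index=expr.columns)
        sds[t] = pd.Series(block.std(axis=0, ddof=ddof), index=expr.columns)
    scalers = TissueScalers(means=pd.DataFrame(means).T,
                            sds=pd.DataFrame(sds).T, ddof=ddof)
    n_flagged = sum(len(v) for v in scalers.zero_sd.values())
    if n_flagged:
        logger.warning("fit_scalers: %d (tissue, gene) pairs have sd=0; "
                       "they will standardize to 0", n_flagged)
    return scalers


def apply_scalers(expr: pd.DataFrame, meta: pd.DataFrame,
                  scalers: TissueScalers) -> pd.DataFrame:
    """Z-score each sample with its tissue's recorded mean/sd.

    Genes with sd=0 map to 0 so downstream matrix shapes stay fixed.
    """
    unseen = set(meta.loc[expr.index, "tissue"]) - set(scalers.means.index)
    if unseen:
        raise ValueError(f"tissues without fitted scalers: {sorted(unseen)}")
    out = np.empty(expr.shape, dtype=np.float64)
    values = expr.to_numpy(dtype=np.float64)
    tissue_arr = meta.loc[expr.index, "tissue"].to_numpy()
    for t in np.unique(tissue_arr):
        rows = np.flatnonzero(tissue_arr == t)
        mu = scalers.means.loc[t, expr.columns].to_numpy()
        sd = scalers.sds.loc[t, expr.columns].to_numpy()
        safe_sd = np.where(sd > 0, sd, 1.0)
        z = (values[rows] - mu) / safe_sd
        z[:, sd == 0] = 0.0
        out[rows] = z
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def inverse_scalers(z: pd.DataFrame, meta_or_tissue,
                    scalers: TissueScalers) -> pd.DataFrame:
    """Undo Z-scoring; exact for sd>0 genes (sd=0 genes return the mean).

    ``meta_or_tissue`` is either a metadata frame covering ``z``'s samples or
    a single tissue label applied to every row.
    """
    if isinstance(meta_or_tissue, str):
        tissue_arr = np.full(len(z), meta_or_tissue)
    else:
        tissue_arr = meta_or_tissue.loc[z.index, "tissue"].to_numpy()
    out = np.empty(z.shape, dtype=np.float64)
    values = z.to_numpy(dtype=np.float64)
    for t in np.unique(tissue_arr):
        rows = np.flatnonzero(tissue_arr == t)
        mu = scalers.means.loc[t, z.columns].to_numpy()
        sd = scalers.sds.loc[t, z.columns].to_numpy()
        out[rows] = values[rows] * sd + mu
    return pd.DataFrame(out, index=z.index, columns=z.columns)


def log_transform(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(TPM + pseudocount); the default scale Z-scoring is applied on."""
    return np.log2(expr + pseudocount)


def build_tissue_pairs(meta: pd.DataFrame, individual_ids,
                       include_self_pairs: bool = False) -> pd.DataFrame:
    """All ordered within-individual sample pairs (both directions).

    Returns a DataFrame with columns source_sample, target_sample,
    source_tissue, target_tissue, individual_id.
    """
    individual_ids = set(individual_ids)
    rows = []
    for ind, group in meta.groupby("individual_id", sort=True):
        if ind not in individual_ids:
            continue
        samples = list(group.index)
        for a in samples:
            for b in samples:
                if a == b and not include_self_pairs:
                    continue
                rows.append((a, b, group.loc[a, "tissue"],
                             group.loc[b, "tissue"], ind))
    return pd.DataFrame(rows, columns=["source_sample", "target_sample",
                                       "source_tissue", "target_tissue",
                                       "individual_id"])


def align_external(expr_ext: pd.DataFrame, meta_ext: pd.DataFrame,
                   reference: TissueScalers) -> pd.DataFrame:
    """Rescale an external cohort so each gene's per-tissue mean/sd match
    the reference statistics (simple batch alignment).

    Genes absent from the reference are dropped (count logged).  A gene that
    is constant in the external data but variable in the reference is mapped
    to the reference mean and flagged.
    """
    shared = [g for g in expr_ext.columns if g in reference.means.columns]
    dropped = expr_ext.shape[1] - len(shared)
    if dropped:
        logger.info("align_external: dropped %d genes absent from reference",
                    dropped)
    if not shared:
        raise ValueError("no shared genes with the reference")
    expr = expr_ext[shared]
    tissue_arr = meta_ext.loc[expr.index, "tissue"].to_numpy()
    unseen = set(tissue_arr) - set(reference.means.index)
    if unseen:
        raise ValueError(f"external tissues absent from reference: "
                         f"{sorted(unseen)}")
    out = np.empty(expr.shape, dtype=np.float64)
    values = expr.to_numpy(dtype=np.float64)
    for t in np.unique(tissue_arr):
        rows = np.flatnonzero(tissue_arr == t)
        block = values[rows]
        mu_ext = block.mean(axis=0)
        sd_ext = block.std(axis=0, ddof=reference.ddof) if len(rows) > 1 \
            else np.zeros(block.shape[1])
        mu_ref = reference.means.loc[t, shared].to_numpy()
        sd_ref = reference.sds.loc[t, shared].to_numpy()
        safe = np.where(sd_ext > 0, sd_ext, 1.0)
        z = (block - mu_ext) / safe
        z[:, sd_ext == 0] = 0.0
        n_const = int((sd_ext == 0).sum())
        if n_const:
            logger.warning("align_external: %d constant external genes in "
                           "%s mapped to reference mean", n_const, t)
        out[rows] = z * sd_ref + mu_ref
    return pd.DataFrame(out, index=expr.index, columns=shared)
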