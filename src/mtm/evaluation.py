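"""Accuracy statistics: sample-wise and gene-wise Pearson correlation,
predictable genes (pGenes), and the individual-level k-fold cross-validation
protocol where per-fold predictions are concatenated before scoring.

Sample-wise accuracy is the Pearson correlation across genes between a
sample's predicted and observed standardized profile; gene-wise accuracy is
the correlation of a gene across individuals within a tissue.  pGenes are
genes with gene-wise correlation strictly greater than 0.3.  Correlations of
constant vectors are undefined and returned as NaN; undefined values are
excluded from summaries and can never qualify as pGenes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["pearson", "samplewise_accuracy", "genewise_accuracy",
           "count_pgenes", "EvaluationReport", "evaluate_predictions",
           "crossval_evaluate"]


def pearson(x, y) -> float:
    """Pearson correlation; NaN if either vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized per-row Pearson correlation; constant rows give NaN."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac * ac).sum(axis=1))
    sb = np.sqrt((bc * bc).sum(axis=1))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ac * bc).sum(axis=1) / denom
    rho[denom == 0] = np.nan
    return np.clip(rho, -1.0, 1.0)


def _align(pred: pd.DataFrame, obs: pd.DataFrame):
    if not pred.index.equals(obs.index) or not pred.columns.equals(obs.columns):
        try:
            pred = pred.loc[obs.index, obs.columns]
        except KeyError as exc:
            raise ValueError(f"prediction/observation misalignment: {exc}")
    return pred, obs


def samplewise_accuracy(pred_std: pd.DataFrame, obs_std: pd.DataFrame,
                        meta: pd.DataFrame) -> dict:
    """Per-sample Pearson correlation across genes, grouped by tissue."""
    pred_std, obs_std = _align(pred_std, obs_std)
    rho = _rowwise_pearson(pred_std.to_numpy(), obs_std.to_numpy())
    series = pd.Series(rho, index=obs_std.index)
    tissue = meta.loc[obs_std.index, "tissue"]
    return {t: series[tissue == t] for t in sorted(tissue.unique())}


def genewise_accuracy(pred: pd.DataFrame, obs: pd.DataFrame,
                      meta: pd.DataFrame) -> dict:
    """Per-gene Pearson correlation across individuals, per tissue."""
    pred, obs = _align(pred, obs)
    tissue = meta.loc[obs.index, "tissue"]
    out = {}
    for t in sorted(tissue.unique()):
        rows = obs.index[tissue == t]
        if len(rows) < 2:
            continue
        rho = _rowwise_pearson(pred.loc[rows].to_numpy().T,
                               obs.loc[rows].to_numpy().T)
        out[t] = pd.Series(rho, index=obs.columns)
    return out


def count_pgenes(gene_rho: pd.Series, threshold: float = 0.3) -> list:
    """Gene IDs with rho strictly greater than the threshold.

    NaN (undefined) correlations never qualify.
    """
    rho = pd.Series(gene_rho)
    mask = rho.notna() & (rho > threshold)
    return list(rho.index[mask])


@dataclasses.dataclass
class EvaluationReport:
    sample_rho: dict          # tissue -> Series of per-sample rho
    gene_rho: dict            # tissue -> Series of per-gene rho
    pgene_ids: dict           # tissue -> list of gene ids
    model_id: str = ""
    fold_provenance: dict = dataclasses.field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.gene_rho:
            srho = self.sample_rho.get(t, pd.Series(dtype=float)).dropna()
            grho = self.gene_rho[t].dropna()
            rows.append({
                "tissue": t,
                "mean_sample_rho": srho.mean() if len(srho) else np.nan,
                "mean_gene_rho": grho.mean() if len(grho) else np.nan,
                "n_pgenes": len(self.pgene_ids.get(t, [])),
                "n_undefined_genes": int(self.gene_rho[t].isna().sum()),
            })
        return pd.DataFrame(rows)


def evaluate_predictions(pred_std: pd.DataFrame, obs_std: pd.DataFrame,
                         meta: pd.DataFrame, model_id: str = "",
                         pgene_threshold: float = 0.3) -> EvaluationReport:
    """All accuracy statistics for one prediction matrix."""
    sample_rho = samplewise_accuracy(pred_std, obs_std, meta)
    gene_rho = genewise_accuracy(pred_std, obs_std, meta)
    pgenes = {t: count_pgenes(r, pgene_threshold)
              for t, r in gene_rho.items()}
    return EvaluationReport(sample_rho=sample_rho, gene_rho=gene_rho,
                            pgene_ids=pgenes, model_id=model_id)


def crossval_evaluate(expr: pd.DataFrame, meta: pd.DataFrame,
                      model_factory, folds, source_tissue: str,
                      model_id: str = "",
                      pgene_threshold: float = 0.3) -> EvaluationReport:
    """Individual-level k-fold protocol with concatenate-then-score.

    ``model_factory(train_individuals)`` must return a predictor
    ``predictor(expr_source_std, target_tissue) -> DataFrame`` together with
    the standardized observation frame for scoring,
    as ``(predictor, expr_std)``.  For each fold, the held-out individuals'
    source-tissue samples are fed to the predictor for every other tissue;
    predictions are concatenated across folds and scored once.
    """
    all_pred, all_obs, meta_rows = [], [], []
    provenance = {}
    for fold_id, (train_ids, test_ids) in enumerate(folds):
        predictor, expr_std = model_factory(train_ids)
        test_meta = meta[meta["individual_id"].isin(set(test_ids))]
        src_samples = test_meta.index[test_meta["tissue"] == source_tissue]
        if len(src_samples) == 0:
            raise ValueError(f"fold {fold_id}: no {source_tissue!r} samples "
                             "among held-out individuals")
        src_ind = test_meta.loc[src_samples, "individual_id"]
        for target in sorted(meta["tissue"].unique()):
            if target == source_tissue:
                continue
            tgt_samples = test_meta.index[test_meta["tissue"] == target]
            tgt_ind = test_meta.loc[tgt_samples, "individual_id"]
            shared = sorted(set(src_ind) & set(tgt_ind))
            if not shared:
                continue
            src_sel = src_samples[src_ind.isin(shared)]
            tgt_sel = tgt_samples[tgt_ind.isin(shared)]
            # order target rows to match the source individuals
            tgt_by_ind = {i: s for s, i in tgt_ind.items()}
            ordered_tgt = [tgt_by_ind[i]
                           for i in src_ind.loc[src_sel]]
            pred = predictor(expr_std.loc[src_sel], target)
            pred.index = ordered_tgt
            all_pred.append(pred)
            all_obs.append(expr_std.loc[ordered_tgt])
            meta_rows.extend(ordered_tgt)
        provenance[fold_id] = list(test_ids)
    pred_cat = pd.concat(all_pred)
    obs_cat = pd.concat(all_obs)
    report = evaluate_predictions(pred_cat, obs_cat, meta.loc[meta_rows],
                                  model_id=model_id,
                                  pgene_threshold=pgene_threshold)
    report.fold_provenance = provenance
    return report
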