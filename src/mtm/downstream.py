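"""Downstream concordance analyses: tissue similarity, latent-code and
decoding-path similarity, trait-association preservation, and differential
expression concordance (Wilcoxon rank-sum with Benjamini-Hochberg FDR, sign
consistency, log2 fold-change correlation, hypergeometric overlap, F1).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluation import pearson

__all__ = [
    "tissue_similarity", "compare_pairwise_to_similarity",
    "latent_code_similarity", "decoding_path_similarity",
    "trait_association_preservation", "wilcoxon_rank_sum", "de_analysis",
    "DEResult", "concordance", "ConcordanceReport",
]


def tissue_similarity(expr: pd.DataFrame, meta: pd.DataFrame,
                      pseudocount: float = 1.0) -> pd.DataFrame:
    """Pearson correlation across genes between per-tissue mean profiles
    on the log2(TPM + pseudocount) scale.  Symmetric with unit diagonal.
    """
    tissue = meta.loc[expr.index, "tissue"]
    tissues = [t for t in sorted(tissue.unique())
               if (tissue == t).sum() > 0]
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    log_expr = np.log2(expr + pseudocount)
    means = {t: log_expr[tissue == t].mean(axis=0).to_numpy()
             for t in tissues}
    sim = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    for a, b in itertools.combinations(tissues, 2):
        rho = pearson(means[a], means[b])
        sim.loc[a, b] = sim.loc[b, a] = rho
    return sim


def _upper_triangle(mat: pd.DataFrame) -> np.ndarray:
    arr = mat.to_numpy()
    iu = np.triu_indices(arr.shape[0], k=1)
    return arr[iu]


def compare_pairwise_to_similarity(stat_matrix: pd.DataFrame,
                                   sim_matrix: pd.DataFrame) -> float:
    """Spearman correlation between flattened upper triangles (diagonal
    excluded) of two symmetric tissue×tissue matrices, average ranks on
    ties.  NaN if either flattened array is constant.
    """
    if set(stat_matrix.index) != set(sim_matrix.index) \
            or stat_matrix.shape != sim_matrix.shape:
        raise ValueError("matrices must cover the same tissue set")
    if list(stat_matrix.index) != list(sim_matrix.index):
        sim_matrix = sim_matrix.loc[stat_matrix.index, stat_matrix.index]
    a = _upper_triangle(stat_matrix)
    b = _upper_triangle(sim_matrix)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return np.nan
    return float(stats.spearmanr(a, b).statistic)


def latent_code_similarity(model, expr_std: pd.DataFrame,
                           meta: pd.DataFrame) -> dict:
    """Pairwise Pearson similarity of latent codes, partitioned into
    same-individual (intra) and different-individual (inter) pairs.

    Returns intra/inter correlation arrays, their means, and a two-sided
    Wilcoxon rank-sum p-value for the intra > inter contrast.
    """
    from ._autograd import Tensor
    codes = model.encode(Tensor(expr_std.to_numpy()),
                         meta.loc[expr_std.index, "tissue"].to_numpy()).data
    individuals = meta.loc[expr_std.index, "individual_id"].to_numpy()
    n = len(codes)
    cmat = np.corrcoef(codes)
    iu = np.triu_indices(n, k=1)
    same = individuals[iu[0]] == individuals[iu[1]]
    intra = cmat[iu][same]
    inter = cmat[iu][~same]
    if len(intra) == 0 or len(inter) == 0:
        raise ValueError("need both intra- and inter-individual pairs")
    stat = stats.ranksums(intra, inter)
    return {"intra": intra, "inter": inter,
            "mean_intra": float(np.mean(intra)),
            "mean_inter": float(np.mean(inter)),
            "p_value": float(stat.pvalue)}


def decoding_path_similarity(model, code, tissues, sim_matrix) -> list:
    """Per generator layer: Spearman agreement between pairwise activation
    similarities across tissue conditions and the tissue similarity matrix.

    ``code`` is a single latent vector; it is decoded under every tissue in
    ``tissues`` and the layer activations compared pairwise (Pearson), then
    rank-correlated against ``sim_matrix``.
    """
    tissues = list(tissues)
    if len(tissues) < 3:
        raise ValueError("need at least 3 tissues for a rank correlation")
    code = np.atleast_2d(np.asarray(code, dtype=np.float64))
    codes = np.repeat(code, len(tissues), axis=0)
    acts = model.collect_activations(codes, tissues)
    out = []
    for layer in acts:
        sim = pd.DataFrame(np.corrcoef(layer), index=tissues,
                           columns=tissues)
        out.append(compare_pairwise_to_similarity(
            sim, sim_matrix.loc[tissues, tissues]))
    return out


def trait_association_preservation(pred: pd.DataFrame, obs: pd.DataFrame,
                                   meta: pd.DataFrame, traits: pd.Series,
                                   pgene_ids=None) -> dict:
    """How well per-gene trait associations in predictions match those in
    observed data, per tissue.

    For each gene, the Pearson correlation between expression and the trait
    is computed across individuals in the predicted and observed data; the
    reported statistic is the correlation of those two association vectors
    (over pGenes when ``pgene_ids`` is given).
    """
    traits = pd.Series(traits)
    if traits.nunique() < 2:
        raise ValueError("trait is constant")
    tissue = meta.loc[obs.index, "tissue"]
    out = {}
    for t in sorted(tissue.unique()):
        rows = obs.index[tissue == t]
        if len(rows) < 3:
            continue
        inds = meta.loc[rows, "individual_id"]
        tvals = traits.loc[inds].to_numpy()
        genes = (list(pgene_ids[t]) if isinstance(pgene_ids, dict)
                 else list(pgene_ids) if pgene_ids is not None
                 else list(obs.columns))
        if not genes:
            out[t] = np.nan
            continue
        assoc_pred = _gene_trait_assoc(pred.loc[rows, genes].to_numpy(), tvals)
        assoc_obs = _gene_trait_assoc(obs.loc[rows, genes].to_numpy(), tvals)
        ok = ~(np.isnan(assoc_pred) | np.isnan(assoc_obs))
        out[t] = (pearson(assoc_pred[ok], assoc_obs[ok])
                  if ok.sum() >= 2 else np.nan)
    return out


def _gene_trait_assoc(mat: np.ndarray, trait: np.ndarray) -> np.ndarray:
    mc = mat - mat.mean(axis=0)
    tc = trait - trait.mean()
    sm = np.sqrt((mc * mc).sum(axis=0))
    st = np.sqrt((tc * tc).sum())
    denom = sm * st
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (mc * tc[:, None]).sum(axis=0) / denom
    rho[denom == 0] = np.nan
    return rho


# ---------------------------------------------------------------------------
# differential expression


def wilcoxon_rank_sum(x, y, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact null distribution for group sizes up to ``exact_max_n`` when the
    data are tie-free; the normal approximation with tie correction
    otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    small = max(len(x), len(y)) <= exact_max_n
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


@dataclasses.dataclass
class DEResult:
    """Per-gene differential expression between cases and controls."""

    table: pd.DataFrame   # index gene; log2fc, p_value, fdr, direction

    @property
    def up(self) -> list:
        return list(self.table.index[self.table["direction"] == "up"])

    @property
    def down(self) -> list:
        return list(self.table.index[self.table["direction"] == "down"])

    def degs(self) -> list:
        return self.up + self.down


def de_analysis(expr: pd.DataFrame, groups, min_group_n: int = 10,
                fdr_threshold: float = 0.05,
                pseudocount: float = 1.0) -> DEResult:
    """Per-gene two-sided Wilcoxon rank-sum between cases (group 1) and
    controls (group 0), Benjamini-Hochberg FDR, and log2 fold changes
    log2(mean_case + eps) - log2(mean_control + eps) on the TPM-like scale.
    """
    groups = pd.Series(groups, index=expr.index) \
        if not isinstance(groups, pd.Series) else groups.loc[expr.index]
    case_rows = expr.index[groups.astype(int) == 1]
    ctrl_rows = expr.index[groups.astype(int) == 0]
    if len(case_rows) < min_group_n or len(ctrl_rows) < min_group_n:
        raise ValueError(
            f"each group needs at least min_group_n={min_group_n} samples "
            f"(got {len(case_rows)} cases, {len(ctrl_rows)} controls)")
    case = expr.loc[case_rows].to_numpy()
    ctrl = expr.loc[ctrl_rows].to_numpy()
    pvals = np.array([wilcoxon_rank_sum(case[:, j], ctrl[:, j])
                      for j in range(expr.shape[1])])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    lfc = (np.log2(case.mean(axis=0) + pseudocount)
           - np.log2(ctrl.mean(axis=0) + pseudocount))
    direction = np.where(fdr < fdr_threshold,
                         np.where(lfc > 0, "up", "down"), "none")
    table = pd.DataFrame({"log2fc": lfc, "p_value": pvals, "fdr": fdr,
                          "direction": direction}, index=expr.columns)
    return DEResult(table=table)


@dataclasses.dataclass
class ConcordanceReport:
    sign_consistency: float
    lfc_rho: float
    overlap_p_up: float
    overlap_p_down: float
    f1_up: float
    f1_down: float


def _hypergeom_overlap_p(universe_n, ref, pred) -> float:
    """P(overlap >= observed) when drawing |pred| genes from the universe."""
    ref, pred = set(ref), set(pred)
    if not ref or not pred:
        return np.nan
    k = len(ref & pred)
    return float(stats.hypergeom.sf(k - 1, universe_n, len(ref), len(pred)))


def _f1(ref, pred) -> float:
    ref, pred = set(ref), set(pred)
    if not ref:
        return np.nan
    if not pred:
        return 0.0
    tp = len(ref & pred)
    precision = tp / len(pred)
    recall = tp / len(ref)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def concordance(de_pred: DEResult, de_ref: DEResult) -> ConcordanceReport:
    """Concordance of a predicted DE result with a reference one.

    Sign consistency is the fraction of genes whose log2 fold changes share
    a sign; genes with a zero fold change in either result are excluded from
    both numerator and denominator.  Overlap significance is hypergeometric
    against the shared gene universe; F1 treats the reference DEGs as truth.
    An empty reference DEG set yields NaN overlap/F1, not zero.
    """
    genes = de_ref.table.index
    if not set(genes) == set(de_pred.table.index):
        raise ValueError("DE results must share the same gene universe")
    lfc_p = de_pred.table.loc[genes, "log2fc"].to_numpy()
    lfc_r = de_ref.table.loc[genes, "log2fc"].to_numpy()
    nonzero = (lfc_p != 0) & (lfc_r != 0)
    sign_cons = (float(np.mean(np.sign(lfc_p[nonzero])
                               == np.sign(lfc_r[nonzero])))
                 if nonzero.any() else np.nan)
    lfc_rho = pearson(lfc_p, lfc_r)
    n = len(genes)
    return ConcordanceReport(
        sign_consistency=sign_cons,
        lfc_rho=lfc_rho,
        overlap_p_up=_hypergeom_overlap_p(n, de_ref.up, de_pred.up),
        overlap_p_down=_hypergeom_overlap_p(n, de_ref.down, de_pred.down),
        f1_up=_f1(de_ref.up, de_pred.up),
        f1_down=_f1(de_ref.down, de_pred.down),
    )
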