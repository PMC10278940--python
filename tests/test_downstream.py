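"""Downstream analyses: tissue similarity, rank agreement of pairwise
matrices, latent-code individuality, decoding paths, trait-association
preservation, and differential-expression concordance — each checked against
brute-force or exact combinatorial oracles where feasible."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtm import (SimulationConfig, concordance, de_analysis,
                 decoding_path_similarity, latent_code_similarity,
                 simulate_cohort, tissue_similarity,
                 trait_association_preservation, wilcoxon_rank_sum,
                 compare_pairwise_to_similarity)
from mtm.downstream import DEResult
from mtm.model import ModelConfig, MTMModel


# -- tissue similarity -----------------------------------------------------


def test_duplicated_tissue_has_unit_similarity(tiny_cohort):
    expr = tiny_cohort.expression
    meta = tiny_cohort.metadata.copy()
    # relabel one tissue's samples to two interleaved pseudo-tissues with
    # identical expression: duplicate blood rows under a second label
    blood = meta.index[meta["tissue"] == "blood"]
    dup_expr = pd.concat([expr, expr.loc[blood].set_index(
        expr.loc[blood].index + "_dup")])
    dup_meta = pd.concat([meta, pd.DataFrame(
        {"individual_id": meta.loc[blood, "individual_id"].to_numpy(),
         "tissue": "blood_copy"}, index=blood + "_dup")])
    sim = tissue_similarity(dup_expr, dup_meta)
    assert sim.loc["blood", "blood_copy"] == pytest.approx(1.0)


def test_similarity_symmetric_unit_diagonal(small_cohort):
    sim = tissue_similarity(small_cohort.expression, small_cohort.metadata)
    assert np.allclose(sim, sim.T)
    assert np.allclose(np.diag(sim), 1.0)


def test_correlated_loadings_rank_more_similar(small_cohort):
    """The generator interpolates tissue loadings toward a common matrix
    with per-tissue weights r_k; measured similarity must rank tissue pairs
    consistently with the ground-truth r_k * r_l ordering."""
    c = small_cohort
    sim = tissue_similarity(c.expression, c.metadata)
    r = c.truth.tissue_corr
    tissues = list(sim.index)
    truth = pd.DataFrame(
        [[r[a] * r[b] if a != b else 1.0 for b in tissues]
         for a in tissues], index=tissues, columns=tissues)
    rho = compare_pairwise_to_similarity(truth, sim)
    assert rho > 0.5


def test_single_tissue_similarity_raises(tiny_cohort):
    meta = tiny_cohort.metadata
    blood = meta.index[meta["tissue"] == "blood"]
    with pytest.raises(ValueError):
        tissue_similarity(tiny_cohort.expression.loc[blood],
                          meta.loc[blood])


# -- pairwise rank agreement ----------------------------------------------


def _sym(mat, labels):
    return pd.DataFrame(mat, index=labels, columns=labels)


def test_rank_agreement_identity_and_reversal():
    labels = list("abcd")
    rng = np.random.default_rng(0)
    m = rng.standard_normal((4, 4))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    sim = _sym(m, labels)
    assert compare_pairwise_to_similarity(sim, sim) == pytest.approx(1.0)
    assert compare_pairwise_to_similarity(-sim, sim) == pytest.approx(-1.0)


def test_rank_agreement_matches_manual_rank_formula():
    labels = list("abcd")
    a = _sym(np.array([[1, .1, .2, .3], [.1, 1, .5, .4],
                       [.2, .5, 1, .6], [.3, .4, .6, 1]]), labels)
    b = _sym(np.array([[1, .3, .1, .6], [.3, 1, .2, .9],
                       [.1, .2, 1, .8], [.6, .9, .8, 1]]), labels)
    got = compare_pairwise_to_similarity(a, b)
    # brute-force Spearman: correlate rank vectors of the 6 upper entries
    iu = np.triu_indices(4, 1)
    ra = stats.rankdata(a.to_numpy()[iu])
    rb = stats.rankdata(b.to_numpy()[iu])
    expected = np.corrcoef(ra, rb)[0, 1]
    assert got == pytest.approx(expected, abs=1e-12)


def test_rank_agreement_dimension_mismatch():
    with pytest.raises(ValueError):
        compare_pairwise_to_similarity(
            _sym(np.eye(3), list("abc")), _sym(np.eye(4), list("abcd")))


# -- latent codes and decoding paths ---------------------------------------


def _tiny_trained_model(cohort):
    from mtm import TrainConfig, split_by_individual, standardize_cohort, \
        train_mtm
    train_ids, val_ids = split_by_individual(cohort.metadata, 0.8, seed=0)
    expr_std, _ = standardize_cohort(cohort.expression, cohort.metadata,
                                     train_ids)
    mc = ModelConfig(
        gene_dim=cohort.expression.shape[1],
        tissues=tuple(sorted(cohort.metadata["tissue"].unique())),
        latent_dim=8, encoder_widths=(24,), noise_dim=4, mapper_widths=(8,),
        discriminator_widths=(16,), seed=0)
    model, _ = train_mtm(expr_std, cohort.metadata, train_ids, None, mc,
                         TrainConfig(batch_size=32, max_epochs=30,
                                     learning_rate=2e-3, adv_weight=0.05,
                                     seed=0))
    return model, expr_std


def test_latent_pair_counts_match_combinatorics(tiny_cohort, tiny_model):
    c = tiny_cohort
    # model fixture has 3 tissues matching tiny_cohort
    from mtm import standardize_cohort
    expr_std, _ = standardize_cohort(c.expression, c.metadata,
                                     c.metadata["individual_id"].unique())
    res = latent_code_similarity(tiny_model, expr_std, c.metadata)
    sizes = c.metadata.groupby("individual_id").size()
    n = len(c.metadata)
    expected_intra = int((sizes * (sizes - 1) // 2).sum())
    assert len(res["intra"]) == expected_intra
    assert len(res["inter"]) == n * (n - 1) // 2 - expected_intra


def test_trained_model_separates_individuals(tiny_cohort):
    model, expr_std = _tiny_trained_model(tiny_cohort)
    res = latent_code_similarity(model, expr_std, tiny_cohort.metadata)
    assert res["mean_intra"] > res["mean_inter"]
    assert res["p_value"] < 0.01


def test_decoding_path_output_length_and_degenerate_case(tiny_model, rng):
    sim = pd.DataFrame(np.eye(3), index=tiny_model.config.tissues,
                       columns=tiny_model.config.tissues)
    code = rng.standard_normal(8)
    rhos = decoding_path_similarity(tiny_model, code,
                                    tiny_model.config.tissues, sim)
    assert len(rhos) == len(tiny_model.generator) + 1
    # identical affines across tissues -> identical activations -> NaN
    for blk in tiny_model.generator:
        blk.gamma.data[:] = 1.0
        blk.beta.data[:] = 0.0
    rhos = decoding_path_similarity(tiny_model, code,
                                    tiny_model.config.tissues, sim)
    assert all(np.isnan(r) for r in rhos)


def test_decoding_path_needs_three_tissues(tiny_model, rng):
    sim = pd.DataFrame(np.eye(2), index=["blood", "tissue_1"],
                       columns=["blood", "tissue_1"])
    with pytest.raises(ValueError):
        decoding_path_similarity(tiny_model, rng.standard_normal(8),
                                 ["blood", "tissue_1"], sim)


def test_trained_decoding_paths_track_tissue_similarity(small_cohort):
    """After training on a cohort whose tissue loadings have a planted
    similarity ordering, generator activations across tissue conditions
    rank-agree with measured tissue similarity (positive median rho)."""
    model, expr_std = _tiny_trained_model(small_cohort)
    sim = tissue_similarity(small_cohort.expression, small_cohort.metadata)
    meta = small_cohort.metadata
    blood = meta.index[meta["tissue"] == "blood"][:10]
    from mtm._autograd import Tensor
    codes = model.encode(Tensor(expr_std.loc[blood].to_numpy()),
                         ["blood"] * len(blood)).data
    med = []
    for code in codes:
        rhos = decoding_path_similarity(model, code, sim.index, sim)
        med.append(np.nanmedian(rhos))
    assert np.median(med) > 0


# -- trait associations ----------------------------------------------------


def test_trait_preservation_perfect_and_permuted(tiny_cohort, rng):
    c = tiny_cohort
    trait = c.traits["trait"]
    res = trait_association_preservation(c.expression, c.expression,
                                         c.metadata, trait)
    for rho in res.values():
        assert rho == pytest.approx(1.0)
    # individual-permuted predictions destroy the association structure
    perm = c.expression.copy()
    for t in c.metadata["tissue"].unique():
        rows = c.metadata.index[c.metadata["tissue"] == t]
        perm.loc[rows] = c.expression.loc[
            rng.permutation(rows)].to_numpy()
    res_p = trait_association_preservation(perm, c.expression, c.metadata,
                                           trait)
    assert np.nanmean(np.abs(list(res_p.values()))) < 0.5


def test_trait_preservation_constant_trait_raises(tiny_cohort):
    with pytest.raises(ValueError):
        trait_association_preservation(
            tiny_cohort.expression, tiny_cohort.expression,
            tiny_cohort.metadata,
            pd.Series(1.0, index=tiny_cohort.traits.index))


def test_planted_trait_genes_preserved_across_realizations():
    from mtm.synthetic import resample_expression
    cfg = SimulationConfig(n_individuals=80, n_tissues=2, n_genes=120,
                           noise_sd=0.2, n_trait_genes=25, trait_effect=1.0,
                           n_deg=0, seed=11)
    a = simulate_cohort(cfg)
    b = resample_expression(a, seed=99)
    res = trait_association_preservation(b.expression, a.expression,
                                         a.metadata, a.traits["trait"],
                                         pgene_ids=a.truth.trait_genes)
    for rho in res.values():
        assert rho > 0.9


# -- differential expression ----------------------------------------------


def _exact_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n].sum()
    stats_all = []
    for comb in itertools.combinations(range(n + m), n):
        stats_all.append(ranks[list(comb)].sum())
    stats_all = np.asarray(stats_all)
    mu = stats_all.mean()
    p = np.mean(np.abs(stats_all - mu) >= abs(obs - mu) - 1e-12)
    return p


def test_wilcoxon_tiny_case_exact_value():
    # {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 assignments
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


@pytest.mark.parametrize("seed", range(6))
def test_wilcoxon_matches_exact_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 7))
    m = int(rng.integers(3, 7))
    x = rng.standard_normal(n)
    y = rng.standard_normal(m) + rng.uniform(-1, 1)
    assert wilcoxon_rank_sum(x, y) == pytest.approx(
        _exact_rank_sum_p(x, y), abs=1e-12)


def _group_frame(n_case=25, n_ctrl=25, n_genes=60, seed=0, shift_genes=()):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n_case + n_ctrl)]
    vals = rng.lognormal(mean=2.0, sigma=1.0,
                         size=(n_case + n_ctrl, n_genes))
    expr = pd.DataFrame(vals, index=idx,
                        columns=[f"g{j}" for j in range(n_genes)])
    for g in shift_genes:
        expr.loc[idx[:n_case], g] *= 8.0     # +3 log2fc in cases
    groups = pd.Series([1] * n_case + [0] * n_ctrl, index=idx)
    return expr, groups


def test_de_null_gives_no_degs():
    expr, groups = _group_frame(seed=2)
    res = de_analysis(expr, groups)
    assert len(res.degs()) == 0
    # p-values roughly uniform: mean near 0.5
    assert 0.3 < res.table["p_value"].mean() < 0.7


def test_de_recovers_planted_upshift():
    expr, groups = _group_frame(seed=3, shift_genes=["g0", "g1", "g2"])
    res = de_analysis(expr, groups)
    for g in ["g0", "g1", "g2"]:
        assert res.table.loc[g, "direction"] == "up"
        assert res.table.loc[g, "log2fc"] > 0


def test_de_group_minimum_enforced():
    expr, groups = _group_frame(n_case=4)
    with pytest.raises(ValueError, match="min_group_n"):
        de_analysis(expr, groups, min_group_n=10)


def test_bh_fdr_monotone_in_threshold():
    expr, groups = _group_frame(seed=4, shift_genes=[f"g{j}"
                                                     for j in range(8)])
    res_strict = de_analysis(expr, groups, fdr_threshold=0.01)
    res_loose = de_analysis(expr, groups, fdr_threshold=0.10)
    assert set(res_strict.degs()) <= set(res_loose.degs())


# -- concordance -----------------------------------------------------------


def _make_de(lfc: dict, degs_up=(), degs_down=()):
    genes = list(lfc)
    direction = ["up" if g in degs_up else
                 "down" if g in degs_down else "none" for g in genes]
    table = pd.DataFrame({"log2fc": [lfc[g] for g in genes],
                          "p_value": 0.5, "fdr": 0.5,
                          "direction": direction}, index=genes)
    return DEResult(table=table)


def test_concordance_identical_results():
    lfc = {f"g{j}": (j - 5) * 0.3 + 0.1 for j in range(12)}
    de = _make_de(lfc, degs_up=("g9", "g10"), degs_down=("g0",))
    rep = concordance(de, de)
    assert rep.sign_consistency == pytest.approx(1.0)
    assert rep.lfc_rho == pytest.approx(1.0)
    assert rep.f1_up == pytest.approx(1.0)
    assert rep.f1_down == pytest.approx(1.0)


def test_hypergeometric_overlap_exact_value():
    # universe 100, 10 reference up-DEGs, 10 predicted, all 10 overlap:
    # P = 1 / C(100, 10)
    genes = [f"g{j}" for j in range(100)]
    lfc = {g: 1.0 for g in genes}
    degs = tuple(genes[:10])
    rep = concordance(_make_de(lfc, degs_up=degs),
                      _make_de(lfc, degs_up=degs))
    assert rep.overlap_p_up == pytest.approx(1 / math.comb(100, 10),
                                             rel=1e-9)


def test_hypergeometric_matches_enumeration_small_universe():
    """P(overlap >= k) against exact enumeration for universes <= 20."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        N = int(rng.integers(8, 21))
        genes = [f"g{j}" for j in range(N)]
        n_ref = int(rng.integers(1, N // 2 + 1))
        n_pred = int(rng.integers(1, N // 2 + 1))
        ref = set(rng.choice(genes, n_ref, replace=False))
        pred = set(rng.choice(genes, n_pred, replace=False))
        k = len(ref & pred)
        total = math.comb(N, n_pred)
        atleast = sum(math.comb(n_ref, i) * math.comb(N - n_ref, n_pred - i)
                      for i in range(k, min(n_ref, n_pred) + 1))
        expected = atleast / total
        lfc = {g: 1.0 for g in genes}
        rep = concordance(_make_de(lfc, degs_up=tuple(pred)),
                          _make_de(lfc, degs_up=tuple(ref)))
        assert rep.overlap_p_up == pytest.approx(expected, rel=1e-9)


def test_disjoint_predictions_zero_f1():
    genes = [f"g{j}" for j in range(20)]
    lfc = {g: 1.0 for g in genes}
    rep = concordance(_make_de(lfc, degs_up=tuple(genes[:5])),
                      _make_de(lfc, degs_up=tuple(genes[5:10])))
    assert rep.f1_up == 0.0


def test_empty_reference_degs_flagged_not_zero():
    genes = [f"g{j}" for j in range(10)]
    lfc = {g: 1.0 for g in genes}
    rep = concordance(_make_de(lfc, degs_up=("g1",)), _make_de(lfc))
    assert np.isnan(rep.overlap_p_up)
    assert np.isnan(rep.f1_up)


def test_sign_consistency_excludes_zero_lfc():
    genes = ["a", "b", "c", "d"]
    pred = _make_de({"a": 1.0, "b": -1.0, "c": 0.0, "d": 2.0})
    ref = _make_de({"a": 2.0, "b": 1.0, "c": 5.0, "d": 1.0})
    rep = concordance(pred, ref)
    # among a, b, d: signs agree for a and d
    assert rep.sign_consistency == pytest.approx(2 / 3)


def test_concordance_invariant_to_gene_order():
    rng = np.random.default_rng(1)
    genes = [f"g{j}" for j in range(30)]
    lfc = {g: float(rng.standard_normal()) for g in genes}
    de_a = _make_de(lfc, degs_up=tuple(genes[:4]))
    shuffled = list(genes)
    rng.shuffle(shuffled)
    lfc_b = {g: lfc[g] + 0.1 for g in shuffled}
    de_b = _make_de(lfc_b, degs_up=tuple(genes[2:6]))
    r1 = concordance(de_a, de_b)
    de_b2 = DEResult(table=de_b.table.sample(frac=1, random_state=0))
    r2 = concordance(de_a, de_b2)
    assert r1.lfc_rho == pytest.approx(r2.lfc_rho, abs=1e-12)
    assert r1.f1_up == pytest.approx(r2.f1_up)
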