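import numpy as np
import pandas as pd
import pytest

from prepostx.coexpression import (
    CoexpressionParams,
    detect_modules,
    gene_trait_correlation,
    mm_trait_link,
    module_eigengenes,
    module_membership,
    module_trait_correlation,
    pick_soft_threshold,
    remove_subject_effect,
    signed_adjacency,
    tom_similarity,
    variance_filter,
    UNASSIGNED,
)
from prepostx.core_io import ExprMatrix, GeneSetCatalog
from tests.conftest import random_expr


def _paired_meta(n_subj):
    rows = []
    for i in range(n_subj):
        for tp in ("TP1", "TP2"):
            rows.append(
                {
                    "sample_id": f"p{i}_{tp}",
                    "subject_id": f"p{i}",
                    "cohort": "ACD",
                    "timepoint": tp,
                }
            )
    return pd.DataFrame(rows)


def planted_blocks(rng, n_samples=32, block_sizes=(50, 50), n_noise=100, noise_sd=0.5):
    """Latent-factor blocks plus independent noise genes, with truth labels."""
    blocks, truth = [], []
    for b, size in enumerate(block_sizes):
        f = rng.normal(0, 1, n_samples)
        blocks.append(
            f[None, :] * rng.uniform(0.7, 1.2, (size, 1))
            + rng.normal(0, noise_sd, (size, n_samples))
        )
        truth += [f"block{b}"] * size
    blocks.append(rng.normal(0, 1, (n_noise, n_samples)))
    truth += ["noise"] * n_noise
    X = np.vstack(blocks)
    em = ExprMatrix(
        pd.DataFrame(
            X,
            index=[f"g{i:04d}" for i in range(len(X))],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
    return em, truth


class TestSubjectCentering:
    def test_per_subject_means_zero(self):
        rng = np.random.default_rng(0)
        meta = _paired_meta(6)
        em = ExprMatrix(
            pd.DataFrame(
                rng.normal(size=(20, 12)),
                index=[f"g{i}" for i in range(20)],
                columns=list(meta["sample_id"]),
            )
        )
        centered = remove_subject_effect(em, meta)
        for i in range(6):
            pair = centered.values[[f"p{i}_TP1", f"p{i}_TP2"]]
            np.testing.assert_allclose(pair.mean(axis=1), 0.0, atol=1e-12)

    def test_pure_subject_offsets_become_zero(self):
        meta = _paired_meta(4)
        offsets = np.array([1.0, 1.0, -3.0, -3.0, 0.5, 0.5, 2.0, 2.0])
        em = ExprMatrix(
            pd.DataFrame(
                np.tile(offsets, (5, 1)),
                index=[f"g{i}" for i in range(5)],
                columns=list(meta["sample_id"]),
            )
        )
        centered = remove_subject_effect(em, meta)
        np.testing.assert_allclose(centered.values.to_numpy(), 0.0, atol=1e-12)

    def test_within_subject_contrast_preserved(self):
        rng = np.random.default_rng(1)
        meta = _paired_meta(5)
        em = ExprMatrix(
            pd.DataFrame(
                rng.normal(size=(15, 10)),
                index=[f"g{i}" for i in range(15)],
                columns=list(meta["sample_id"]),
            )
        )
        centered = remove_subject_effect(em, meta)
        for i in range(5):
            diff_before = em.values[f"p{i}_TP2"] - em.values[f"p{i}_TP1"]
            diff_after = centered.values[f"p{i}_TP2"] - centered.values[f"p{i}_TP1"]
            np.testing.assert_allclose(diff_after, diff_before, atol=1e-12)


class TestVarianceFilter:
    def test_fraction_one_is_identity(self):
        rng = np.random.default_rng(2)
        em = random_expr(rng, 10, 5)
        out = variance_filter(em, 1.0)
        assert out.gene_ids == em.gene_ids

    def test_top_fraction_kept(self):
        values = np.diag([4.0, 3.0, 2.0, 1.0]) @ np.tile([1.0, -1.0, 1.0, -1.0], (4, 1))
        em = ExprMatrix(
            pd.DataFrame(values, index=["a", "b", "c", "d"], columns=list("wxyz"))
        )
        out = variance_filter(em, 0.75)
        assert out.gene_ids == ["a", "b", "c"]

    def test_tie_break_lexicographic(self):
        values = np.tile([1.0, -1.0, 1.0, -1.0], (3, 1))  # equal variances
        em = ExprMatrix(pd.DataFrame(values, index=["zz", "aa", "mm"], columns=list("wxyz")))
        out = variance_filter(em, 2 / 3)
        assert set(out.gene_ids) == {"aa", "mm"}


class TestSoftThreshold:
    def test_mean_connectivity_decreases_with_beta(self):
        rng = np.random.default_rng(3)
        em, _ = planted_blocks(rng)
        result = pick_soft_threshold(em, CoexpressionParams())
        conn = result.diagnostics["mean_connectivity"].to_numpy()
        assert (np.diff(conn) < 0).all()

    def test_heterogeneous_blocks_reach_target(self):
        rng = np.random.default_rng(3)
        n_s = 40
        blocks = []
        for size in (200, 100, 60, 40, 25, 15, 10, 8):
            f = rng.normal(0, 1, n_s)
            blocks.append(
                f[None, :] * rng.uniform(0.5, 1.3, (size, 1))
                + rng.normal(0, 0.7, (size, n_s))
            )
        blocks.append(rng.normal(0, 1, (300, n_s)))
        X = np.vstack(blocks)
        em = ExprMatrix(
            pd.DataFrame(X, index=[f"g{i}" for i in range(len(X))],
                         columns=[f"s{j}" for j in range(n_s)])
        )
        result = pick_soft_threshold(em)
        assert result.reached_target
        assert result.diagnostics["r2"].max() >= 0.8

    def test_degenerate_structure_takes_warning_path(self):
        # a single shared factor gives every gene the same connectivity, so
        # the log-log fit cannot reach the target and the fallback warns
        rng = np.random.default_rng(4)
        f = rng.normal(0, 1, 20)
        X = f[None, :] + rng.normal(0, 0.3, (100, 20))
        em = ExprMatrix(
            pd.DataFrame(X, index=[f"g{i}" for i in range(100)],
                         columns=[f"s{j}" for j in range(20)])
        )
        with pytest.warns(UserWarning, match="scale-free"):
            result = pick_soft_threshold(em)
        assert not result.reached_target


class TestTOM:
    def test_definitional_properties(self):
        rng = np.random.default_rng(5)
        em, _ = planted_blocks(rng, block_sizes=(10,), n_noise=10)
        tom = tom_similarity(signed_adjacency(em.values.to_numpy(), 6))
        assert np.allclose(np.diag(tom), 1.0)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_matches_per_pair_loop(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(25, 12))
        a = signed_adjacency(values, 4)
        tom = tom_similarity(a)
        a0 = a.copy()
        np.fill_diagonal(a0, 0.0)
        k = a0.sum(axis=1)
        n = len(a0)
        for i in range(0, n, 5):
            for j in range(0, n, 7):
                if i == j:
                    continue
                l_ij = sum(a0[i, u] * a0[u, j] for u in range(n) if u not in (i, j))
                expected = (l_ij + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-10)


class TestModules:
    def test_planted_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        params = CoexpressionParams(min_module_size=20)
        em, truth = planted_blocks(rng)
        soft = pick_soft_threshold(em, params)
        assignment = detect_modules(em, soft.beta, params)
        assert len(assignment.modules()) == 2
        assert adjusted_rand_score(truth, assignment.labels.to_list()) >= 0.9

    def test_duplicate_gene_lands_with_original(self):
        rng = np.random.default_rng(8)
        params = CoexpressionParams(min_module_size=10)
        em, _ = planted_blocks(rng, block_sizes=(30,), n_noise=40)
        dup = em.values.copy()
        dup.loc["g_dup"] = dup.loc["g0000"]
        assignment = detect_modules(ExprMatrix(dup), 6, params)
        assert assignment.labels["g_dup"] == assignment.labels["g0000"]
        assert assignment.labels["g0000"] != UNASSIGNED

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(9)
        params = CoexpressionParams(min_module_size=15)
        em, _ = planted_blocks(rng, block_sizes=(30, 30), n_noise=40)
        a1 = detect_modules(em, 8, params)
        order = rng.permutation(em.gene_ids)
        a2 = detect_modules(ExprMatrix(em.values.loc[order]), 8, params)
        # same partition up to labels: compare co-membership on a sample of pairs
        for g in em.gene_ids[::13]:
            for h in em.gene_ids[::17]:
                same1 = (
                    a1.labels[g] == a1.labels[h] and a1.labels[g] != UNASSIGNED
                )
                same2 = (
                    a2.labels[g] == a2.labels[h] and a2.labels[g] != UNASSIGNED
                )
                assert same1 == same2


class TestEigengenes:
    def test_identical_genes_module(self):
        rng = np.random.default_rng(10)
        profile = rng.normal(size=16)
        values = np.tile(profile, (8, 1))
        em = ExprMatrix(
            pd.DataFrame(values, index=[f"g{i}" for i in range(8)],
                         columns=[f"s{j}" for j in range(16)])
        )
        from prepostx.coexpression import ModuleAssignment

        assignment = ModuleAssignment(labels=pd.Series("g0", index=em.gene_ids))
        eig = module_eigengenes(em, assignment).loc["g0"].to_numpy()
        standardized = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig, standardized, atol=1e-8)

    def test_matches_svd_oracle_and_orientation_invariance(self):
        rng = np.random.default_rng(11)
        em, _ = planted_blocks(rng, block_sizes=(20,), n_noise=0)
        from prepostx.coexpression import ModuleAssignment

        labels = pd.Series("m", index=em.gene_ids)
        assignment = ModuleAssignment(labels=labels)
        eig = module_eigengenes(em, assignment).loc["m"].to_numpy()
        X = em.values.to_numpy()
        Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
        v = Vt[0] / Vt[0].std(ddof=1)
        assert np.allclose(eig, v, atol=1e-8) or np.allclose(eig, -v, atol=1e-8)
        # flipping every gene's sign changes nothing observable after orientation
        flipped = ExprMatrix(-em.values)
        eig_f = module_eigengenes(flipped, assignment).loc["m"].to_numpy()
        corr = np.corrcoef(eig, eig_f)[0, 1]
        assert abs(abs(corr) - 1.0) < 1e-9
        assert eig.std(ddof=1) == pytest.approx(1.0)


class TestModuleTrait:
    def test_eigengene_equal_to_trait(self):
        trait = pd.Series(
            [0.0, 1.0] * 8, index=[f"s{j}" for j in range(16)], name="music"
        )
        eig = pd.DataFrame([trait.to_numpy()], index=["m"], columns=trait.index)
        mt = module_trait_correlation(eig, trait)
        assert mt["R"].iloc[0] == pytest.approx(1.0)

    def test_planted_trait_correlation_recovered(self):
        rng = np.random.default_rng(12)
        hits = 0
        target = -0.7
        for rep in range(20):
            n = 32
            trait_vec = np.tile([0.0, 1.0], n // 2)
            latent = target * (trait_vec - trait_vec.mean()) / (trait_vec.std() or 1)
            latent = latent + np.sqrt(1 - target**2) * rng.normal(size=n)
            eig = pd.DataFrame(
                [latent], index=["m"], columns=[f"s{j}" for j in range(n)]
            )
            trait = pd.Series(trait_vec, index=eig.columns)
            r = module_trait_correlation(eig, trait)["R"].iloc[0]
            hits += abs(r - target) <= 0.15
        assert hits >= 18

    def test_null_modules_rarely_significant(self):
        rng = np.random.default_rng(13)
        n = 30
        eig = pd.DataFrame(
            rng.normal(size=(40, n)),
            index=[f"m{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(n)],
        )
        trait = pd.Series(np.tile([0.0, 1.0], n // 2), index=eig.columns)
        mt = module_trait_correlation(eig, trait)
        assert mt["significant"].mean() <= 0.05


class TestModuleMembership:
    def test_eigengene_identical_gene_has_mm_one(self):
        rng = np.random.default_rng(14)
        em, _ = planted_blocks(rng, block_sizes=(15,), n_noise=5)
        from prepostx.coexpression import ModuleAssignment

        labels = pd.Series(UNASSIGNED, index=em.gene_ids, dtype=object)
        labels.iloc[:15] = "m"
        assignment = ModuleAssignment(labels=labels)
        eig = module_eigengenes(em, assignment)
        values = em.values.copy()
        values.loc["g_eig"] = eig.loc["m"].to_numpy()
        mm = module_membership(ExprMatrix(values), eig)
        assert mm.loc["g_eig", "m"] == pytest.approx(1.0, abs=1e-9)
        assert mm.to_numpy().min() >= -1 and mm.to_numpy().max() <= 1

    def test_trait_driven_module_links_mm_to_trait(self):
        rng = np.random.default_rng(15)
        n = 32
        trait_vec = np.tile([0.0, 1.0], n // 2)
        genes = (
            trait_vec[None, :] * rng.uniform(0.5, 1.5, (40, 1))
            + rng.normal(0, 0.8, (40, n))
        )
        em = ExprMatrix(
            pd.DataFrame(genes, index=[f"g{i:02d}" for i in range(40)],
                         columns=[f"s{j}" for j in range(n)])
        )
        from prepostx.coexpression import ModuleAssignment

        assignment = ModuleAssignment(labels=pd.Series("m", index=em.gene_ids))
        eig = module_eigengenes(em, assignment)
        mm = module_membership(em, eig)
        trait = pd.Series(trait_vec, index=em.sample_ids)
        gt = gene_trait_correlation(em, trait)
        link = mm_trait_link(mm, gt, assignment)
        assert link["R"].iloc[0] > 0.5

    def test_small_module_link_flagged_nan(self):
        from prepostx.coexpression import ModuleAssignment

        rng = np.random.default_rng(16)
        em = random_expr(rng, 2, 8)
        assignment = ModuleAssignment(labels=pd.Series("m", index=em.gene_ids))
        eig = module_eigengenes(em, assignment)
        mm = module_membership(em, eig)
        trait = pd.Series(np.tile([0.0, 1.0], 4), index=em.sample_ids)
        link = mm_trait_link(mm, gene_trait_correlation(em, trait), assignment)
        assert np.isnan(link["R"].iloc[0])


def test_module_enrichment_hypergeometric():
    from prepostx.coexpression import ModuleAssignment, module_enrichment
    from scipy.stats import hypergeom

    genes = [f"g{i:02d}" for i in range(40)]
    labels = pd.Series(UNASSIGNED, index=genes, dtype=object)
    labels.iloc[:10] = "m"
    assignment = ModuleAssignment(labels=labels)
    catalog = GeneSetCatalog()
    catalog.add("hit_set", "", genes[:8])         # 8 of 10 module genes
    catalog.add("null_set", "", genes[20:30])
    out = module_enrichment(assignment, catalog).set_index("set_name")
    expected = hypergeom.sf(8 - 1, 40, 8, 10)
    assert out.loc["hit_set", "pvalue"] == pytest.approx(expected, rel=1e-9)
    assert out.loc["hit_set", "pvalue"] < out.loc["null_set", "pvalue"]
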