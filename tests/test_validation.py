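"""The four validation statistics and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest

from sigvalid import (
    Block,
    DegenerateDataError,
    ExpressionMatrix,
    MatchError,
    SignatureTable,
    SignatureValidator,
    SyntheticDesign,
    coherence,
    explained_variance_profile,
    fit_pca,
    generate_dataset,
    make_signature,
    robustness,
    scale_genes,
    transferability,
    uniqueness,
    validate_signature,
)

from conftest import random_matrix


def equicorrelated_matrix(rng, k=10, rho=0.5, n=20000):
    f = rng.standard_normal(n)
    X = np.sqrt(rho) * np.outer(np.ones(k), f) + np.sqrt(1 - rho) * rng.standard_normal((k, n))
    return ExpressionMatrix(
        pd.DataFrame(X, index=[f"G{i}" for i in range(k)], columns=[f"S{j}" for j in range(n)])
    )


class TestStatistics:
    def test_coherence_of_independent_genes_approaches_100_over_k(self, rng):
        m = equicorrelated_matrix(rng, k=10, rho=0.0, n=20000)
        model = fit_pca(scale_genes(m), k=2)
        assert coherence(model) == pytest.approx(10.0, rel=0.05)

    def test_coherence_and_robustness_closed_forms(self, rng):
        # k equicorrelated genes: eigenvalues 1+(k-1)rho and 1-rho
        m = equicorrelated_matrix(rng, k=10, rho=0.5, n=20000)
        model = fit_pca(scale_genes(m), k=2)
        assert coherence(model) == pytest.approx(55.0, rel=0.02)
        assert robustness(model) == pytest.approx(11.0, rel=0.10)

    def test_robustness_near_one_for_two_equal_blocks(self):
        design = SyntheticDesign(
            n_samples=2000,
            n_background_genes=0,
            blocks=[Block(size=10, rho=0.5), Block(size=10, rho=0.5)],
            seed=3,
        )
        matrix, _ = generate_dataset(design)
        model = fit_pca(scale_genes(matrix), k=2)
        assert robustness(model) < 1.1  # lambda1 == lambda2 by symmetry

    def test_robustness_infinite_sentinel_for_rank_one(self, rng):
        base = rng.normal(size=10)
        X = np.vstack([base, 2 * base, -base])
        m = ExpressionMatrix(
            pd.DataFrame(X, index=list("abc"), columns=[f"S{j}" for j in range(10)])
        )
        with pytest.warns(RuntimeWarning):
            model = fit_pca(scale_genes(m), k=2)
        assert robustness(model) == np.inf

    def test_uniqueness_of_signature_equal_to_all_genes_is_one(self, rng):
        scaled = scale_genes(random_matrix(rng, 12, 15))
        model = fit_pca(scaled, k=2)
        assert uniqueness(model, model) == pytest.approx(1.0)

    def test_uniqueness_rejects_mismatched_samples(self, rng):
        a = fit_pca(scale_genes(random_matrix(rng, 8, 10)), k=2)
        b = fit_pca(scale_genes(random_matrix(rng, 8, 12)), k=2)
        with pytest.raises(Exception):
            uniqueness(a, b)

    def test_transferability_perfect_when_loadings_proportional(self, rng):
        model = fit_pca(scale_genes(random_matrix(rng, 8, 12)), k=2)
        assert transferability(model, 3.0 * model.loadings[:, 0]) == pytest.approx(1.0)

    def test_transferability_constant_reference_rejected(self, rng):
        model = fit_pca(scale_genes(random_matrix(rng, 8, 12)), k=2)
        with pytest.raises(DegenerateDataError, match="constant reference"):
            transferability(model, np.ones(8))

    def test_profile_truncates_and_is_non_increasing(self, rng):
        m = random_matrix(rng, 3, 12)  # only 3 components exist
        model = fit_pca(scale_genes(m), k=3)
        profile = explained_variance_profile(model)
        assert profile.size == 3
        assert np.all(np.diff(profile) <= 1e-9)

    def test_two_equal_blocks_show_scree_drop_after_pc2(self):
        design = SyntheticDesign(
            n_samples=500,
            n_background_genes=0,
            blocks=[Block(size=15, rho=0.6), Block(size=15, rho=0.6)],
            seed=5,
        )
        matrix, _ = generate_dataset(design)
        ev = explained_variance_profile(fit_pca(scale_genes(matrix), k=5))
        assert ev[1] / ev[2] > 2 * ev[0] / ev[1]


class TestValidateSignature:
    def test_planted_signature_beats_all_random_sets(self):
        design = SyntheticDesign(
            n_samples=150,
            n_background_genes=400,
            blocks=[Block(size=29, rho=0.5, factor="two-group")],
            seed=21,
        )
        matrix, manifest = generate_dataset(design)
        sig = make_signature(manifest, [0], name="planted29")
        report = validate_signature(matrix, sig, n_random=2000, seed=1)
        assert report.empirical_p["coherence"] <= 0.001
        assert report.empirical_p["robustness"] <= 0.001
        assert report.statistics.transferability_r2 > 0.8

    def test_disjoint_signature_error_names_signature(self, rng):
        m = random_matrix(rng, 10, 12)
        sig = SignatureTable([("zz1", 1.0), ("zz2", -1.0), ("zz3", 1.0)], name="lost")
        with pytest.raises(MatchError, match="lost"):
            validate_signature(m, sig, n_random=0)

    def test_same_seed_gives_byte_identical_reports(self):
        design = SyntheticDesign(
            n_samples=60,
            n_background_genes=80,
            blocks=[Block(size=10, rho=0.5)],
            seed=2,
        )
        matrix, manifest = generate_dataset(design)
        sig = make_signature(manifest, [0])
        a = validate_signature(matrix, sig, n_random=200, seed=9)
        b = validate_signature(matrix, sig, n_random=200, seed=9)
        assert a.to_text() == b.to_text()

    def test_validator_is_sklearn_parameterized(self):
        from sklearn.base import clone

        sig = SignatureTable([("a", 1.0), ("b", -1.0), ("c", 1.0)])
        v = SignatureValidator(signature=sig, n_random=10, seed=4)
        c = clone(v)
        assert c.get_params()["seed"] == 4
        assert c.get_params()["signature"] == sig

    def test_statistics_invariant_under_transformations(self):
        """Sample/gene permutation and positive row rescaling leave all four
        statistics unchanged (sign flips are covered by orientation tests)."""
        design = SyntheticDesign(
            n_samples=50,
            n_background_genes=60,
            blocks=[Block(size=8, rho=0.5)],
            seed=13,
        )
        matrix, manifest = generate_dataset(design)
        sig = make_signature(manifest, [0])
        base = validate_signature(matrix, sig, n_random=0).statistics.as_dict()

        rng = np.random.default_rng(0)
        variants = []
        variants.append(matrix.data.iloc[:, rng.permutation(matrix.n_samples)])
        variants.append(matrix.data.iloc[rng.permutation(matrix.n_genes), :])
        rescaled = matrix.data.mul(
            pd.Series(rng.uniform(0.5, 2.0, matrix.n_genes), index=matrix.data.index),
            axis=0,
        )
        variants.append(rescaled)
        for data in variants:
            got = validate_signature(
                ExpressionMatrix(data), sig, n_random=0
            ).statistics.as_dict()
            for name in base:
                assert got[name] == pytest.approx(base[name], abs=1e-9), name

    def test_mixed_signature_flagged_by_robustness(self):
        """Two orthogonal equal blocks merged: the signature is no longer a
        one-component model and the PC1/PC2 ratio collapses toward 1."""
        flagged = 0
        for seed in range(10):
            design = SyntheticDesign(
                n_samples=200,
                n_background_genes=100,
                blocks=[Block(size=15, rho=0.5), Block(size=15, rho=0.5)],
                seed=seed,
            )
            matrix, manifest = generate_dataset(design)
            mixed = make_signature(manifest, [0, 1], name="mixed")
            rep = validate_signature(matrix, mixed, n_random=0)
            if rep.statistics.robustness_ratio < 2:
                flagged += 1
        assert flagged >= 9

    def test_pc1_locks_to_dominant_block_at_imbalance(self):
        """With imbalanced block sizes the leading component describes the
        larger block alone, not a blend — the score correlates strongly with
        exactly one latent factor and switches across the balance point."""
        for seed in range(5):
            design = SyntheticDesign(
                n_samples=200,
                n_background_genes=100,
                blocks=[Block(size=18, rho=0.5), Block(size=12, rho=0.5)],
                seed=100 + seed,
            )
            matrix, manifest = generate_dataset(design)
            mixed = make_signature(manifest, [0, 1], name="mixed")
            validator = SignatureValidator(mixed, n_random=0).fit(matrix)
            t1 = validator.signature_model_.scores[:, 0]
            r_big = abs(np.corrcoef(t1, manifest.factors[0])[0, 1])
            r_small = abs(np.corrcoef(t1, manifest.factors[1])[0, 1])
            assert r_big > 0.9 and r_small < 0.9
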