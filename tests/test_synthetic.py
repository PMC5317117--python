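"""The planted-structure data generator."""

import numpy as np
import pytest

from sigvalid import (
    Block,
    SigvalidError,
    SyntheticDesign,
    fit_pca,
    generate_dataset,
    make_signature,
    scale_genes,
    validate_signature,
)


class TestGenerateDataset:
    def test_deterministic_given_seed(self):
        design = SyntheticDesign(
            n_samples=30, n_background_genes=20, blocks=[Block(5, 0.4)], seed=8
        )
        a, _ = generate_dataset(design)
        b, _ = generate_dataset(design)
        np.testing.assert_array_equal(a.values, b.values)

    def test_within_block_correlation_matches_rho(self):
        design = SyntheticDesign(
            n_samples=20000, n_background_genes=0, blocks=[Block(10, 0.5)], seed=1
        )
        matrix, manifest = generate_dataset(design)
        signs = manifest.genes["sign"].to_numpy()
        C = np.corrcoef(matrix.values) * np.outer(signs, signs)
        off = C[~np.eye(10, dtype=bool)]
        assert off.mean() == pytest.approx(0.5, abs=0.01)

    def test_pure_noise_has_no_structure(self):
        # rho=0, beta=0: 99% of pairwise |correlations| within the Fisher-z bound
        design = SyntheticDesign(n_samples=400, n_background_genes=60, seed=2)
        matrix, _ = generate_dataset(design)
        C = np.corrcoef(matrix.values)
        off = np.abs(C[~np.eye(60, dtype=bool)])
        assert (off < 4 / np.sqrt(400)).mean() > 0.99

    def test_two_group_factor_separates_groups_per_sign(self):
        design = SyntheticDesign(
            n_samples=400,
            n_background_genes=0,
            blocks=[Block(6, 0.8, factor="two-group")],
            seed=3,
        )
        matrix, manifest = generate_dataset(design)
        f = manifest.factors[0]
        groups = f > 0
        for gid, row in manifest.genes.iterrows():
            diff = matrix.data.loc[gid][groups].mean() - matrix.data.loc[gid][~groups].mean()
            assert np.sign(diff) == row["sign"]

    def test_bias_loads_requested_fraction(self):
        design = SyntheticDesign(
            n_samples=50,
            n_background_genes=200,
            blocks=[Block(10, 0.5)],
            bias_fraction=0.4,
            bias_strength=0.5,
            seed=4,
        )
        _, manifest = generate_dataset(design)
        assert manifest.genes["bias_loaded"].sum() == round(0.4 * 210)

    def test_invalid_design_rejected(self):
        with pytest.raises(SigvalidError):
            generate_dataset(SyntheticDesign(blocks=[Block(1, 0.5)]))
        with pytest.raises(SigvalidError):
            generate_dataset(SyntheticDesign(blocks=[Block(5, 1.0)]))


class TestMakeSignature:
    def design(self, seed=5):
        return SyntheticDesign(
            n_samples=50,
            n_background_genes=300,
            blocks=[Block(20, 0.5), Block(10, 0.4)],
            seed=seed,
        )

    def test_pure_block_signature(self):
        _, manifest = generate_dataset(self.design())
        sig = make_signature(manifest, [0], dilution=0.0)
        assert len(sig) == 20
        assert all(g.startswith("B0") for g in sig.gene_ids)

    def test_dilution_replaces_with_background(self):
        _, manifest = generate_dataset(self.design())
        sig = make_signature(manifest, [0], dilution=0.9)
        true_genes = [g for g in sig.gene_ids if g.startswith("B0")]
        noise_genes = [g for g in sig.gene_ids if g.startswith("BG")]
        assert len(sig) == 20
        assert len(true_genes) == 2 and len(noise_genes) == 18

    def test_append_mode_keeps_all_block_genes(self):
        _, manifest = generate_dataset(self.design())
        sig = make_signature(manifest, [0], dilution=0.5, mode="append")
        assert sum(g.startswith("B0") for g in sig.gene_ids) == 20
        assert len(sig) == 40

    def test_two_block_request_concatenates(self):
        _, manifest = generate_dataset(self.design())
        sig = make_signature(manifest, [0, 1])
        assert len(sig) == 30

    def test_heavy_dilution_warns_but_succeeds(self):
        _, manifest = generate_dataset(self.design())
        with pytest.warns(UserWarning, match="true signature genes"):
            make_signature(manifest, [1], dilution=0.9)  # 1 true gene left

    def test_loading_reference_uses_planted_loadings(self):
        _, manifest = generate_dataset(self.design())
        sig = make_signature(manifest, [0], reference="loading")
        np.testing.assert_allclose(np.abs(sig.reference_values), np.sqrt(0.5))


class TestQualitativeTrends:
    def test_coherence_and_robustness_degrade_monotonically_with_dilution(self):
        """Replacing signature genes with unrelated ones drives PC1 explained
        variance and the PC1/PC2 ratio down, monotonically in the median."""
        dilutions = [0.0, 0.5, 0.75, 0.9]
        med_coh, med_rob = [], []
        for d in dilutions:
            coh, rob = [], []
            for seed in range(10):
                design = SyntheticDesign(
                    n_samples=120,
                    n_background_genes=300,
                    blocks=[Block(30, 0.5)],
                    seed=seed,
                )
                matrix, manifest = generate_dataset(design)
                sig = make_signature(manifest, [0], dilution=d, seed=seed)
                rep = validate_signature(matrix, sig, n_random=0)
                coh.append(rep.statistics.coherence_pct)
                rob.append(rep.statistics.robustness_ratio)
            med_coh.append(np.median(coh))
            med_rob.append(np.median(rob))
        assert all(np.diff(med_coh) <= 0)
        assert all(np.diff(med_rob) <= 0)

    def test_global_bias_raises_null_uniqueness(self):
        """The stronger a dataset-wide bias direction, the more random
        gene-sets track the all-gene PC1 (the random-signatures phenomenon)."""
        from sigvalid import build_null

        means = []
        for beta in (0.0, 0.6):
            acc = []
            for seed in range(2):
                design = SyntheticDesign(
                    n_samples=100,
                    n_background_genes=300,
                    bias_fraction=0.5,
                    bias_strength=beta,
                    seed=seed,
                )
                matrix, _ = generate_dataset(design)
                scaled = scale_genes(matrix)
                allg = fit_pca(scaled, k=1)
                nulls = build_null(scaled, allg, set_size=20, n_random=300, seed=seed)
                acc.append(nulls["uniqueness"].mean)
            means.append(np.mean(acc))
        assert means[1] > means[0]
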