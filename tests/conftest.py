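import numpy as np
import pandas as pd
import pytest

from sigvalid import Block, ExpressionMatrix, SyntheticDesign, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n_genes=10, n_samples=20, prefix="G"):
    """A random ExpressionMatrix with log2-like values."""
    values = rng.normal(8.0, 1.5, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(n_genes)],
            columns=[f"S{j}" for j in range(n_samples)],
        )
    )


@pytest.fixture
def small_matrix(rng):
    return random_matrix(rng, n_genes=10, n_samples=20)


@pytest.fixture
def planted_dataset():
    """One strong 20-gene two-group block plus 200 background genes."""
    design = SyntheticDesign(
        n_samples=100,
        n_background_genes=200,
        blocks=[Block(size=20, rho=0.5, factor="two-group")],
        seed=7,
    )
    return generate_dataset(design)


@pytest.fixture
def tsv_matrix_file(tmp_path):
    path = tmp_path / "expr.tsv"
    lines = ["gene_id\tS1\tS2\tS3\tS4\tS5"]
    for i in range(4):
        vals = "\t".join(str(float(i + j)) for j in range(5))
        lines.append(f"G{i}\t{vals}")
    path.write_text("\n".join(lines) + "\n")
    return path
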