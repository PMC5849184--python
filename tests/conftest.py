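import numpy as np
import pytest

from coexkit.data_io import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 10 samples with exact linear dependences on the query.

    QRY is the query; POS is identical to it, NEG its negation (about the
    mean), FLAT constant.
    """
    rng = np.random.default_rng(7)
    q = rng.normal(8.0, 1.0, 10)
    return ExpressionMatrix(
        gene_ids=["QRY", "POS", "NEG", "FLAT"],
        sample_ids=[f"s{i}" for i in range(10)],
        values=np.vstack([q, q, 2 * q.mean() - q, np.full(10, 5.0)]),
    )


@pytest.fixture
def write_tsv(tmp_path):
    """Write a small expression TSV and return its path."""

    def _write(genes, samples, values, name="expr.tsv"):
        path = tmp_path / name
        lines = ["GENE\t" + "\t".join(samples)]
        for g, row in zip(genes, values):
            lines.append(g + "\t" + "\t".join(str(v) for v in row))
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
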