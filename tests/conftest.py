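import numpy as np
import pandas as pd
import pytest

from diseasomics.dataio import ExpressionMatrix
from diseasomics.deg import DEGSet


def make_degset(condition_id, up=(), down=(), nonsig=(), alpha=0.05, lfc=1.0):
    """Build a DEGSet with given significant up/down genes and extra tested genes."""
    rows = []
    for g in sorted(up):
        rows.append((g, 2.0, 8.0, 18.0, 1e-6, 1e-5, "up", True))
    for g in sorted(down):
        rows.append((g, -2.0, -8.0, 18.0, 1e-6, 1e-5, "down", True))
    for g in sorted(nonsig):
        rows.append((g, 0.1, 0.4, 18.0, 0.7, 0.9, "up", False))
    table = pd.DataFrame(
        rows, columns=["gene", "logFC", "t", "df", "p", "p_adj", "direction", "significant"]
    )
    return DEGSet(condition_id=condition_id, table=table, alpha=alpha, lfc=lfc)


def make_matrix(values, genes, samples, groups, condition_id="test", scale="raw"):
    data = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    return ExpressionMatrix(
        condition_id=condition_id, data=data, groups=dict(groups), scale=scale
    )


@pytest.fixture
def tiny_expression_files(tmp_path):
    """3-gene x 4-sample expression TSV plus a complete group map."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "gene\tS1\tS2\tS3\tS4\n"
        "tp53\t10\t12\t3\t4\n"
        "BRCA1\t5\t6\t5.5\t6.5\n"
        "EGFR\t100\t110\t90\t95\n"
    )
    groups = tmp_path / "groups.tsv"
    groups.write_text("S1\tcase\nS2\tcase\nS3\tcontrol\nS4\tcontrol\n")
    return expr, groups


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
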