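"""Differential expression calling.

Per gene, an unpaired two-sample Student t-test (pooled variance,
df = n1 + n2 - 2, two-sided p) compares case against control on the log2
scale.  p-values are adjusted with the Benjamini-Hochberg step-up procedure,
and a gene is a DEG when p_adj < alpha (default 0.05) and |log2 FC| > lfc
(default 1.0), both strict.  log2 FC is the difference of group means on the
log2 scale (case minus control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from diseasomics.dataio import DataError, ExpressionMatrix


class DegenerateGeneError(ValueError):
    """Zero pooled variance: the t statistic is undefined for this gene."""


def two_sample_t(case, control) -> tuple[float, float, float]:
    """Pooled-variance (Student) two-sample t-test, two-sided.

    Returns ``(t, df, p)`` with ``df = n1 + n2 - 2``.  Raises
    :class:`DegenerateGeneError` when the pooled variance is zero and
    ``ValueError`` when either group has fewer than two observations.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.ndim != 1 or control.ndim != 1:
        raise ValueError("two_sample_t expects 1-d vectors")
    if len(case) < 2 or len(control) < 2:
        raise ValueError(f"each group needs >=2 values (got {len(case)} vs {len(control)})")
    if not (np.isfinite(case).all() and np.isfinite(control).all()):
        raise ValueError("non-finite values in input")
    df = len(case) + len(control) - 2
    pooled = ((len(case) - 1) * case.var(ddof=1) + (len(control) - 1) * control.var(ddof=1)) / df
    if pooled == 0.0:
        if case.mean() == control.mean():
            raise DegenerateGeneError("both groups constant and equal; t undefined")
        raise DegenerateGeneError("zero pooled variance; t undefined")
    t, p = stats.ttest_ind(case, control, equal_var=True)
    return float(t), float(df), float(p)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-d vector of p-values")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGSet:
    """Per-condition DEG call: significant up/down sets plus the full table.

    ``table`` has one row per tested gene with columns gene, logFC, t, df, p,
    p_adj, direction, significant; ``degenerate`` lists zero-variance genes
    that could not be tested.
    """

    condition_id: str
    table: pd.DataFrame
    alpha: float
    lfc: float
    degenerate: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def up(self) -> frozenset[str]:
        m = self.table["significant"] & (self.table["direction"] == "up")
        return frozenset(self.table.loc[m, "gene"])

    @property
    def down(self) -> frozenset[str]:
        m = self.table["significant"] & (self.table["direction"] == "down")
        return frozenset(self.table.loc[m, "gene"])

    @property
    def degs(self) -> frozenset[str]:
        return self.up | self.down

    @property
    def tested_genes(self) -> frozenset[str]:
        return frozenset(self.table["gene"])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def call_degs(M: ExpressionMatrix, alpha: float = 0.05, lfc: float = 1.0) -> DEGSet:
    """Call up/down DEGs on a log2-scale matrix.

    Genes with zero pooled variance are excluded from testing and reported in
    ``DEGSet.degenerate``.  Significance requires p_adj < alpha AND
    |logFC| > lfc, strict on both sides.
    """
    if M.scale != "log2":
        raise DataError(f"call_degs expects scale=log2, got {M.scale!r}")
    if M.needs_collapse:
        raise DataError("matrix has uncollapsed duplicate-symbol probes; collapse first")
    if alpha <= 0 or lfc < 0:
        raise DataError("alpha must be positive and lfc non-negative")
    case = M.case_values().to_numpy(dtype=float)
    ctrl = M.control_values().to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError(f"need >=2 case and >=2 control samples (got {n1} vs {n2})")

    df = n1 + n2 - 2
    pooled = ((n1 - 1) * case.var(axis=1, ddof=1) + (n2 - 1) * ctrl.var(axis=1, ddof=1)) / df
    testable = pooled > 0
    degenerate = tuple(sorted(np.asarray(M.gene_ids)[~testable]))

    genes = np.asarray(M.gene_ids)[testable]
    case_t, ctrl_t = case[testable], ctrl[testable]
    if genes.size == 0:
        raise DataError("no testable genes (all rows have zero pooled variance)")

    logfc = case_t.mean(axis=1) - ctrl_t.mean(axis=1)
    se = np.sqrt(pooled[testable] * (1.0 / n1 + 1.0 / n2))
    t = logfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p_adj = benjamini_hochberg(p)

    table = pd.DataFrame(
        {
            "gene": genes,
            "logFC": logfc,
            "t": t,
            "df": float(df),
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(logfc > 0, "up", "down"),
            "significant": (p_adj < alpha) & (np.abs(logfc) > lfc),
        }
    )
    table = table.sort_values(["p_adj", "p", "gene"], kind="mergesort").reset_index(drop=True)
    return DEGSet(
        condition_id=M.condition_id,
        table=table,
        alpha=alpha,
        lfc=lfc,
        degenerate=degenerate,
    )
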