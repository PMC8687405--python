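"""Normalisation and probe collapsing.

Two normalisations are supported: log2 transformation of raw intensities and
per-gene z-scoring ((g - mean(g)) / SD(g), sample SD with n-1).  Differential
testing downstream operates on the log2 scale, because the |log2 FC| > 1
threshold is only meaningful there; z-scoring serves cross-dataset
comparison output.  A per-sample z-score variant exists behind ``axis``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from diseasomics.dataio import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

COLLAPSE_METHODS = ("max_abs_t", "mean")


def log2_transform(M: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Replace values by log2(value + offset); scale becomes ``log2``.

    Requires scale=raw and value + offset > 0 everywhere; the first offending
    gene/sample is named otherwise.
    """
    if M.scale != "raw":
        raise DataError(f"log2_transform expects scale=raw, got {M.scale!r}")
    if offset < 0:
        raise DataError(f"offset must be non-negative, got {offset}")
    vals = M.data.to_numpy(dtype=float) + offset
    if (vals <= 0).any():
        r, c = np.argwhere(vals <= 0)[0]
        raise DataError(
            f"non-positive value {M.data.iat[r, c]} + offset {offset} at gene "
            f"{M.data.index[r]!r}, sample {M.data.columns[c]!r}"
        )
    out = pd.DataFrame(np.log2(vals), index=M.data.index, columns=M.data.columns)
    return M.replace_values(out, scale="log2")


def zscore_rows(M: ExpressionMatrix, axis: str = "gene") -> ExpressionMatrix:
    """Z-score each gene row: (g - mean(g)) / SD(g), SD with the n-1 convention.

    Rows with zero variance cannot be z-scored; they are excluded from the
    output and listed in ``meta["zscore_excluded"]`` rather than NaN-filled.
    ``axis="sample"`` applies the same transform per column instead.
    """
    if axis not in ("gene", "sample"):
        raise DataError(f"axis must be 'gene' or 'sample', got {axis!r}")
    vals = M.data.to_numpy(dtype=float)
    if axis == "gene":
        if vals.shape[1] < 2:
            raise DataError("z-scoring needs at least 2 samples")
        sd = vals.std(axis=1, ddof=1)
        keep = sd > 0
        excluded = sorted(M.data.index[~keep])
        z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        out = pd.DataFrame(z, index=M.data.index[keep], columns=M.data.columns)
    else:
        if vals.shape[0] < 2:
            raise DataError("per-sample z-scoring needs at least 2 genes")
        sd = vals.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(M.data.columns[sd == 0])
            raise DataError(f"constant sample column(s): {bad}")
        excluded = []
        z = (vals - vals.mean(axis=0, keepdims=True)) / sd[None, :]
        out = pd.DataFrame(z, index=M.data.index, columns=M.data.columns)
    if out.empty:
        raise DataError("all rows were constant; nothing to z-score")
    if excluded:
        logger.info("%s: excluded %d constant row(s) from z-scoring", M.condition_id, len(excluded))
    res = M.replace_values(out, scale="zscore")
    res.meta["zscore_excluded"] = excluded
    return res


def default_probe_map(M: ExpressionMatrix) -> dict[str, str]:
    """Probe map implied by the matrix's own probe keys (SYMBOL@k -> SYMBOL)."""
    if M.probe_to_gene is not None:
        return dict(M.probe_to_gene)
    return {g: g for g in M.gene_ids}


def _row_abs_t(row: np.ndarray, case_idx: np.ndarray, ctrl_idx: np.ndarray) -> float:
    case, ctrl = row[case_idx], row[ctrl_idx]
    t, _ = stats.ttest_ind(case, ctrl, equal_var=True)
    return abs(t) if np.isfinite(t) else 0.0


def collapse_probes(
    M: ExpressionMatrix,
    probe_map: dict[str, str] | None = None,
    method: str = "max_abs_t",
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene symbol.

    ``max_abs_t`` keeps, for each symbol, the probe with the largest absolute
    pooled t statistic between case and control (needs >=2 samples per
    group); ``mean`` averages the probe rows.  Probes absent from the map are
    dropped with a logged count.
    """
    if method not in COLLAPSE_METHODS:
        raise DataError(f"unknown collapse method {method!r}; expected one of {COLLAPSE_METHODS}")
    pm = probe_map if probe_map is not None else default_probe_map(M)
    for probe, sym in pm.items():
        if not sym:
            raise DataError(f"probe {probe!r} maps to an empty symbol")

    mapped = [p for p in M.gene_ids if p in pm]
    dropped = len(M.gene_ids) - len(mapped)
    if dropped:
        logger.info("%s: dropped %d probe(s) absent from the probe map", M.condition_id, dropped)
    if not mapped:
        raise DataError("no probes left after applying the probe map")

    sub = M.data.loc[mapped]
    symbols = pd.Index([pm[p].upper() for p in mapped], name="gene")

    if method == "mean":
        out = sub.groupby(symbols, sort=True).mean()
    else:
        samples = list(M.data.columns)
        case_idx = np.array([i for i, s in enumerate(samples) if M.groups[s] == "case"])
        ctrl_idx = np.array([i for i, s in enumerate(samples) if M.groups[s] == "control"])
        if len(case_idx) < 2 or len(ctrl_idx) < 2:
            raise DataError("max_abs_t collapsing needs >=2 case and >=2 control samples")
        vals = sub.to_numpy(dtype=float)
        scores = np.array([_row_abs_t(vals[i], case_idx, ctrl_idx) for i in range(len(mapped))])
        frame = pd.DataFrame({"probe": mapped, "symbol": symbols, "score": scores})
        # deterministic tie-break: highest |t|, then probe key
        frame = frame.sort_values(["symbol", "score", "probe"], ascending=[True, False, True])
        keep = frame.drop_duplicates("symbol", keep="first")
        out = sub.loc[keep["probe"]]
        out.index = pd.Index(keep["symbol"], name="gene")
        out = out.sort_index()

    res = ExpressionMatrix(
        condition_id=M.condition_id,
        data=out,
        groups=dict(M.groups),
        scale=M.scale,
        probe_to_gene=None,
        meta=dict(M.meta),
    )
    res.meta["probes_dropped"] = dropped
    return res
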