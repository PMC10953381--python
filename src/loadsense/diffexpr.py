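"""Per-gene contrasts and gene-set overrepresentation.

The contrast compares two sample groups gene by gene: the log2 fold change is
a difference of group means (on log2 scale; count input is pseudocounted and
log2-transformed first), the p-value comes from Welch's unequal-variance
t-test, and multiplicity is handled by Benjamini-Hochberg.  A gene is called
differentially expressed (DEG) when |lfc| exceeds the fold-change threshold
and the (by default adjusted) p falls below alpha — defaults 1 and 0.05.

This is deliberately a light-weight location test, not a negative-binomial
GLM: count-model dispersion estimation is a job for dedicated differential
expression packages, and :func:`load_deg_table` accepts their output so a
real-data run can plug published DEG tables straight in.

Overrepresentation of gene sets among the DEGs uses the one-sided Fisher
exact test (hypergeometric upper tail) with, by default, Bonferroni
correction across the sets tested.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import GeneSetCollection
from .preprocess import ExpressionMatrix, LoadsenseError, validate_sample_table

#: default DEG thresholds
LFC_THRESHOLD = 1.0
ALPHA = 0.05


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise LoadsenseError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contrast_genes(
    expr: ExpressionMatrix | pd.DataFrame,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    *,
    input_kind: Literal["expression", "counts"] = "expression",
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Per-gene contrast of condition ``group_a`` against ``group_b``.

    Returns a DataFrame with columns gene_id, lfc, p_raw, p_adj, is_deg and
    attrs recording the thresholds.  ``lfc`` is mean(group_a) - mean(group_b)
    on log2 scale; for ``input_kind="counts"`` the matrix is transformed to
    log2(count + 1) first.  ``adjusted`` selects whether the alpha cut
    applies to the BH-adjusted or the raw p.
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else expr
    validate_sample_table(samples)
    ids_a = samples.loc[samples["condition"] == group_a, "sample_id"]
    ids_b = samples.loc[samples["condition"] == group_b, "sample_id"]
    ids_a = [s for s in ids_a if s in data.columns]
    ids_b = [s for s in ids_b if s in data.columns]
    for name, ids in ((group_a, ids_a), (group_b, ids_b)):
        if len(ids) < 2:
            raise LoadsenseError(
                f"group {name!r} has {len(ids)} samples in the matrix; need >= 2"
            )
    a = data[ids_a].to_numpy(dtype=float)
    b = data[ids_b].to_numpy(dtype=float)
    if input_kind == "counts":
        a = np.log2(a + 1.0)
        b = np.log2(b + 1.0)
    elif input_kind != "expression":
        raise LoadsenseError(f"unknown input_kind {input_kind!r}")

    lfc = a.mean(axis=1) - b.mean(axis=1)
    t_res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p_raw = np.asarray(t_res.pvalue, dtype=float)
    # Welch's p is undefined for genes with zero variance in both groups;
    # identical means there mean no evidence, different means certainty.
    degenerate = ~np.isfinite(p_raw)
    p_raw[degenerate & (lfc == 0)] = 1.0
    p_raw[degenerate & (lfc != 0)] = 0.0
    p_adj = bh_adjust(p_raw)
    p_for_cut = p_adj if adjusted else p_raw
    is_deg = (np.abs(lfc) > lfc_threshold) & (p_for_cut < alpha)
    table = pd.DataFrame(
        {
            "gene_id": list(data.index),
            "lfc": lfc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "is_deg": is_deg,
        }
    )
    table.attrs["lfc_threshold"] = lfc_threshold
    table.attrs["alpha"] = alpha
    table.attrs["alpha_on_adjusted"] = adjusted
    table.attrs["contrast"] = (group_a, group_b)
    return table


def enrich_sets(
    deg_genes: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    alpha: float = 0.01,
    correction: Literal["bonferroni", "bh"] = "bonferroni",
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of each gene set among the DEGs.

    Each set is intersected with the background before testing.  p_raw is the
    hypergeometric upper tail P(overlap >= observed); the multiplicity
    correction (Bonferroni by default, BH as the alternative reading) is
    applied across the sets tested, and ``selected`` marks p_adj < alpha.
    """
    background = set(background)
    degs = set(deg_genes)
    if not background:
        raise LoadsenseError("background gene set is empty")
    if not degs:
        raise LoadsenseError("DEG list is empty")
    if not degs <= background:
        raise LoadsenseError("DEG list must be a subset of the background")

    n_bg = len(background)
    n_deg = len(degs)
    rows = []
    for name, members in sets.items():
        in_bg = members & background
        if not in_bg:
            continue
        overlap = len(in_bg & degs)
        # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=|set|, n=n_deg)
        p_raw = float(stats.hypergeom.sf(overlap - 1, n_bg, len(in_bg), n_deg))
        rows.append((name, overlap, len(in_bg), 100.0 * overlap / len(in_bg), p_raw))
    table = pd.DataFrame(
        rows,
        columns=["set_name", "overlap_count", "set_size", "matched_percentage", "p_raw"],
    )
    if table.empty:
        table["p_adj"] = []
        table["selected"] = []
        return table
    if correction == "bonferroni":
        table["p_adj"] = np.minimum(1.0, table["p_raw"] * len(table))
    elif correction == "bh":
        table["p_adj"] = bh_adjust(table["p_raw"])
    else:
        raise LoadsenseError(f"unknown correction {correction!r}")
    table["selected"] = table["p_adj"] < alpha
    table.attrs["alpha"] = alpha
    table.attrs["correction"] = correction
    return table.sort_values("p_raw", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_deg_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def load_deg_table(path: str | Path) -> pd.DataFrame:
    """Load an externally computed DEG table (gene_id, lfc, p_adj[, p_raw]).

    Accepts published differential-expression output so real-data runs can
    reuse it.  Missing columns are filled: p_raw defaults to p_adj, is_deg is
    recomputed from the default thresholds if absent.
    """
    path = Path(path)
    if not path.exists():
        raise LoadsenseError(f"DEG table not found: {path}")
    table = pd.read_csv(path)
    required = {"gene_id", "lfc", "p_adj"}
    missing = required - set(table.columns)
    if missing:
        raise LoadsenseError(f"DEG table missing columns: {sorted(missing)}")
    if "p_raw" not in table.columns:
        table["p_raw"] = table["p_adj"]
    if "is_deg" not in table.columns:
        table["is_deg"] = (table["lfc"].abs() > LFC_THRESHOLD) & (table["p_adj"] < ALPHA)
        table.attrs["lfc_threshold"] = LFC_THRESHOLD
        table.attrs["alpha"] = ALPHA
    table["gene_id"] = table["gene_id"].astype(str)
    return table


def write_enrichment_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")
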