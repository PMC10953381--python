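"""Panel aggregation and prioritization.

Repeated runs of the four feature-selection models (RFE/RGIFE x RF/SVM)
produce many candidate biomarker panels.  Three criteria rank them:

* **f1** — outer stratified 10-fold cross-validated f1 of the load-stress
  class using only the panel's genes;
* **occurrence** — how many independent runs (across models) returned the
  exact same gene set, a stability measure;
* **margin** — the signed minimal Euclidean distance between load-stress and
  other samples in the panel's expression subspace.  The distance for a
  sample pair is counted negative when the pair's per-gene expression
  differences contradict the class-mean direction, so a negative margin
  flags classes that interleave along the panel's axes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .featsel import (
    LINEAR_SVM,
    RANDOM_FOREST,
    CVConfig,
    ClassifierSpec,
    rfe,
    rgife,
)
from .preprocess import ExpressionMatrix, LoadsenseError, validate_sample_table

_SEED_BOUND = 2**31 - 1

MODEL_LABELS = {
    ("rfe", RANDOM_FOREST): "RFE-RF",
    ("rfe", LINEAR_SVM): "RFE-SVM",
    ("rgife", RANDOM_FOREST): "RGIFE-RF",
    ("rgife", LINEAR_SVM): "RGIFE-SVM",
}


@dataclass
class PanelRecord:
    """A candidate biomarker gene set with its selection provenance."""

    genes: frozenset[str]
    model_names: list[str]
    occurrence: int
    f1: float
    f1_sd: float = math.nan
    margin: float = math.nan

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class EnsembleConfig:
    """How many runs of each selection model to execute.

    The reference study ran RFE at each target size 2-6 for 100 repetitions
    and RGIFE 1000 times, keeping RGIFE panels of size 2-6; these are the
    defaults.  Scale ``rfe_repetitions`` / ``rgife_repetitions`` down for
    desk-size experiments.
    """

    rfe_sizes: tuple[int, ...] = (2, 3, 4, 5, 6)
    rfe_repetitions: int = 100
    rgife_repetitions: int = 1000
    size_retention: tuple[int, int] = (2, 6)
    base_seed: int = 0

    def validate(self) -> None:
        if self.rfe_repetitions < 0 or self.rgife_repetitions < 0:
            raise LoadsenseError("repetition counts must be non-negative")
        lo, hi = self.size_retention
        if lo > hi or lo < 1:
            raise LoadsenseError("invalid size retention range")


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

def _design_matrix(
    expr: ExpressionMatrix, samples: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """samples x genes matrix, load-stress labels, gene ids (column order)."""
    validate_sample_table(samples)
    meta = samples.set_index("sample_id").loc[expr.sample_ids]
    X = expr.values.T
    y = meta["is_loadstress"].to_numpy().astype(int)
    return X, y, expr.gene_ids


def run_ensemble(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    config: EnsembleConfig,
    classifiers: Sequence[ClassifierSpec] = (
        ClassifierSpec(RANDOM_FOREST),
        ClassifierSpec(LINEAR_SVM),
    ),
    cv: CVConfig = CVConfig(),
    rfe_step: int = 2,
) -> list[PanelRecord]:
    """Run the selection ensemble and aggregate panels into records.

    Every individual run gets seed ``base_seed + run_index``; identical gene
    sets from different runs collapse into a single record whose occurrence
    counts the producing runs and whose model names merge.  Each unique panel
    is then scored once by outer stratified CV f1 (mean and sd over folds).
    """
    config.validate()
    X, y, gene_ids = _design_matrix(expr, samples)
    lo, hi = config.size_retention
    selections: list[tuple[frozenset[str], str]] = []
    run_index = 0
    for clf in classifiers:
        for size in config.rfe_sizes:
            for _ in range(config.rfe_repetitions):
                seed = (config.base_seed + run_index) % _SEED_BOUND
                run_index += 1
                idx = rfe(X, y, clf, cv, n_select=size, step=rfe_step, seed=seed)
                selections.append(
                    (frozenset(gene_ids[i] for i in idx), MODEL_LABELS[("rfe", clf.kind)])
                )
    for clf in classifiers:
        for _ in range(config.rgife_repetitions):
            seed = (config.base_seed + run_index) % _SEED_BOUND
            run_index += 1
            idx, _trace = rgife(X, y, clf, cv, seed=seed)
            if lo <= idx.size <= hi:
                selections.append(
                    (frozenset(gene_ids[i] for i in idx), MODEL_LABELS[("rgife", clf.kind)])
                )

    counted = occurrence_count(selections)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    records = []
    for genes, (occurrence, labels) in sorted(
        counted.items(), key=lambda kv: sorted(kv[0])
    ):
        cols = [gene_pos[g] for g in sorted(genes)]
        mean_f1, sd_f1 = outer_cv_f1(
            X[:, cols], y, classifiers[0], cv, seed=config.base_seed
        )
        records.append(
            PanelRecord(
                genes=genes,
                model_names=sorted(labels),
                occurrence=occurrence,
                f1=mean_f1,
                f1_sd=sd_f1,
            )
        )
    return records


def outer_cv_f1(
    X: np.ndarray,
    y: np.ndarray,
    clf: ClassifierSpec,
    cv: CVConfig,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and sd of per-fold f1 for a fixed panel (outer evaluation)."""
    from sklearn.metrics import f1_score
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=seed % _SEED_BOUND)
    scores = []
    for k, (train, test) in enumerate(skf.split(X, y)):
        model = clf.build(seed=(seed + k) % _SEED_BOUND)
        model.fit(X[train], y[train])
        scores.append(f1_score(y[test], model.predict(X[test]), pos_label=1, zero_division=0))
    return float(np.mean(scores)), float(np.std(scores, ddof=1))


def occurrence_count(
    panels: Iterable[tuple[frozenset[str] | Iterable[str], str]],
) -> dict[frozenset[str], tuple[int, set[str]]]:
    """Count identical unordered gene sets across runs and models."""
    out: dict[frozenset[str], tuple[int, set[str]]] = {}
    for genes, label in panels:
        key = frozenset(genes)
        count, labels = out.get(key, (0, set()))
        labels.add(label)
        out[key] = (count + 1, labels)
    return out


# ---------------------------------------------------------------------------
# Margin
# ---------------------------------------------------------------------------

def margin(
    expr: ExpressionMatrix,
    panel: Iterable[str],
    labels: Sequence[bool] | np.ndarray,
    sign_rule: Literal["strict", "product"] = "strict",
) -> float:
    """Signed minimal Euclidean class distance in the panel's subspace.

    For every pair (i in load-stress, j in other) the distance is the
    Euclidean norm of the panel-gene expression difference.  Under the
    default ``strict`` rule the pair is positive only when *every* panel
    gene's difference has the same (non-zero) sign as the class-mean
    difference for that gene; otherwise the distance enters negatively.  The
    ``product`` rule instead multiplies the per-gene sign agreements, so an
    even number of disagreements still counts positive.  The margin is the
    minimum of the signed distances over all pairs.
    """
    panel = list(panel)
    missing = [g for g in panel if g not in expr.data.index]
    if missing:
        raise LoadsenseError(f"panel genes absent from expression matrix: {missing}")
    labels = np.asarray(labels, dtype=bool)
    if labels.shape[0] != len(expr.sample_ids):
        raise LoadsenseError("labels must align with expression samples")
    if not labels.any() or labels.all():
        raise LoadsenseError("both classes must be non-empty")

    sub = expr.data.loc[panel].to_numpy()  # panel genes x samples
    XI = sub[:, labels].T  # load-stress samples x genes
    XJ = sub[:, ~labels].T  # other samples x genes
    mean_dir = np.sign(XI.mean(axis=0) - XJ.mean(axis=0))  # per gene

    diff = XI[:, None, :] - XJ[None, :, :]  # i x j x gene
    dist = np.sqrt((diff**2).sum(axis=2))
    pair_signs = np.sign(diff)
    agree = pair_signs == mean_dir[None, None, :]
    nonzero = (pair_signs != 0) & (mean_dir[None, None, :] != 0)
    if sign_rule == "strict":
        positive = (agree & nonzero).all(axis=2)
    elif sign_rule == "product":
        # literal product form: prod_k sgn(mean)*sgn(pair) == 1
        prod = np.prod(pair_signs * mean_dir[None, None, :], axis=2)
        positive = prod == 1
    else:
        raise LoadsenseError(f"unknown sign rule {sign_rule!r}")
    signed = np.where(positive, dist, -dist)
    return float(signed.min())


# ---------------------------------------------------------------------------
# Shortlist, growth correlation, size study
# ---------------------------------------------------------------------------

def shortlist(
    records: Sequence[PanelRecord],
    f1_min: float = 0.98,
    margin_min: float = 0.1,
) -> pd.DataFrame:
    """Retain records with f1 > f1_min and margin > margin_min, ranked.

    Sort: margin descending, ties by f1 descending, then lexicographic gene
    ids.  Columns mirror the published shortlist layout with genes joined by
    ";".
    """
    rows = []
    for rec in records:
        if rec.f1 > f1_min and rec.margin > margin_min:
            rows.append(
                {
                    "genes": ";".join(sorted(rec.genes)),
                    "model_names": ";".join(rec.model_names),
                    "occurrence": rec.occurrence,
                    "f1": rec.f1,
                    "margin": rec.margin,
                }
            )
    table = pd.DataFrame(rows, columns=["genes", "model_names", "occurrence", "f1", "margin"])
    if table.empty:
        return table
    return table.sort_values(
        by=["margin", "f1", "genes"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)


class GrowthCorrelation(NamedTuple):
    r: float
    p: float
    reason: str | None = None


def growth_correlation(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    gene: str,
) -> GrowthCorrelation:
    """Pearson r and two-sided p of gene expression vs growth rate.

    Computed over load-stress samples with a growth-rate measurement only.
    Returns NaN with a reason code when either variable is constant.
    """
    validate_sample_table(samples)
    if gene not in expr.data.index:
        raise LoadsenseError(f"gene {gene!r} absent from expression matrix")
    meta = samples[samples["is_loadstress"].astype(bool)].dropna(subset=["growth_rate"])
    meta = meta[meta["sample_id"].isin(set(expr.sample_ids))]
    if len(meta) < 3:
        raise LoadsenseError(
            f"need >= 3 load-stress samples with growth rates, have {len(meta)}"
        )
    x = expr.data.loc[gene, meta["sample_id"]].to_numpy(dtype=float)
    g = meta["growth_rate"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return GrowthCorrelation(math.nan, math.nan, "constant_expression")
    if np.ptp(g) == 0:
        return GrowthCorrelation(math.nan, math.nan, "constant_growth")
    res = stats.pearsonr(x, g)
    return GrowthCorrelation(float(res.statistic), float(res.pvalue), None)


def panel_size_study(records: Sequence[PanelRecord]) -> pd.DataFrame:
    """Per panel-size (and per model, plus pooled) f1 distribution summary."""
    rows = []
    for rec in records:
        for model in rec.model_names:
            rows.append({"size": rec.size, "model": model, "f1": rec.f1})
        rows.append({"size": rec.size, "model": "all", "f1": rec.f1})
    if not rows:
        return pd.DataFrame(columns=["size", "model", "count", "median", "q1", "q3"])
    long = pd.DataFrame(rows)
    summary = (
        long.groupby(["size", "model"])["f1"]
        .agg(
            count="count",
            median="median",
            q1=lambda s: float(np.percentile(s, 25)),
            q3=lambda s: float(np.percentile(s, 75)),
        )
        .reset_index()
    )
    return summary


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_records_jsonl(records: Sequence[PanelRecord], path: str | Path) -> None:
    lines = []
    for rec in records:
        lines.append(
            json.dumps(
                {
                    "genes": sorted(rec.genes),
                    "model_names": rec.model_names,
                    "occurrence": rec.occurrence,
                    "f1": rec.f1,
                    "f1_sd": None if math.isnan(rec.f1_sd) else rec.f1_sd,
                    "margin": None if math.isnan(rec.margin) else rec.margin,
                }
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_records_jsonl(path: str | Path) -> list[PanelRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        records.append(
            PanelRecord(
                genes=frozenset(obj["genes"]),
                model_names=list(obj["model_names"]),
                occurrence=int(obj["occurrence"]),
                f1=float(obj["f1"]),
                f1_sd=math.nan if obj.get("f1_sd") is None else float(obj["f1_sd"]),
                margin=math.nan if obj.get("margin") is None else float(obj["margin"]),
            )
        )
    return records
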