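"""Regulon and iModulon activity quantification.

Two condition-level indices summarize how strongly a gene group responds to a
perturbation:

* **percentage index** — the fraction of the condition's differentially
  expressed genes (DEGs) that fall inside the group:
  ``|group ∩ DEGs| / |DEGs|``.
* **intensity index** — for a regulon, the mean log2 fold change of the DEGs
  overlapping it; for an iModulon, the change in its activity (the difference
  of mean activity between the condition samples and the reference samples,
  activities already living on a log-derived scale).

Both indices are undefined (reported as missing, never 0) when their
denominator or overlap is empty: an intensity of 0 is a meaningful "no net
change" and must stay distinguishable from "nothing to average".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .preprocess import LoadsenseError

#: recognized gene-set kinds
SET_KINDS = ("regulon", "imodulon", "go")


@dataclass
class GeneSetCollection:
    """Named gene sets with a kind tag (regulon | imodulon | go) per set."""

    sets: dict[str, frozenset[str]]
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise LoadsenseError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)
        for name in self.sets:
            kind = self.kinds.setdefault(name, "regulon")
            if kind not in SET_KINDS:
                raise LoadsenseError(f"unknown gene-set kind {kind!r} for {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self) -> Iterable[tuple[str, frozenset[str]]]:
        return self.sets.items()

    def of_kind(self, kind: str) -> "GeneSetCollection":
        names = [n for n in self.sets if self.kinds[n] == kind]
        return GeneSetCollection(
            {n: self.sets[n] for n in names}, {n: kind for n in names}
        )


@dataclass
class IModulonModel:
    """Planted or inferred decomposition X = M @ A.

    ``weights`` (M) is genes x iModulons, ``activities`` (A) is iModulons x
    samples; labels must align with the expression matrix and sample table.
    """

    weights: pd.DataFrame
    activities: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.weights.columns) != list(self.activities.index):
            raise LoadsenseError("iModulon labels of M columns and A rows disagree")


# ---------------------------------------------------------------------------
# Index operations
# ---------------------------------------------------------------------------

def percentage_index(gene_set: Iterable[str], degs: Iterable[str]) -> float:
    """Fraction of the DEG list captured by ``gene_set``; NaN if no DEGs."""
    degs = set(degs)
    if not degs:
        return math.nan
    return len(set(gene_set) & degs) / len(degs)


def regulon_intensity(gene_set: Iterable[str], deg_table: pd.DataFrame) -> float:
    """Mean lfc over the DEGs inside ``gene_set``; NaN if the overlap is empty.

    ``deg_table`` is the per-gene contrast table with columns gene_id, lfc,
    is_deg (see :mod:`loadsense.diffexpr`).
    """
    deg_rows = deg_table[deg_table["is_deg"].astype(bool)]
    overlap = deg_rows[deg_rows["gene_id"].isin(set(gene_set))]
    if overlap.empty:
        return math.nan
    return float(overlap["lfc"].mean())


def imodulon_intensity(
    model: IModulonModel,
    condition_samples: Sequence[str],
    reference_samples: Sequence[str],
) -> pd.Series:
    """Activity change per iModulon: mean A over condition minus reference."""
    if len(condition_samples) == 0 or len(reference_samples) == 0:
        raise LoadsenseError("both sample groups must be non-empty")
    known = set(model.activities.columns)
    unknown = [s for s in [*condition_samples, *reference_samples] if s not in known]
    if unknown:
        raise LoadsenseError(f"unknown sample ids in activity matrix: {unknown}")
    cond = model.activities[list(condition_samples)].mean(axis=1)
    ref = model.activities[list(reference_samples)].mean(axis=1)
    return cond - ref


def build_activity_table(
    sets: GeneSetCollection,
    deg_tables: Mapping[str, pd.DataFrame],
    model: IModulonModel | None = None,
    condition_samples: Mapping[str, Sequence[str]] | None = None,
    reference_samples: Mapping[str, Sequence[str]] | None = None,
    report_threshold: float = 0.3,
    report_condition: str = "load_stress",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute both indices for every set x condition.

    ``deg_tables`` maps condition name -> DEG table for the contrast of that
    condition against its reference.  For iModulon-kind sets whose name
    matches a column of ``model.weights``, the intensity is the activity
    change computed from ``model`` (requires the per-condition sample groups);
    all other sets use the mean-lfc regulon form.

    Returns ``(full_table, report_view)``: the full long-format table and the
    reporting view keeping sets whose percentage index in ``report_condition``
    exceeds ``report_threshold``.
    """
    rows = []
    for condition, deg_table in deg_tables.items():
        degs = set(deg_table.loc[deg_table["is_deg"].astype(bool), "gene_id"])
        imod_change: pd.Series | None = None
        if model is not None and condition_samples and reference_samples:
            if condition in condition_samples and condition in reference_samples:
                imod_change = imodulon_intensity(
                    model,
                    condition_samples[condition],
                    reference_samples[condition],
                )
        for name, members in sets.items():
            kind = sets.kinds[name]
            pct = percentage_index(members, degs)
            if kind == "imodulon" and imod_change is not None and name in imod_change.index:
                intensity = float(imod_change[name])
            else:
                intensity = regulon_intensity(members, deg_table)
            rows.append((name, kind, condition, pct, intensity))
    full = pd.DataFrame(
        rows, columns=["set_name", "kind", "condition", "percentage", "intensity"]
    )
    in_report = full[
        (full["condition"] == report_condition)
        & (full["percentage"] > report_threshold)
    ]["set_name"]
    report = full[full["set_name"].isin(set(in_report))].reset_index(drop=True)
    return full, report


def write_activity_csv(table: pd.DataFrame, path) -> None:
    """Write the long-format activity table; undefined intensities as empty cells."""
    table.to_csv(path, index=False, float_format="%.10g", na_rep="")
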