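"""Compendium containers, file I/O and study-specific reference normalization.

A multi-study RNA-seq compendium mixes experiments run in different labs on
different base media, so absolute log-TPM values carry strong per-study
offsets.  Before any cross-study classification, each sample is re-expressed
relative to its own study's reference (control) condition: the per-gene mean
of the study's reference samples is subtracted from every sample of that
study.  After this step a value of 0 means "expressed like the study's
control", and values are comparable across studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("loadsense")

#: scale tags for ExpressionMatrix
LOG_TPM = "log_tpm"
NORMALIZED = "normalized"

#: required columns of a sample table
SAMPLE_COLUMNS = (
    "sample_id",
    "study_id",
    "condition",
    "is_reference",
    "is_loadstress",
    "growth_rate",
)


class LoadsenseError(RuntimeError):
    """Raised for contract violations anywhere in the pipeline."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix with a scale tag.

    ``data`` is a pandas DataFrame whose index holds unique gene ids and
    whose columns hold unique sample ids.  ``scale`` is :data:`LOG_TPM` for
    raw log-TPM input and :data:`NORMALIZED` after reference subtraction.
    """

    data: pd.DataFrame
    scale: str = LOG_TPM

    def __post_init__(self) -> None:
        if self.scale not in (LOG_TPM, NORMALIZED):
            raise LoadsenseError(f"unknown scale tag {self.scale!r}")
        if self.data.index.has_duplicates:
            raise LoadsenseError("duplicate gene ids in expression matrix")
        if self.data.columns.has_duplicates:
            raise LoadsenseError("duplicate sample ids in expression matrix")
        values = self.data.to_numpy()
        if values.size and not np.all(np.isfinite(values)):
            raise LoadsenseError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-table schema and invariants; return the table.

    Required columns: sample_id, study_id, condition, is_reference,
    is_loadstress, growth_rate (growth_rate may be NaN for samples without a
    measurement).  A reference sample can never carry the load-stress label.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise LoadsenseError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
        raise LoadsenseError(f"duplicate sample ids: {sorted(set(dupes))}")
    bad = samples["is_reference"].astype(bool) & samples["is_loadstress"].astype(bool)
    if bad.any():
        raise LoadsenseError(
            "reference samples cannot be load-stress samples: "
            f"{sorted(samples.loc[bad, 'sample_id'])}"
        )
    return samples


# ---------------------------------------------------------------------------
# Reference selection and normalization
# ---------------------------------------------------------------------------

def select_reference_samples(
    samples: pd.DataFrame,
    fallback: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, list[str]]:
    """Map each study to its reference (control) sample ids.

    Studies with flagged ``is_reference`` samples use those; studies without
    flags fall back to an explicit study -> samples mapping (the "samples
    grown with least environmental changes").  A study with neither aborts.
    """
    if samples.empty:
        raise LoadsenseError("sample table is empty")
    validate_sample_table(samples)
    fallback = dict(fallback or {})
    refs: dict[str, list[str]] = {}
    missing: list[str] = []
    for study_id, group in samples.groupby("study_id", sort=True):
        flagged = group.loc[group["is_reference"].astype(bool), "sample_id"].tolist()
        if flagged:
            refs[str(study_id)] = flagged
        elif study_id in fallback:
            fb = list(fallback[study_id])
            known = set(group["sample_id"])
            unknown = [s for s in fb if s not in known]
            if unknown:
                raise LoadsenseError(
                    f"fallback reference samples {unknown} do not belong to study {study_id}"
                )
            refs[str(study_id)] = fb
        else:
            missing.append(str(study_id))
    if missing:
        raise LoadsenseError(
            f"studies with no flagged controls and no fallback entry: {missing}"
        )
    return refs


def normalize_by_reference(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    refs: Mapping[str, Sequence[str]],
) -> ExpressionMatrix:
    """Subtract each study's mean reference expression from its samples.

    output(g, s) = expr(g, s) - mean_{r in refs[study(s)]} expr(g, r)

    Means are arithmetic means on the log scale.  Gene and sample order are
    preserved; the result carries the :data:`NORMALIZED` tag.  Samples whose
    study is absent from the expression matrix are ignored with a warning
    (metadata supersets are tolerated); a reference id missing from the
    matrix aborts.
    """
    validate_sample_table(samples)
    in_matrix = set(expr.sample_ids)
    meta = samples[samples["sample_id"].isin(in_matrix)]
    dropped = len(samples) - len(meta)
    if dropped:
        logger.warning("ignoring %d metadata samples absent from expression matrix", dropped)
    unknown = in_matrix - set(meta["sample_id"])
    if unknown:
        raise LoadsenseError(f"expression samples missing from metadata: {sorted(unknown)}")

    study_of = dict(zip(meta["sample_id"], meta["study_id"]))
    studies_present = sorted(set(study_of.values()))
    uncovered = [s for s in studies_present if s not in refs]
    if uncovered:
        raise LoadsenseError(f"reference map does not cover studies: {uncovered}")

    out = expr.data.copy()
    for study in studies_present:
        ref_ids = list(refs[study])
        bad = [r for r in ref_ids if r not in in_matrix]
        if bad:
            raise LoadsenseError(
                f"reference samples {bad} of study {study} absent from expression matrix"
            )
        study_samples = [s for s in expr.sample_ids if study_of[s] == study]
        ref_mean = expr.data[ref_ids].mean(axis=1)
        out[study_samples] = expr.data[study_samples].sub(ref_mean, axis=0)
    return ExpressionMatrix(out, scale=NORMALIZED)


# ---------------------------------------------------------------------------
# File formats: expression TSV, sample CSV, reference-map CSV, GMT
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, scale: str = LOG_TPM) -> ExpressionMatrix:
    """Read a genes-in-rows TSV (first column gene id, remaining sample ids)."""
    path = Path(path)
    if not path.exists():
        raise LoadsenseError(f"expression file not found: {path}")
    data = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    return ExpressionMatrix(data, scale=scale)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    data = expr.data.copy()
    data.index.name = "gene_id"
    data.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadsenseError(f"sample table not found: {path}")
    samples = pd.read_csv(
        path,
        dtype={"sample_id": str, "study_id": str, "condition": str},
    )
    for col in ("is_reference", "is_loadstress"):
        samples[col] = samples[col].astype(bool)
    if "growth_rate" not in samples.columns:
        samples["growth_rate"] = np.nan
    return validate_sample_table(samples)


def write_sample_csv(samples: pd.DataFrame, path: str | Path) -> None:
    validate_sample_table(samples)
    samples.loc[:, list(SAMPLE_COLUMNS)].to_csv(path, index=False, float_format="%.10g")


def read_reference_map_csv(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column CSV (study_id, sample_id) into a reference map."""
    path = Path(path)
    if not path.exists():
        raise LoadsenseError(f"reference map not found: {path}")
    table = pd.read_csv(path, dtype=str)
    refs: dict[str, list[str]] = {}
    for study, sample in zip(table["study_id"], table["sample_id"]):
        refs.setdefault(study, []).append(sample)
    return refs


def write_reference_map_csv(refs: Mapping[str, Sequence[str]], path: str | Path) -> None:
    rows = [(study, sample) for study in sorted(refs) for sample in refs[study]]
    pd.DataFrame(rows, columns=["study_id", "sample_id"]).to_csv(path, index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, tab-separated members)."""
    path = Path(path)
    if not path.exists():
        raise LoadsenseError(f"GMT file not found: {path}")
    sets: dict[str, set[str]] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise LoadsenseError(f"malformed GMT line: {line!r}")
        name, _desc, *members = parts
        if name in sets:
            raise LoadsenseError(f"duplicate gene-set name {name!r}")
        sets[name] = set(members)
    return sets


def write_gmt(
    sets: Mapping[str, set[str] | Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    lines = []
    for name in sets:
        members = sorted(sets[name])
        lines.append("\t".join([name, descriptions.get(name, "na"), *members]))
    Path(path).write_text("\n".join(lines) + "\n")
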