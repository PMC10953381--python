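"""Seeded synthetic multi-study expression compendia.

The generator emulates the statistical structure a load-stress biomarker
analysis assumes: a genes x samples log-TPM matrix pooled from several
studies, each study carrying its own additive batch offset and designated
reference (control) samples; a binary load-stress class; a handful of
planted biomarker genes shifted by a configurable effect size in the
load-stress samples; block-structured gene sets with one set holding the
planted genes; a low-rank iModulon decomposition of the signal; and per
load-stress-sample growth rates coupled to the planted-gene deviation so a
biomarker/growth correlation is plantable.

Each logical component (baseline, batch, noise, counts, growth) draws from
its own pseudo-random stream spawned from the master seed, so adding or
resizing one component never perturbs another's draws and identical configs
reproduce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .activity import GeneSetCollection, IModulonModel
from .preprocess import (
    LOG_TPM,
    ExpressionMatrix,
    LoadsenseError,
    validate_sample_table,
    write_expression_tsv,
    write_gmt,
    write_sample_csv,
)

#: condition label carried by load-stress samples
LOAD_STRESS = "load_stress"
#: condition label carried by reference samples
CONTROL = "control"


@dataclass
class CompendiumConfig:
    """Knobs of the synthetic compendium.

    Defaults emulate the scale of the real compendium the analysis targets:
    250 samples over 10 equal-size studies (each with 2 designated controls),
    82 of them load-stress, two planted biomarker genes shifted by 2 log2
    units (4x the per-observation noise sd of 0.5), and study batch offsets
    of sd 1.0 so that cross-study classification genuinely requires the
    reference normalization step.
    """

    n_genes: int = 4202
    n_studies: int = 10
    samples_per_study: int = 25
    n_reference_per_study: int = 2
    n_loadstress_samples: int = 82
    planted_genes: tuple[int, ...] = (0, 1)
    effect_size: float = 2.0
    batch_sd: float = 1.0
    noise_sd: float = 0.5
    n_gene_sets: int = 20
    n_imodulons: int = 12
    seed: int = 0
    # growth-rate coupling: rate = base - slope * mean planted deviation + noise
    growth_base_rate: float = 0.9
    growth_slope: float = 0.15
    growth_noise_sd: float = 0.05

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_studies <= 0 or self.samples_per_study <= 0:
            raise LoadsenseError("n_genes, n_studies and samples_per_study must be positive")
        if self.n_reference_per_study < 0 or self.n_loadstress_samples < 0:
            raise LoadsenseError("sample counts must be non-negative")
        if self.n_reference_per_study > self.samples_per_study:
            raise LoadsenseError("n_reference_per_study exceeds samples_per_study")
        total = self.n_studies * self.samples_per_study
        if self.n_loadstress_samples > total:
            raise LoadsenseError(
                f"n_loadstress_samples={self.n_loadstress_samples} exceeds "
                f"total samples {total}"
            )
        n_free = total - self.n_studies * self.n_reference_per_study
        if self.n_loadstress_samples > n_free:
            raise LoadsenseError(
                f"n_loadstress_samples={self.n_loadstress_samples} exceeds the "
                f"{n_free} non-reference samples (references are never load-stress)"
            )
        if any(g < 0 or g >= self.n_genes for g in self.planted_genes):
            raise LoadsenseError("planted gene indices must lie in [0, n_genes)")
        if self.noise_sd <= 0:
            raise LoadsenseError("noise_sd must be positive")
        if self.batch_sd < 0:
            raise LoadsenseError("batch_sd must be non-negative")
        if self.n_gene_sets < 0 or self.n_imodulons < 0:
            raise LoadsenseError("set and iModulon counts must be non-negative")


@dataclass
class SyntheticCompendium:
    """Bundle of everything the pipeline consumes, plus the ground truth."""

    expression: ExpressionMatrix
    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_sets: GeneSetCollection
    imodulons: IModulonModel
    growth_rates: pd.Series
    truth: dict


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent generator per logical component."""
    names = ["baseline", "batch", "noise", "library", "growth", "sets"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_compendium(config: CompendiumConfig) -> SyntheticCompendium:
    """Generate a full synthetic compendium from ``config``.

    Expression model (log-TPM scale)::

        X(g, s) = baseline(g) + batch(study(s), g)
                  + effect_size * 1[g planted and s load-stress]
                  + Normal(0, noise_sd)

    Counts are round(2**X * library_factor) with per-sample library factors
    log-normal around 1.  The iModulon model is an exact truncated singular
    value decomposition of the noise-free, gene-centered signal; the achieved
    residual max|X_centered - M@A| is declared in ``truth`` as
    ``decomposition_tolerance``.
    """
    config.validate()
    rng = _streams(config.seed)
    n_total = config.n_studies * config.samples_per_study
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    sample_ids = [
        f"S{st:02d}_{k:02d}"
        for st in range(config.n_studies)
        for k in range(config.samples_per_study)
    ]
    study_ids = [f"study{st:02d}" for st in range(config.n_studies) for _ in range(config.samples_per_study)]

    # --- sample table: references first within each study
    is_reference = np.zeros(n_total, dtype=bool)
    for st in range(config.n_studies):
        start = st * config.samples_per_study
        is_reference[start : start + config.n_reference_per_study] = True
    # load-stress labels go round-robin over the studies' non-reference
    # samples so the class is never confounded with a study's batch offset
    # (raw batch structure must not predict the class on its own)
    is_loadstress = np.zeros(n_total, dtype=bool)
    nonref_by_study = [
        [st * config.samples_per_study + k
         for k in range(config.n_reference_per_study, config.samples_per_study)]
        for st in range(config.n_studies)
    ]
    remaining = config.n_loadstress_samples
    round_idx = 0
    while remaining > 0:
        for st in range(config.n_studies):
            if remaining == 0:
                break
            if round_idx < len(nonref_by_study[st]):
                is_loadstress[nonref_by_study[st][round_idx]] = True
                remaining -= 1
        round_idx += 1
    condition = np.where(
        is_reference, CONTROL, np.where(is_loadstress, LOAD_STRESS, "")
    ).astype(object)
    for idx in range(n_total):
        if not condition[idx]:
            condition[idx] = f"env{study_ids[idx][-2:]}"

    # --- expression components
    baseline = rng["baseline"].normal(6.0, 2.0, size=config.n_genes)
    batch = rng["batch"].normal(0.0, config.batch_sd, size=(config.n_studies, config.n_genes))
    study_index = np.repeat(np.arange(config.n_studies), config.samples_per_study)
    signal = baseline[:, None] + batch[study_index, :].T  # genes x samples
    planted = np.array(sorted(set(config.planted_genes)), dtype=int)
    effect = np.zeros((config.n_genes, n_total))
    if planted.size and config.effect_size != 0.0:
        effect[np.ix_(planted, np.where(is_loadstress)[0])] = config.effect_size
    signal = signal + effect
    noise = rng["noise"].normal(0.0, config.noise_sd, size=(config.n_genes, n_total))
    values = signal + noise

    expression = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale=LOG_TPM
    )

    # --- counts: round(2^x * library factor), library factors log-normal ~1
    library = rng["library"].lognormal(mean=0.0, sigma=0.2, size=n_total)
    counts_values = np.rint(np.exp2(values) * library[None, :]).astype(np.int64)
    counts = pd.DataFrame(counts_values, index=gene_ids, columns=sample_ids)

    # --- growth rates for load-stress samples: coupled to planted deviation
    growth = pd.Series(np.nan, index=sample_ids, dtype=float)
    ls_idx = np.where(is_loadstress)[0]
    if ls_idx.size and planted.size:
        # deviation of each load-stress sample's planted genes from the
        # noise-free study background (what normalization is meant to expose)
        deviation = (values - (baseline[:, None] + batch[study_index, :].T))[
            np.ix_(planted, ls_idx)
        ].mean(axis=0)
        rates = (
            config.growth_base_rate
            - config.growth_slope * deviation
            + rng["growth"].normal(0.0, config.growth_noise_sd, size=ls_idx.size)
        )
        growth.iloc[ls_idx] = np.maximum(rates, 0.05)

    samples = validate_sample_table(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "study_id": study_ids,
                "condition": condition,
                "is_reference": is_reference,
                "is_loadstress": is_loadstress,
                "growth_rate": growth.to_numpy(),
            }
        )
    )

    # --- gene sets: one set holding the planted genes, the rest a partition
    # of the remaining genes into equal blocks
    sets: dict[str, frozenset[str]] = {}
    kinds: dict[str, str] = {}
    planted_ids = [gene_ids[g] for g in planted]
    planted_set_name = None
    if planted.size:
        planted_set_name = "set_planted"
        sets[planted_set_name] = frozenset(planted_ids)
        kinds[planted_set_name] = "regulon"
    if config.n_gene_sets > 0:
        others = [g for g in range(config.n_genes) if g not in set(planted)]
        blocks = np.array_split(np.array(others), config.n_gene_sets)
        for i, block in enumerate(blocks):
            if block.size == 0:
                continue
            name = f"set_{i:03d}"
            sets[name] = frozenset(gene_ids[g] for g in block)
            kinds[name] = "regulon"
    gene_sets = GeneSetCollection(sets, kinds)

    # --- iModulon decomposition of the gene-centered signal (exact up to the
    # truncation rank; the residual against centered X is the declared tol)
    k = config.n_imodulons
    imod_ids = [f"iM{j:02d}" for j in range(k)]
    centered_signal = signal - signal.mean(axis=1, keepdims=True)
    if k > 0:
        u, s, vt = np.linalg.svd(centered_signal, full_matrices=False)
        k_eff = min(k, s.size)
        M = np.zeros((config.n_genes, k))
        A = np.zeros((k, n_total))
        M[:, :k_eff] = u[:, :k_eff] * s[:k_eff]
        A[:k_eff, :] = vt[:k_eff, :]
    else:
        M = np.zeros((config.n_genes, 0))
        A = np.zeros((0, n_total))
    x_centered = values - values.mean(axis=1, keepdims=True)
    residual = float(np.abs(x_centered - M @ A).max()) if n_total else 0.0
    imodulons = IModulonModel(
        weights=pd.DataFrame(M, index=gene_ids, columns=imod_ids),
        activities=pd.DataFrame(A, index=imod_ids, columns=sample_ids),
    )

    truth = {
        "planted_genes": planted_ids,
        "planted_indices": [int(g) for g in planted],
        "planted_set_name": planted_set_name,
        "effect_size": config.effect_size,
        "noise_sd": config.noise_sd,
        "batch_sd": config.batch_sd,
        "decomposition_tolerance": residual,
        "growth_slope": config.growth_slope,
        "seed": config.seed,
    }

    return SyntheticCompendium(
        expression=expression,
        counts=counts,
        samples=samples,
        gene_sets=gene_sets,
        imodulons=imodulons,
        growth_rates=growth[samples["is_loadstress"].to_numpy()],
        truth=truth,
    )


def write_compendium(comp: SyntheticCompendium, out_dir: str | Path) -> None:
    """Write all compendium artifacts as plain-text files into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(comp.expression, out / "expression.tsv")
    counts = comp.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(out / "counts.tsv", sep="\t")
    write_sample_csv(comp.samples, out / "samples.csv")
    write_gmt(dict(comp.gene_sets.items()), out / "gene_sets.gmt")
    M = comp.imodulons.weights.copy()
    M.index.name = "gene_id"
    M.to_csv(out / "imodulon_M.tsv", sep="\t", float_format="%.10g")
    A = comp.imodulons.activities.copy()
    A.index.name = "imodulon_id"
    A.to_csv(out / "imodulon_A.tsv", sep="\t", float_format="%.10g")
    (out / "truth.json").write_text(json.dumps(comp.truth, indent=2) + "\n")
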