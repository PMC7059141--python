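"""Relative qPCR quantification: ddCt fold changes and mtDNA content.

Conventions (the standard comparative-Ct method, assuming amplification
efficiency 2.0):

* technical replicates are averaged (arithmetic mean of Ct) first;
* dCt = Ct(target) - mean(Ct of the housekeeping genes); the arithmetic
  mean of Cts equals geometric-mean normalization of linear quantities,
  the standard multi-reference-gene summary;
* ddCt = mean dCt(group) - mean dCt(reference group);
  fold change = 2^(-ddCt), so the reference group's fold is exactly 1;
* relative mitochondrial DNA content per sample is
  2^-(Ct_mito - Ct_nuclear), normalized so the control-group mean is 1.

Adding a constant to every Ct of a sample (a global efficiency or input
shift) cancels in dCt, which is the point of the normalization.

A Ct table is a tidy DataFrame with columns
``sample_id, group, target, replicate, ct``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CT_COLUMNS",
    "read_ct_table",
    "write_ct_table",
    "validate_ct_table",
    "delta_ct",
    "fold_change",
    "mtdna_content",
    "FoldChangeResult",
    "MtContentResult",
]

CT_COLUMNS = ["sample_id", "group", "target", "replicate", "ct"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValueError("all Ct values must be finite and > 0")
    return table


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    return validate_ct_table(table)


def write_ct_table(table: pd.DataFrame, path) -> None:
    validate_ct_table(table)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _replicate_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (sample_id, group, target) over technical replicates."""
    return (
        table.groupby(["sample_id", "group", "target"], sort=True)["ct"]
        .mean()
        .reset_index()
    )


@dataclass
class FoldChangeResult:
    """ddCt-derived relative expression of one target across groups."""

    target: str
    reference_group: str
    delta_ct: pd.Series  # per sample, indexed by sample_id
    delta_delta_ct: pd.Series  # per group, vs reference
    fold_change: pd.Series  # per group, 2^-ddCt (from group-mean dCt)
    per_sample_fold: pd.Series  # per sample, 2^-(dCt_i - mean dCt(ref))
    fold_change_sample_mean: pd.Series  # per group, mean of per-sample folds
    sem: pd.Series  # per group, SEM of per-sample folds


def delta_ct(table: pd.DataFrame, target: str, hkg_list: list[str]) -> pd.Series:
    """Per-sample dCt of *target* against the mean of the housekeeping genes.

    Every housekeeping gene must be measured in every sample; a missing
    one raises, naming the sample and gene.
    """
    validate_ct_table(table)
    means = _replicate_means(table)
    by_sample = means.pivot_table(index="sample_id", columns="target", values="ct")
    if target not in by_sample.columns:
        raise ValueError(f"target {target!r} not present in Ct table")
    target_ct = by_sample[target].dropna()
    for sample in target_ct.index:
        for hkg in hkg_list:
            if hkg not in by_sample.columns or pd.isna(by_sample.loc[sample, hkg]):
                raise ValueError(
                    f"housekeeping gene {hkg!r} missing for sample {sample!r}"
                )
    hkg_summary = by_sample.loc[target_ct.index, list(hkg_list)].mean(axis=1)
    out = target_ct - hkg_summary
    out.name = f"delta_ct({target})"
    return out


def _sample_groups(table: pd.DataFrame) -> pd.Series:
    groups = table[["sample_id", "group"]].drop_duplicates()
    dup = groups["sample_id"].duplicated()
    if dup.any():
        bad = sorted(groups.loc[dup, "sample_id"])
        raise ValueError(f"samples assigned to multiple groups: {bad}")
    return groups.set_index("sample_id")["group"]


def fold_change(
    delta_cts: pd.Series,
    groups: pd.Series,
    reference_group: str,
    target: str = "",
) -> FoldChangeResult:
    """Group fold changes 2^-ddCt relative to *reference_group*.

    Two group summaries are emitted: the canonical fold from the
    group-mean dCt (``fold_change``) and the mean of per-sample folds
    (``fold_change_sample_mean``); per-sample folds also provide the SEM.
    """
    groups = groups.reindex(delta_cts.index)
    if groups.isna().any():
        bad = sorted(delta_cts.index[groups.isna()])
        raise ValueError(f"samples without a group assignment: {bad}")
    group_means = delta_cts.groupby(groups).mean()
    if reference_group not in group_means.index:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    ref_mean = group_means[reference_group]
    ddct = group_means - ref_mean
    per_sample_fold = np.power(2.0, -(delta_cts - ref_mean))
    fold_sample_mean = per_sample_fold.groupby(groups).mean()
    sem = per_sample_fold.groupby(groups).sem()
    return FoldChangeResult(
        target=target,
        reference_group=reference_group,
        delta_ct=delta_cts,
        delta_delta_ct=ddct,
        fold_change=np.power(2.0, -ddct),
        per_sample_fold=per_sample_fold,
        fold_change_sample_mean=fold_sample_mean,
        sem=sem,
    )


def target_fold_change(
    table: pd.DataFrame, target: str, hkg_list: list[str], reference_group: str
) -> FoldChangeResult:
    """Convenience: dCt then fold change straight from a Ct table."""
    dct = delta_ct(table, target, hkg_list)
    return fold_change(dct, _sample_groups(table), reference_group, target=target)


@dataclass
class MtContentResult:
    """Relative mitochondrial DNA content per sample and per group."""

    control_group: str
    per_sample: pd.Series  # normalized 2^-(Ct_mito - Ct_nuc), control mean = 1
    group_means: pd.Series
    group_fold: pd.Series  # group mean / control mean (== group_means)
    sem: pd.Series


def mtdna_content(
    table: pd.DataFrame,
    mito_amplicon: str,
    nuclear_amplicon: str,
    control_group: str,
) -> MtContentResult:
    """Relative mtDNA copy number from a mito/nuclear amplicon pair.

    Per sample: 2^-(Ct_mito - Ct_nuclear); all values are divided by the
    control-group mean, so the control group averages exactly 1 and every
    group mean reads directly as a fold change versus control.
    """
    validate_ct_table(table)
    means = _replicate_means(table)
    by_sample = means.pivot_table(index="sample_id", columns="target", values="ct")
    for amp in (mito_amplicon, nuclear_amplicon):
        if amp not in by_sample.columns:
            raise ValueError(f"amplicon {amp!r} not present in Ct table")
        missing = by_sample.index[by_sample[amp].isna()]
        if len(missing):
            raise ValueError(
                f"amplicon {amp!r} missing for samples {sorted(missing)}"
            )
    groups = _sample_groups(table).reindex(by_sample.index)
    rel = np.power(2.0, -(by_sample[mito_amplicon] - by_sample[nuclear_amplicon]))
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} has no samples")
    control_mean = rel[groups == control_group].mean()
    normalized = rel / control_mean
    group_means = normalized.groupby(groups).mean()
    sem = normalized.groupby(groups).sem()
    return MtContentResult(
        control_group=control_group,
        per_sample=normalized,
        group_means=group_means,
        group_fold=group_means,
        sem=sem,
    )
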