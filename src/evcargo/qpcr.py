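"""ΔΔCt relative quantification with two conjoint endogenous controls.

Per sample, ΔCt = target Ct minus the arithmetic mean of the two control Ct
values (equivalent to the geometric mean of the linear quantities). ΔΔCt is
the difference of group-mean ΔCt (comparison group minus reference group),
and the log2 fold change is -ΔΔCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["DeltaDeltaCtResult", "delta_delta_ct"]

#: Spike-in QC assays accepted in Ct tables but never used in calculations.
SPIKE_IN_ASSAYS = ("UniSp2", "UniSp4", "UniSp5", "UniSp6")


@dataclass
class DeltaDeltaCtResult:
    target_assay: str
    control_assays: tuple[str, str]
    reference_group: str
    comparison_group: str
    delta_ct: pd.DataFrame = field(repr=False)  # per-sample ΔCt
    delta_delta_ct: float = float("nan")
    log2_fold_change: float = float("nan")
    n_reference: int = 0
    n_comparison: int = 0
    spike_ins_present: tuple[str, ...] = ()


def delta_delta_ct(
    table: pd.DataFrame,
    target_assay: str,
    control_assays: tuple[str, str],
    reference_group: str = "young",
) -> DeltaDeltaCtResult:
    """Relative quantification of one target assay versus the reference group.

    Parameters
    ----------
    table :
        Long-format Ct table with columns sample_id, group, assay_id, ct.
    target_assay :
        Assay to quantify.
    control_assays :
        The two conjoint endogenous control assays; their Ct values are
        combined per sample as an arithmetic mean.
    reference_group :
        Group whose mean ΔCt anchors the comparison (log2FC of the other
        group relative to this one).

    Samples missing the target or either control are excluded with a
    warning; an empty group after exclusion is an error.
    """
    required = {"sample_id", "group", "assay_id", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    c1, c2 = control_assays
    spikes = tuple(s for s in SPIKE_IN_ASSAYS if s in set(table["assay_id"]))

    wide = table.pivot_table(index=["sample_id", "group"], columns="assay_id", values="ct")
    for assay in (target_assay, c1, c2):
        if assay not in wide.columns:
            raise ValueError(f"assay {assay!r} not present in Ct table")
    complete = wide[[target_assay, c1, c2]].notna().all(axis=1)
    excluded = wide.index[~complete].get_level_values("sample_id").tolist()
    if excluded:
        warnings.warn(f"samples excluded (missing target/control Ct): {excluded}", stacklevel=2)
    wide = wide[complete]

    dct = (wide[target_assay] - (wide[c1] + wide[c2]) / 2.0).rename("delta_ct").reset_index()
    groups = set(dct["group"])
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} empty after exclusions")
    others = sorted(groups - {reference_group})
    if len(others) != 1:
        raise ValueError(f"expected exactly one comparison group, found {others}")
    comparison_group = others[0]

    ref = dct.loc[dct["group"] == reference_group, "delta_ct"]
    cmp_ = dct.loc[dct["group"] == comparison_group, "delta_ct"]
    if ref.empty or cmp_.empty:
        raise ValueError("a group is empty after exclusions")
    ddct = float(cmp_.mean() - ref.mean())
    return DeltaDeltaCtResult(
        target_assay=target_assay,
        control_assays=(c1, c2),
        reference_group=reference_group,
        comparison_group=comparison_group,
        delta_ct=dct,
        delta_delta_ct=ddct,
        log2_fold_change=-ddct,
        n_reference=int(len(ref)),
        n_comparison=int(len(cmp_)),
        spike_ins_present=spikes,
    )
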