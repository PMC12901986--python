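"""5'-3' RT-qPCR transcript-integrity statistics and conventional ddCq.

With oligo-dT-primed reverse transcription, degradation biases cDNA
toward the transcript 3' end, so the 5' primer pair returns higher Cq
than the 3' pair. The integrity statistic is the difference
``dCq = Cq(5') - Cq(3')`` — unlike the 5'/3' Cq *ratio*, the difference
is invariant to overall expression level (adding a constant to every Cq
leaves it unchanged). ``ddCq`` references dCq to the mean of the empty
transfection controls.

Replicate Cq values are collapsed to their mean before any dCq is
computed (replicates are technical triplicates of one cDNA); undetected
replicates are never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "collapse_replicates",
    "five_three_dcq",
    "compute_dcq",
    "five_three_ddcq",
    "integrity_analysis",
    "relative_expression_ddcq",
]

logger = logging.getLogger(__name__)

_CQ_COLUMNS = {"sample", "target", "primer_end", "replicate", "cq"}


def _check_cq_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = _CQ_COLUMNS - set(table.columns)
    if missing:
        raise ValidationError(f"Cq table missing columns: {sorted(missing)}")
    table = table.copy()
    if "detected" not in table.columns:
        table["detected"] = table["cq"].notna()
    return table


def collapse_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Cq of detected replicates per (sample, target, primer_end).

    Returns columns ``sample, target, primer_end, cq, n_detected, n_total``.
    Groups with no detected replicate get NaN Cq and a logged warning;
    partial dropout is noted at debug level.
    """
    table = _check_cq_table(table)
    rows = []
    for (sample, target, end), grp in table.groupby(
        ["sample", "target", "primer_end"], sort=True
    ):
        detected = grp[grp["detected"].astype(bool)]
        n_total = len(grp)
        n_detected = len(detected)
        if n_detected == 0:
            logger.warning(
                "no detected replicate for sample=%s target=%s end=%s; "
                "group excluded downstream",
                sample,
                target,
                end,
            )
            mean_cq = np.nan
        else:
            if n_detected < n_total:
                logger.debug(
                    "replicate dropout for sample=%s target=%s end=%s "
                    "(%d/%d detected)",
                    sample,
                    target,
                    end,
                    n_detected,
                    n_total,
                )
            mean_cq = float(detected["cq"].mean())
        rows.append(
            {
                "sample": sample,
                "target": target,
                "primer_end": end,
                "cq": mean_cq,
                "n_detected": n_detected,
                "n_total": n_total,
            }
        )
    return pd.DataFrame(rows)


def five_three_dcq(cq5: float, cq3: float) -> float:
    """Integrity statistic for one sample/target: ``Cq(5') - Cq(3')``."""
    if not (np.isfinite(cq5) and np.isfinite(cq3)):
        raise ValidationError("both primer ends must be detected to compute dCq")
    return float(cq5 - cq3)


def compute_dcq(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample, target) dCq from a replicate-collapsed table."""
    rows = []
    for (sample, target), grp in collapsed.groupby(["sample", "target"], sort=True):
        by_end = grp.set_index("primer_end")["cq"]
        for end in ("5p", "3p"):
            if end not in by_end.index:
                raise ValidationError(
                    f"missing primer end {end!r} for sample={sample!r} "
                    f"target={target!r}"
                )
        if by_end[["5p", "3p"]].isna().any():
            logger.warning(
                "undetected primer end for sample=%s target=%s; dCq is NaN",
                sample,
                target,
            )
            rows.append({"sample": sample, "target": target, "dcq_53": np.nan})
            continue
        rows.append(
            {
                "sample": sample,
                "target": target,
                "dcq_53": five_three_dcq(by_end["5p"], by_end["3p"]),
            }
        )
    return pd.DataFrame(rows)


def five_three_ddcq(
    treatment_dcqs: "list[float] | np.ndarray",
    control_dcqs: "list[float] | np.ndarray",
) -> dict:
    """Reference treatment dCq values to the empty-control mean.

    Returns per-treatment-sample ddCq plus the condition mean and SEM.
    """
    control = np.asarray(control_dcqs, dtype=float)
    control = control[np.isfinite(control)]
    if control.size == 0:
        raise ValidationError("empty transfection control required")
    treatment = np.asarray(treatment_dcqs, dtype=float)
    ddcq = treatment - control.mean()
    finite = ddcq[np.isfinite(ddcq)]
    sem = (
        float(np.std(finite, ddof=1) / np.sqrt(finite.size))
        if finite.size > 1
        else np.nan
    )
    return {
        "ddcq": ddcq,
        "mean": float(finite.mean()) if finite.size else np.nan,
        "sem": sem,
        "control_mean_dcq": float(control.mean()),
    }


def integrity_analysis(
    cq_table: pd.DataFrame, sample_sheet: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full 5'-3' analysis of a Cq table against a sample sheet.

    ``sample_sheet`` needs columns ``sample, condition, is_empty_control``.
    Returns ``(per_sample, per_condition)`` tables: per-sample dCq/ddCq
    and per-(condition, target) ddCq mean and SEM.
    """
    for col in ("sample", "condition", "is_empty_control"):
        if col not in sample_sheet.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    sheet = sample_sheet.set_index("sample")
    dcq = compute_dcq(collapse_replicates(cq_table))
    unknown = set(dcq["sample"]) - set(sheet.index)
    if unknown:
        raise ValidationError(f"samples missing from sample sheet: {sorted(unknown)}")
    dcq["condition"] = dcq["sample"].map(sheet["condition"])
    dcq["is_empty_control"] = (
        dcq["sample"].map(sheet["is_empty_control"]).astype(bool)
    )

    per_sample_rows = []
    per_condition_rows = []
    for target, grp in dcq.groupby("target", sort=True):
        controls = grp[grp["is_empty_control"]]["dcq_53"].to_numpy()
        for condition, cgrp in grp.groupby("condition", sort=True):
            result = five_three_ddcq(cgrp["dcq_53"].to_numpy(), controls)
            for (_, row), ddcq in zip(cgrp.iterrows(), result["ddcq"]):
                per_sample_rows.append(
                    {
                        "sample": row["sample"],
                        "target": target,
                        "condition": condition,
                        "dcq_53": row["dcq_53"],
                        "ddcq_53": ddcq,
                    }
                )
            per_condition_rows.append(
                {
                    "condition": condition,
                    "target": target,
                    "ddcq_53_mean": result["mean"],
                    "ddcq_53_sem": result["sem"],
                    "n_samples": len(cgrp),
                }
            )
    return pd.DataFrame(per_sample_rows), pd.DataFrame(per_condition_rows)


def relative_expression_ddcq(
    cq_table: pd.DataFrame,
    target: str,
    reference: str,
    sample_conditions: dict[str, str],
    control_condition: str,
) -> pd.DataFrame:
    """Conventional relative expression: fold change = ``2 ** (-ddCq)``.

    ``dCq = Cq(target) - Cq(reference)`` per sample (any primer ends are
    averaged by :func:`collapse_replicates` upstream of this), then ddCq
    references the mean dCq of the control condition.
    """
    collapsed = collapse_replicates(cq_table)
    per_sample = (
        collapsed.groupby(["sample", "target"])["cq"].mean().unstack("target")
    )
    for gene in (target, reference):
        if gene not in per_sample.columns:
            raise ValidationError(f"gene {gene!r} absent from the Cq table")
    if per_sample[reference].isna().any():
        bad = per_sample.index[per_sample[reference].isna()].tolist()
        raise ValidationError(
            f"reference gene {reference!r} not measured in samples: {bad}"
        )
    dcq = per_sample[target] - per_sample[reference]
    conditions = pd.Series(sample_conditions)
    unknown = set(dcq.index) - set(conditions.index)
    if unknown:
        raise ValidationError(f"samples without condition labels: {sorted(unknown)}")
    control_mask = conditions.reindex(dcq.index) == control_condition
    if not control_mask.any():
        raise ValidationError(
            f"no samples in control condition {control_condition!r}"
        )
    ddcq = dcq - dcq[control_mask].mean()
    out = pd.DataFrame(
        {
            "condition": conditions.reindex(dcq.index),
            "dcq": dcq,
            "ddcq": ddcq,
            "fold_change": 2.0 ** (-ddcq),
        }
    )
    out.index.name = "sample"
    return out
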