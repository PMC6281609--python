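"""Relative expression quantification by the 2^-ddCt method.

Replicate Ct values are averaged per (sample, gene); the target gene is
normalized to the endogenous control (dCt = Ct_target - Ct_control) and
expressed as a fold change versus a calibrator group:
``2 ** -(dCt - dCt_ref)`` with the calibrator group's mean dCt as reference.
Under the group-mean convention the per-sample folds are finally rescaled by
the calibrator group's arithmetic mean, so that group's mean relative level
is exactly 1 while per-sample variation (hence a nonzero SEM) is retained.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

GROUP_MEAN = "group_mean"
REFERENCE_SAMPLE = "reference_sample"


def delta_delta_ct(panel: pd.DataFrame, calibrator_group: str,
                   convention: str = GROUP_MEAN,
                   reference_sample=None) -> pd.DataFrame:
    """Per-sample relative expression from a long-format Ct panel.

    Parameters
    ----------
    panel:
        Long-format table with columns ``sample_id, genotype_group, gene,
        replicate, ct``; ``gene`` takes values ``"target"`` and
        ``"control"``.
    calibrator_group:
        Genotype group whose expression defines 1-fold.
    convention:
        ``"group_mean"`` (default; reference dCt is the calibrator group's
        mean, folds rescaled so the calibrator mean is exactly 1) or
        ``"reference_sample"`` (classic single-sample calibration; requires
        ``reference_sample``).

    Returns a per-sample frame with mean Cts, dCt, and the relative level.
    """
    required = {"sample_id", "genotype_group", "gene", "ct"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    if not np.isfinite(panel["ct"]).all() or (panel["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")

    counts = panel.groupby(["sample_id", "gene"], observed=True)["ct"].size()
    if (counts < 2).any():
        singles = counts[counts < 2].index.get_level_values(0).unique().tolist()
        warnings.warn(f"single-replicate Ct for samples {singles}; used as-is")
    mean_ct = (panel.groupby(["sample_id", "genotype_group", "gene"],
                             observed=True)["ct"].mean().unstack("gene"))
    for gene in ("target", "control"):
        if gene not in mean_ct.columns or mean_ct[gene].isna().any():
            bad = (mean_ct.index.get_level_values(0).tolist()
                   if gene not in mean_ct.columns
                   else mean_ct.index[mean_ct[gene].isna()].get_level_values(0).tolist())
            raise ValueError(f"missing {gene} gene Ct for samples {bad}")
    out = mean_ct.reset_index().rename(
        columns={"target": "ct_target", "control": "ct_control"})
    out["delta_ct"] = out["ct_target"] - out["ct_control"]

    cal = out["genotype_group"] == calibrator_group
    if not cal.any():
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    if convention == GROUP_MEAN:
        ref = out.loc[cal, "delta_ct"].mean()
    elif convention == REFERENCE_SAMPLE:
        if reference_sample is None:
            raise ValueError("reference_sample required for this convention")
        row = out["sample_id"] == reference_sample
        if not row.any():
            raise ValueError(f"reference sample {reference_sample!r} not found")
        ref = float(out.loc[row, "delta_ct"].iloc[0])
    else:
        raise ValueError(f"unknown calibration convention {convention!r}")

    out["relative_raw"] = 2.0 ** -(out["delta_ct"] - ref)
    if convention == GROUP_MEAN:
        out["relative"] = out["relative_raw"] / out.loc[cal, "relative_raw"].mean()
    else:
        out["relative"] = out["relative_raw"]
    out.attrs["calibrator_group"] = calibrator_group
    out.attrs["convention"] = convention
    return out


def group_summary(expression: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SEM of relative expression per genotype group."""
    g = expression.groupby("genotype_group", observed=True)["relative"]
    return pd.DataFrame({"mean": g.mean(),
                         "sem": g.sem(),
                         "n": g.size()})
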