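"""Bench-assay arithmetic: qPCR delta-Ct, dual-luciferase and blot ratios.

All operations are pure and deterministic.  Undetected qPCR wells are kept
as explicit missing values (never imputed with a ceiling cycle count) and
excluded from group means with a reported count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .excitability import two_group_test

__all__ = [
    "normalized_ct",
    "normalized_ct_table",
    "genotype_fold_change",
    "relative_luciferase",
    "blot_ratio",
]


def normalized_ct(ct_goi, ct_norm):
    """Relative expression 2^-(Ct_GOI - Ct_Normaliser).

    Strictly decreasing in the gene-of-interest Ct (one fewer cycle doubles
    the value) and strictly increasing in the normaliser Ct.  Missing cycle
    thresholds propagate as NaN (undetected, never imputed).
    """
    ct_goi = np.asarray(ct_goi, dtype=float)
    ct_norm = np.asarray(ct_norm, dtype=float)
    out = np.power(2.0, -(ct_goi - ct_norm))
    return float(out) if out.ndim == 0 else out


def normalized_ct_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Copy of a Ct table with ``expression`` (2^-dCt) and a detected flag."""
    out = ct_table.copy()
    out["expression"] = normalized_ct(out["ct_goi"].to_numpy(),
                                      out["ct_norm"].to_numpy())
    out["detected"] = out["ct_goi"].notna() & out["ct_norm"].notna()
    return out


def genotype_fold_change(values_ko, values_wt) -> dict:
    """KO/WT ratio of group means with a two-sided Student's t-test.

    NaN (undetected) values are dropped; the returned dict reports how many
    were excluded per group.  When all WT values are undetected the ratio is
    undefined (NaN) and no p value is computed, mirroring the case of a
    transcript detected in no wild-type sample.
    """
    ko = np.asarray(values_ko, dtype=float)
    wt = np.asarray(values_wt, dtype=float)
    ko_det, wt_det = ko[~np.isnan(ko)], wt[~np.isnan(wt)]
    result = {"n_ko": len(ko_det), "n_wt": len(wt_det),
              "n_undetected_ko": int(np.isnan(ko).sum()),
              "n_undetected_wt": int(np.isnan(wt).sum())}
    if len(wt_det) == 0 or wt_det.mean() == 0 or len(ko_det) == 0:
        result.update(ratio=float("nan"), p=float("nan"),
                      note="ratio undefined: no detected WT values")
        return result
    result["ratio"] = float(ko_det.mean() / wt_det.mean())
    if len(ko_det) >= 2 and len(wt_det) >= 2:
        if ko_det.std() == 0 and wt_det.std() == 0:
            result.update(p=float("nan"),
                          note="degenerate: zero within-group variance")
            return result
        stat = _stats.ttest_ind(ko_det, wt_det)
        result["p"] = float(stat.pvalue)
    else:
        result.update(p=float("nan"), note="too few detected values for a test")
    return result


def relative_luciferase(records: pd.DataFrame,
                        control_mimic: str = "miCon") -> pd.DataFrame:
    """Per-well firefly/renilla ratios as a percentage of the control mean.

    Operates within one reporter construct: each well's ratio is scaled by
    100 / mean(control-mimic ratios), so the control group averages exactly
    100%.  Zero or negative renilla (the transfection control) is an error.
    """
    df = records.copy()
    if (df["renilla"] <= 0).any():
        raise ValueError("renilla luminescence must be positive")
    if not (df["mimic"] == control_mimic).any():
        raise ValueError(f"no {control_mimic} wells present")
    df["ratio"] = df["firefly"] / df["renilla"]
    control_mean = df.loc[df["mimic"] == control_mimic, "ratio"].mean()
    df["percent_of_control"] = 100.0 * df["ratio"] / control_mean
    return df


def blot_ratio(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Loading-control normalised band intensities and a genotype comparison.

    Each lane's target band is divided by its GAPDH band; genotypes are
    compared with :func:`lfpexcite.excitability.two_group_test`.  Returns
    (per-lane table with ``ratio``, comparison dict).
    """
    df = records.copy()
    if (df["gapdh_intensity"] <= 0).any():
        raise ValueError("GAPDH intensity must be positive")
    df["ratio"] = df["target_intensity"] / df["gapdh_intensity"]
    genotypes = df["genotype"].unique()
    comparison: dict = {}
    if len(genotypes) == 2:
        a = df.loc[df["genotype"] == genotypes[0], "ratio"].to_numpy()
        b = df.loc[df["genotype"] == genotypes[1], "ratio"].to_numpy()
        stat, p, test = two_group_test(a, b)
        comparison = {"group_a": genotypes[0], "group_b": genotypes[1],
                      "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                      "statistic": stat, "p": p, "test": test}
    return df, comparison
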