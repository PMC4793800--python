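"""Bacterial-titer analysis: does a pre-infection treatment prime resistance?

Resistance is measured as colony-forming units (CFU) in infected leaf
tissue; analysis is on log10 titers.  Fold changes in resistance are
ratios of geometric means (differences of mean log10 CFU), so a "340-fold
decrease in CFU" means the treated group's mean log10 titer sits 2.53
decades below the reference.  Group comparisons use Welch's
unequal-variance t-test on log10 titers with Benjamini-Hochberg
correction across the strain x treatment family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geneset_response import bh_adjust

__all__ = ["FoldChange", "log_titers", "fold_change_resistance", "resistance_test"]


@dataclass
class FoldChange:
    reference: str
    treatment: str
    strain: str
    fold: float          # 10^(mean log10 reference - mean log10 treated)
    fold_median: float   # same, from medians (robust variant)
    n_reference: int
    n_treatment: int


def log_titers(records: pd.DataFrame) -> pd.DataFrame:
    """Attach log10 CFU; requires positive titers."""
    if (records["cfu"] <= 0).any():
        raise ValueError("all CFU values must be positive")
    out = records.copy()
    out["log10_cfu"] = np.log10(out["cfu"].to_numpy(float))
    return out


def _group(records: pd.DataFrame, treatment: str, strain: str) -> np.ndarray:
    g = records[(records["treatment"] == treatment) & (records["strain"] == strain)]
    if len(g) < 2:
        raise ValueError(f"group ({treatment!r}, {strain!r}) has fewer than 2 replicates")
    return np.log10(g["cfu"].to_numpy(float))


def fold_change_resistance(
    records: pd.DataFrame, reference: str, treatment: str, strain: str
) -> FoldChange:
    """Fold decrease in pathogen load: ratio of geometric-mean CFU in the
    reference group over the treated group (values > 1 mean the treatment
    increased resistance).  A median-based variant is reported alongside."""
    ref = _group(records, reference, strain)
    trt = _group(records, treatment, strain)
    return FoldChange(
        reference=reference,
        treatment=treatment,
        strain=strain,
        fold=float(10.0 ** (ref.mean() - trt.mean())),
        fold_median=float(10.0 ** (np.median(ref) - np.median(trt))),
        n_reference=len(ref),
        n_treatment=len(trt),
    )


def resistance_test(records: pd.DataFrame, reference: str = "control") -> pd.DataFrame:
    """Welch tests of every treatment against the reference, per strain.

    Returns one row per strain x treatment with the difference in mean
    log10 CFU, the Welch statistic and p, and BH-adjusted p across the
    whole family.  Groups of n < 3 with zero pooled variance are flagged
    and their p omitted.
    """
    rows = []
    for strain in sorted(records["strain"].unique()):
        ref = _group(records, reference, strain)
        treatments = sorted(set(records.loc[records["strain"] == strain, "treatment"]) - {reference})
        for trt in treatments:
            obs = _group(records, trt, strain)
            degenerate = (len(ref) < 3 or len(obs) < 3) and (np.var(ref) + np.var(obs) == 0)
            if degenerate:
                t, p = 0.0, np.nan
            else:
                t, p = stats.ttest_ind(ref, obs, equal_var=False)
            rows.append(
                (strain, trt, float(ref.mean() - obs.mean()), float(t), float(p),
                 bool(degenerate), len(ref), len(obs))
            )
    out = pd.DataFrame(
        rows,
        columns=["strain", "treatment", "mean_log10_decrease", "t", "p",
                 "degenerate", "n_reference", "n_treatment"],
    )
    mask = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["p_adjusted"] = adj
    return out
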