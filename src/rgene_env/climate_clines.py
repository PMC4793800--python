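"""Expression clinality against historical climate, with resampled nulls.

The questions answered here: does a focal gene set's average expression
(or its plasticity — the log2 change upon a perturbation) track the
climate of each accession's origin, and is that clinality unusual
compared with the rest of the transcriptome?

* Per-accession basal expression is the fixed accession effect of a mixed
  model with gene as a random intercept, so constant per-gene offsets
  (primer bias) cancel out of every accession contrast.
* Clines are ordinary least-squares regressions of the per-accession
  estimate on one of four climate covariates (latitude, minimum
  temperature of the coldest month, precipitation of the driest month,
  temperature seasonality), Bonferroni-corrected across the four.
* The null for "is the focal set unusual" is the distribution of
  regression t-values for the average expression of many random gene sets
  of the same size drawn from a transcriptome matrix.
* For two populations sampled along a cline, per-gene Welch tests with a
  Bonferroni correction summarize how many genes are significantly higher
  in which population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_models import ModelSpec, fit_lmm

__all__ = [
    "CLIMATE_COVARIATES",
    "ClineResult",
    "NullDistribution",
    "PercentileResult",
    "accession_estimates",
    "plasticity",
    "cline_regression",
    "resampling_null",
    "empirical_percentile",
    "population_comparison",
]

CLIMATE_COVARIATES = (
    "latitude",
    "min_temp_coldest_month",
    "precip_driest_month",
    "temperature_seasonality",
)


@dataclass
class ClineResult:
    covariate: str
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    f: float
    t: float
    p: float
    p_bonferroni: float
    n: int


@dataclass
class NullDistribution:
    t_values: np.ndarray
    set_size: int
    n_sets: int
    source: str
    seed: int | None
    n_failed: int = 0


class PercentileResult(NamedTuple):
    raw: float          # fraction of the null as extreme or more extreme
    pseudocount: float  # (1 + count) / (n + 1)


def accession_estimates(
    data: pd.DataFrame,
    treatment: str,
    random: tuple[str, ...] = ("gene",),
) -> pd.Series:
    """Model-based per-accession mean log2 expression for one treatment.

    Fits expression ~ accession with gene as a random intercept and
    returns intercept + accession coefficient per accession, so gene-level
    offsets never enter the accession contrasts.
    """
    sub = data[data["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"treatment {treatment!r} absent from data")
    accs = sorted(sub["accession"].unique())
    if len(accs) < 2 or sub["gene"].nunique() < 1:
        raise ValueError("need >= 2 accessions with data for the treatment")
    if sub["gene"].nunique() == 1:
        # degenerate single-gene case: plain per-accession means
        return sub.groupby("accession")["value"].mean().reindex(accs)
    fit = fit_lmm(sub, ModelSpec(response="value", fixed=("accession",), random=random))
    intercept = fit.fixed_estimates["(Intercept)"]
    est = {}
    for a in accs:
        est[a] = intercept + fit.fixed_estimates.get(f"accession[{a}]", 0.0)
    return pd.Series(est, name=treatment).reindex(accs)


def plasticity(estimates_treatment: pd.Series, estimates_control: pd.Series) -> pd.Series:
    """Expression plasticity: treatment minus control model estimates, per
    accession, in log2 fold-change units."""
    if set(estimates_treatment.index) != set(estimates_control.index):
        raise ValueError("accession sets differ between treatment and control")
    out = estimates_treatment - estimates_control.reindex(estimates_treatment.index)
    out.name = f"{estimates_treatment.name}_vs_{estimates_control.name}"
    return out


def cline_regression(
    values: pd.Series,
    climate: pd.DataFrame,
    covariate: str,
    n_covariates_tested: int = 4,
) -> ClineResult:
    """OLS of a per-accession value on one climate covariate.

    Returns slope, R^2, adjusted R^2, F(1, n-2), the slope t and two-sided
    p, and the Bonferroni-corrected p across the tested covariates.
    """
    merged = pd.concat([values.rename("y"), climate[covariate].rename("x")], axis=1).dropna()
    n = len(merged)
    if n < 3:
        raise ValueError("need >= 3 accessions with value and covariate")
    x = merged["x"].to_numpy(float)
    y = merged["y"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} has zero variance")
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return ClineResult(
        covariate=covariate,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(r2),
        adj_r2=float(adj),
        f=float(t * t),
        t=float(t),
        p=float(res.pvalue),
        p_bonferroni=float(min(1.0, n_covariates_tested * res.pvalue)),
        n=n,
    )


def _set_mean_tvalues(M: np.ndarray, idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Slope t-values of OLS(mean expression of each gene set ~ x)."""
    n = len(x)
    means = M[idx].mean(axis=1)  # (n_sets, n_accessions)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    mc = means - means.mean(axis=1, keepdims=True)
    sxy = mc @ xc
    syy = np.einsum("ij,ij->i", mc, mc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy**2 / (sxx * syy), np.nan)
        t = np.sign(sxy) * np.sqrt(np.where(r2 < 1, r2 * (n - 2) / (1 - r2), np.inf))
    t[syy <= 0] = np.nan
    return t


def resampling_null(
    matrix: pd.DataFrame,
    climate: pd.DataFrame,
    covariate: str,
    set_size: int = 150,
    n_sets: int = 1000,
    pool: Sequence[str] | None = None,
    exclude: Iterable[str] = (),
    seed: int | None = None,
    source: str = "all_genes",
) -> NullDistribution:
    """Null distribution of cline t-values for random gene sets.

    Each of ``n_sets`` draws samples ``set_size`` genes uniformly without
    replacement (independently across sets) from ``pool`` (default: all
    matrix genes minus ``exclude``), averages their expression per
    accession and regresses the average on the covariate, keeping the
    slope's t-value.  Degenerate sets (zero expression variance) are
    dropped and counted in ``n_failed``.
    """
    if pool is None:
        pool = [g for g in matrix.index if g not in set(exclude)]
    else:
        pool = [g for g in pool if g not in set(exclude)]
    if len(pool) < set_size:
        raise ValueError(f"pool of {len(pool)} genes is smaller than set_size={set_size}")
    common = [a for a in matrix.columns if a in climate.index]
    if len(common) < 3:
        raise ValueError("matrix accessions do not match the climate table")
    M = matrix.loc[pool, common].to_numpy(float)
    x = climate.loc[common, covariate].to_numpy(float)
    rng = np.random.default_rng(seed)
    # argpartition of uniform noise = uniform sample without replacement per row
    u = rng.random((n_sets, len(pool)))
    idx = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    t = _set_mean_tvalues(M, idx, x)
    good = t[np.isfinite(t)]
    if len(good) == 0:
        raise ValueError("all resampled sets were degenerate (constant expression)")
    return NullDistribution(
        t_values=good, set_size=set_size, n_sets=n_sets,
        source=source, seed=seed, n_failed=int(n_sets - len(good)),
    )


def empirical_percentile(
    t_obs: float, null: NullDistribution, two_sided: bool = True
) -> PercentileResult:
    """Fraction of the null as extreme as or more extreme than ``t_obs``.

    Two-sided by default (compares |t|); the pseudocount variant
    (1 + count) / (n + 1) never returns exactly zero.
    """
    t = null.t_values
    if len(t) == 0:
        raise ValueError("null distribution is empty")
    if two_sided:
        count = int(np.sum(np.abs(t) >= abs(t_obs)))
    else:
        count = int(np.sum(t >= t_obs))
    return PercentileResult(
        raw=count / len(t), pseudocount=(1 + count) / (len(t) + 1)
    )


def population_comparison(
    matrix: pd.DataFrame,
    populations: pd.Series,
    focal_genes: Sequence[str],
    alpha: float = 0.05,
    higher: str = "north",
    lower: str = "south",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene Welch tests of expression between two populations.

    Bonferroni-corrects over the tested genes and summarizes how many
    significant genes are expressed higher in each population.
    """
    pops = populations.reindex(matrix.columns)
    a_cols = pops[pops == higher].index
    b_cols = pops[pops == lower].index
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each population needs at least 2 accessions")
    genes = [g for g in focal_genes if g in matrix.index]
    m = len(genes)
    rows = []
    for g in genes:
        va = matrix.loc[g, a_cols].to_numpy(float)
        vb = matrix.loc[g, b_cols].to_numpy(float)
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        rows.append((g, float(va.mean() - vb.mean()), float(t), float(p),
                     float(min(1.0, m * p))))
    per_gene = pd.DataFrame(
        rows, columns=["gene", "mean_diff", "t", "p", "p_bonferroni"]
    )
    sig = per_gene[per_gene["p_bonferroni"] < alpha]
    summary = {
        "n_tested": m,
        "n_significant": int(len(sig)),
        f"n_higher_{higher}": int((sig["mean_diff"] > 0).sum()),
        f"n_higher_{lower}": int((sig["mean_diff"] < 0).sum()),
    }
    return per_gene, summary
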