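"""Gene-set perturbation-response analysis (expression meta-study).

Given per-gene differential-expression calls (up / no-change / down) for a
panel of environmental perturbations, this module compares how a focal
gene set (R-genes) responds relative to two matched sets:

* a **control set** chosen to mimic the chromosomal positions and
  inter-gene distances of the focal genes (controls for co-regulation of
  clustered genes), and
* a **stress-response set** sampled uniformly from genes annotated with
  GO:0006950 (response to stress).

Per perturbation, the 2x3 table of (up, no-change, down) counts for two
sets is tested with Pearson's chi-square (no continuity correction — the
published statistics for this design reproduce only under the plain
Pearson statistic), p-values are Benjamini-Hochberg corrected across the
perturbation family, and a descriptive direction-bias statistic
|up - down| / (up + down) summarizes the consistency of the response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetDefinition",
    "build_control_set",
    "sample_stress_set",
    "tabulate_counts",
    "contingency_chisq",
    "chisq_2x2_up",
    "bh_adjust",
    "direction_bias",
    "run_meta_study",
]

CATEGORIES = ("up", "nc", "down")


@dataclass
class GeneSetDefinition:
    set_name: str
    genes: list[str]
    metadata: pd.DataFrame | None = None  # chromosome/start/strand per gene


def build_control_set(
    r_genes: pd.DataFrame,
    genome: pd.DataFrame,
    exclusions: Iterable[str] = (),
    offset: float = 500_000.0,
    cluster_distance: float = 10_000.0,
    seed: int | None = None,
) -> GeneSetDefinition:
    """Positionally matched control set: one control per focal gene.

    For each focal gene the target position is its start shifted by a fixed
    per-chromosome offset (sign chosen to stay on the chromosome), and the
    nearest unused non-focal candidate gene is selected.  Focal genes
    closer than ``cluster_distance`` form clusters; within a cluster each
    subsequent member's target preserves the original spacing from the
    previously chosen control, and chosen controls must keep the cluster's
    positional order — so consecutive distances keep their rank order.

    Both inputs need columns ``gene``, ``chrom``, ``start``.  The ``seed``
    argument is accepted for interface symmetry; the procedure is
    deterministic (ties break on smaller start coordinate).
    """
    excl = set(exclusions) | set(r_genes["gene"])
    chosen: list[str] = []
    meta_rows = []
    for chrom, rsub in r_genes.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cand = genome[(genome["chrom"] == chrom) & ~genome["gene"].isin(excl)]
        if cand.empty:
            raise ValueError(f"no candidate genes available on chromosome {chrom!r}")
        cand = cand.sort_values("start")
        cstarts = cand["start"].to_numpy(float)
        cgenes = cand["gene"].to_numpy()
        used = np.zeros(len(cand), bool)
        chrom_end = float(cstarts.max())

        starts = rsub["start"].to_numpy(float)
        # split into clusters of focal genes closer than cluster_distance
        breaks = np.flatnonzero(np.diff(starts) >= cluster_distance) + 1
        clusters = np.split(np.arange(len(starts)), breaks)
        for cl in clusters:
            first = starts[cl[0]]
            sign = 1.0 if first + offset <= chrom_end else -1.0
            prev_control = None
            prev_start = None
            for i in cl:
                if prev_control is None:
                    target = starts[i] + sign * offset
                else:
                    target = prev_control + (starts[i] - prev_start)
                dist = np.abs(cstarts - target)
                ok = ~used
                if prev_control is not None:
                    ok &= cstarts > prev_control  # preserve cluster order
                ok &= dist <= 2.0 * offset
                if not ok.any():
                    raise ValueError(
                        f"no control candidate within {2 * offset:.0f} bp of "
                        f"target position {target:.0f} on chromosome {chrom!r}"
                    )
                idx = np.flatnonzero(ok)
                j = idx[np.lexsort((cstarts[idx], dist[idx]))[0]]
                used[j] = True
                chosen.append(cgenes[j])
                meta_rows.append((cgenes[j], chrom, cstarts[j]))
                prev_control, prev_start = cstarts[j], starts[i]
    meta = pd.DataFrame(meta_rows, columns=["gene", "chrom", "start"])
    return GeneSetDefinition("control", chosen, meta)


def sample_stress_set(
    go_annotation: pd.DataFrame,
    n: int,
    exclusions: Iterable[str] = (),
    seed: int | None = None,
    terms: Iterable[str] = ("GO:0006950",),
) -> GeneSetDefinition:
    """Uniform sample (without replacement) of ``n`` genes annotated with
    any of ``terms`` (default: response to stress), excluding the given
    genes.  Pass an expanded term collection to include ontology
    descendants; by default the annotation is used exactly as supplied.
    """
    terms = set(terms)
    eligible = sorted(
        set(go_annotation.loc[go_annotation["term"].isin(terms), "gene"]) - set(exclusions)
    )
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} eligible genes; need {n}")
    rng = np.random.default_rng(seed)
    genes = sorted(rng.choice(eligible, size=n, replace=False))
    return GeneSetDefinition("stress", list(genes))


def tabulate_counts(
    calls: pd.DataFrame,
    sets: Mapping[str, Iterable[str]],
    contrast: str,
) -> pd.DataFrame:
    """Per-set (up, nc, down) counts for one contrast.

    Genes absent from the contrast are excluded (not counted as
    no-change).  Raises if the sets overlap.
    """
    all_genes: set[str] = set()
    for name, genes in sets.items():
        g = set(genes)
        if all_genes & g:
            raise ValueError("gene sets must be pairwise disjoint")
        all_genes |= g
    sub = calls[calls["contrast"] == contrast]
    rows = []
    for name, genes in sets.items():
        s = sub[sub["gene"].isin(set(genes))]
        counts = s["category"].value_counts()
        rows.append((name, *(int(counts.get(c, 0)) for c in CATEGORIES)))
    return pd.DataFrame(rows, columns=["set", *CATEGORIES]).set_index("set")


def _as_counts(v) -> np.ndarray:
    a = np.asarray(v, float)
    if a.shape != (3,):
        raise ValueError("expected a (up, nc, down) triple")
    if np.any(a < 0):
        raise ValueError("counts must be non-negative")
    return a


def contingency_chisq(counts_a, counts_b) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on the 2x3 table of
    two sets' (up, nc, down) counts.  Columns with zero total are dropped
    and the degrees of freedom reduced accordingly."""
    a, b = _as_counts(counts_a), _as_counts(counts_b)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both row totals must be positive")
    table = np.vstack([a, b])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("fewer than two non-empty categories")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def chisq_2x2_up(counts_a, counts_b) -> tuple[float, int, float]:
    """Collapse to up vs (nc + down), then Pearson chi-square without
    continuity correction — isolates whether up-regulation drives a 2x3
    difference."""
    a, b = _as_counts(counts_a), _as_counts(counts_b)
    table = np.array([[a[0], a[1] + a[2]], [b[0], b[1] + b[2]]])
    if table.sum(axis=1).min() == 0:
        raise ValueError("both row totals must be positive")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("one category is empty in both sets")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def direction_bias(counts) -> float:
    """Consistency of the differential response: |up - down| / (up + down).

    1 means every differentially expressed gene moved the same way, 0 an
    even split.  Undefined (NaN) when no gene moved at all.
    """
    a = _as_counts(counts)
    up, _, down = a
    if up + down == 0:
        return float("nan")
    return float(abs(up - down) / (up + down))


def run_meta_study(
    counts: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]] = (("R", "control"), ("R", "stress")),
) -> pd.DataFrame:
    """Chi-square tests for every perturbation and set comparison, with BH
    correction applied per comparison type across perturbations.

    ``counts`` is long format: perturbation, set, up, nc, down.
    """
    results = []
    for set_a, set_b in comparisons:
        for pert, grp in counts.groupby("perturbation", sort=False):
            g = grp.set_index("set")
            ca = g.loc[set_a, ["up", "nc", "down"]].to_numpy()
            cb = g.loc[set_b, ["up", "nc", "down"]].to_numpy()
            chi2, df, p = contingency_chisq(ca, cb)
            try:
                chi2_up, _, p_up = chisq_2x2_up(ca, cb)
            except ValueError:  # no up-regulated genes in either set
                chi2_up, p_up = float("nan"), float("nan")
            results.append(
                (pert, f"{set_a}_vs_{set_b}", chi2, df, p, chi2_up, p_up,
                 direction_bias(ca), direction_bias(cb))
            )
    out = pd.DataFrame(
        results,
        columns=["perturbation", "comparison", "chi2", "df", "p",
                 "chi2_2x2_up", "p_2x2_up", "bias_a", "bias_b"],
    )
    out["p_adjusted"] = out.groupby("comparison")["p"].transform(
        lambda s: bh_adjust(s.to_numpy())
    )
    return out
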