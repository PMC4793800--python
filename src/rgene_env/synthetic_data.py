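"""Synthetic inputs with the statistical structure the pipeline assumes.

Every downstream stage (qPCR quantification, mixed models, gene-set
response tests, climate clines, resistance) can be exercised without any
external download.  The default qPCR design mirrors the study layout this
package targets: 12 Arabidopsis accessions (7 run through 8 treatments, 5
through 2), 13 target R-genes plus 3 reference genes, 3 biological x 3
technical replicates, and log2-scale expression whose random-effect
variances default to the published point estimates (gene 11.21,
gene x accession 5.72, residual 3.35).

True expression is generated on the log2 scale and converted to a
quantification cycle via Ct = (offset - y) / log2(E); amplification curves
are a baseline-plus-logistic stand-in for instrument fluorescence, chosen
so that the quantification stage can recover the generating (E, Ct) in a
round trip.  Reference genes receive no treatment, accession or
interaction effects (they emulate stably expressed normalizers) but keep
their own residual noise.

One RNG stream per logical component (effects, curves, noise), all spawned
from the master seed, so enlarging one part of the design never perturbs
the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QpcrDesign",
    "CurveParams",
    "SimulationParams",
    "ClinalMatrixParams",
    "SimulatedExperiment",
    "gen_normalized_truth",
    "gen_amp_curve",
    "gen_melt_curve",
    "gen_qpcr_experiment",
    "gen_expression_matrix",
    "gen_de_calls",
    "gen_cfu",
]

#: treatment ids in study order: control, short days, high temperature,
#: high water, low water, high temperature + low water, cold shock, heat shock
TREATMENTS = (
    "control",
    "short_day",
    "high_temp",
    "high_water",
    "low_water",
    "high_temp_low_water",
    "cold_shock",
    "heat_shock",
)

_FULL_ACCESSIONS = ("Col-0", "Cvi-0", "Est-1", "Fei-0", "Ler-1", "RRS-7", "Van-0")
_CLINE_ACCESSIONS = ("Kin-0", "Kno-11", "Rmx-A02", "SLSP-30", "Tsu-1")


@dataclass(frozen=True)
class QpcrDesign:
    accessions: tuple[str, ...]
    treatments_per_accession: Mapping[str, tuple[str, ...]]
    target_genes: tuple[str, ...]
    reference_genes: tuple[str, ...] = ("PP2A", "HEL", "bHLH")
    n_bio_reps: int = 3
    n_tech_reps: int = 3

    def __post_init__(self) -> None:
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValueError("replicate counts must be positive")
        if set(self.target_genes) & set(self.reference_genes):
            raise ValueError("target and reference gene sets must be disjoint")
        for acc in self.accessions:
            if not self.treatments_per_accession.get(acc):
                raise ValueError(f"accession {acc!r} maps to no treatments")

    @classmethod
    def default(cls) -> "QpcrDesign":
        """The study design: 7 accessions x 8 treatments, 5 x 2."""
        tpa = {a: TREATMENTS for a in _FULL_ACCESSIONS}
        tpa.update({a: TREATMENTS[:2] for a in _CLINE_ACCESSIONS})
        targets = tuple(f"R{i:02d}" for i in range(1, 14))
        return cls(
            accessions=_FULL_ACCESSIONS + _CLINE_ACCESSIONS,
            treatments_per_accession=tpa,
            target_genes=targets,
        )

    @property
    def genes(self) -> tuple[str, ...]:
        return self.target_genes + self.reference_genes

    def n_wells(self) -> int:
        cells = sum(len(self.treatments_per_accession[a]) for a in self.accessions)
        return cells * len(self.genes) * self.n_bio_reps * self.n_tech_reps


@dataclass(frozen=True)
class CurveParams:
    """Baseline plus generalized-logistic fluorescence for one amplification
    curve:

        F(c) = baseline + drift c + plateau (1 + E^(shape (m - c)))^(-1/shape)

    The ``shape`` constant controls how sharply the exponential phase turns
    into the plateau: below the shoulder the curve is an exact exponential
    with per-cycle ratio E (so log-linear estimators can recover E), and
    large ``shape`` keeps the exponential regime valid almost up to the
    plateau.  ``midpoint_shift`` positions m relative to the generating Ct;
    when None it is chosen so the noise-free curve crosses
    ``anchor_fraction`` of its plateau exactly at the generating Ct.
    """

    plateau: float = 100.0
    midpoint_shift: float | None = None
    shape: float = 8.0
    anchor_fraction: float = 0.10
    baseline: float = 5.0
    drift: float = 0.0
    noise_sd: float = 0.05
    n_cycles: int = 40
    melt_tm_dimer: float = 74.0
    melt_width: float = 0.8
    melt_amplitude: float = 100.0
    melt_floor: float = 2.0


@dataclass(frozen=True)
class SimulationParams:
    grand_mean_log2: float = 12.0
    sigma2_gene: float = 11.21
    sigma2_gene_accession: float = 5.72
    sigma2_residual: float = 3.35
    accession_effect_sd: float = 1.0
    treatment_effect_log2: Mapping[str, float] = field(
        default_factory=lambda: {
            "control": 0.0,
            # strongest response: 2.5-fold up-regulation after 3 h cold shock
            "cold_shock": math.log2(2.5),
            # more modest 1.6-fold responses for the other perturbations
            "short_day": math.log2(1.6),
            "high_temp": math.log2(1.6),
            "high_water": math.log2(1.6),
            "low_water": math.log2(1.6),
            "high_temp_low_water": math.log2(1.6),
            "heat_shock": math.log2(1.6),
        }
    )
    interaction_sd: float = 1.0
    ref_residual_sd: float = 0.0
    efficiency_true: float = 2.0
    ct_offset: float = 30.0
    curve: CurveParams = field(default_factory=CurveParams)
    primer_dimer_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_gene", "sigma2_gene_accession", "sigma2_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (1.0 < self.efficiency_true <= 3.0):
            raise ValueError("efficiency_true must lie in (1, 3]")


@dataclass
class SimulatedExperiment:
    wells: pd.DataFrame        # long: plate, well, labels, cycle, fluorescence
    melts: pd.DataFrame        # long: well, temperature, fluorescence
    well_info: pd.DataFrame    # one row per well: labels, ct_true, efficiency, dimer
    truth: dict                # every drawn effect, keyed by component
    expected_tm: dict[str, float]


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_normalized_truth(
    design: QpcrDesign, params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """True log2 expression per target gene x accession x treatment x bio rep.

    y = mu + gene + accession + treatment + accession x treatment
          + gene x accession + residual,
    with gene, gene x accession and residual drawn at the configured
    variances.  Returns the table and a truth dict of every drawn effect.
    """
    if rng is None:
        rng = _rng_streams(params.seed, 3)[0]
    genes = list(design.target_genes)
    accs = list(design.accessions)
    g_eff = dict(zip(genes, rng.normal(0.0, math.sqrt(params.sigma2_gene), len(genes))))
    a_eff = dict(zip(accs, rng.normal(0.0, params.accession_effect_sd, len(accs))))
    t_eff = {t: params.treatment_effect_log2.get(t, 0.0) for t in TREATMENTS}
    at_eff = {
        (a, t): rng.normal(0.0, params.interaction_sd)
        for a in accs
        for t in design.treatments_per_accession[a]
    }
    ga_eff = {
        (g, a): rng.normal(0.0, math.sqrt(params.sigma2_gene_accession))
        for g in genes
        for a in accs
    }
    rows = []
    resid = {}
    sd_e = math.sqrt(params.sigma2_residual)
    for a in accs:
        for t in design.treatments_per_accession[a]:
            for g in genes:
                for b in range(1, design.n_bio_reps + 1):
                    e = rng.normal(0.0, sd_e)
                    resid[(g, a, t, b)] = e
                    y = (
                        params.grand_mean_log2
                        + g_eff[g]
                        + a_eff[a]
                        + t_eff[t]
                        + at_eff[(a, t)]
                        + ga_eff[(g, a)]
                        + e
                    )
                    rows.append((g, a, t, b, y))
    df = pd.DataFrame(rows, columns=["gene", "accession", "treatment", "bio_rep", "y_true"])
    truth = {
        "grand_mean": params.grand_mean_log2,
        "gene": g_eff,
        "accession": a_eff,
        "treatment": t_eff,
        "accession:treatment": at_eff,
        "gene:accession": ga_eff,
        "residual": resid,
    }
    return df, truth


def gen_amp_curve(
    efficiency: float,
    ct_true: float,
    curve: CurveParams = CurveParams(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One amplification curve on cycles 1..n: a generalized logistic whose
    exponential phase has per-cycle ratio ``efficiency`` and which crosses
    ``anchor_fraction`` of the plateau at ``ct_true`` (see CurveParams)."""
    if not (1.0 < efficiency <= 3.0):
        raise ValueError("efficiency must lie in (1, 3]")
    if not (0.0 < ct_true < curve.n_cycles):
        raise ValueError("ct_true outside the cycle range")
    cycles = np.arange(1, curve.n_cycles + 1, dtype=float)
    g = curve.shape
    shift = curve.midpoint_shift
    if shift is None:
        # F(ct_true) = anchor_fraction * plateau exactly (noise-free)
        shift = math.log(curve.anchor_fraction ** (-g) - 1.0) / (g * math.log(efficiency))
    expo = g * math.log(efficiency) * (ct_true + shift - cycles)
    fluor = curve.baseline + curve.drift * cycles + curve.plateau * (
        1.0 + np.exp(np.clip(expo, -700.0, 700.0))
    ) ** (-1.0 / g)
    if rng is not None and curve.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, curve.noise_sd, len(cycles))
    return cycles, fluor


def gen_melt_curve(
    tm: float,
    curve: CurveParams = CurveParams(),
    rng: np.random.Generator | None = None,
    primer_dimer: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Dissociation curve from 60 to 95 C: fluorescence drops sigmoidally at
    the product Tm, so -dF/dT has a single dominant peak there.  With the
    primer-dimer flag a larger low-Tm component makes a spurious dominant
    peak at the dimer melting temperature."""
    temps = np.arange(60.0, 95.0 + 1e-9, 0.5)
    w = curve.melt_width
    fluor = curve.melt_floor + curve.melt_amplitude / (1.0 + np.exp((temps - tm) / w))
    if primer_dimer:
        fluor = fluor + 1.5 * curve.melt_amplitude / (
            1.0 + np.exp((temps - curve.melt_tm_dimer) / w)
        )
    if rng is not None and curve.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, curve.noise_sd, len(temps))
    return temps, fluor


def _default_tm_map(design: QpcrDesign) -> dict[str, float]:
    return {g: 80.0 + 2.0 * (i % 5) for i, g in enumerate(design.genes)}


def gen_qpcr_experiment(
    design: QpcrDesign, params: SimulationParams
) -> SimulatedExperiment:
    """Simulate a full plate export: one well per design cell x bio rep x
    tech rep x gene (targets and references), with amplification and melt
    curves, plus a truth table of every drawn effect."""
    effects_rng, curve_rng, noise_rng = _rng_streams(params.seed, 3)
    expr, truth = gen_normalized_truth(design, params, effects_rng)
    expr = expr.set_index(["gene", "accession", "treatment", "bio_rep"])["y_true"]

    # reference genes: stable baseline per gene, residual noise only
    ref_base = {
        g: effects_rng.normal(0.0, math.sqrt(params.sigma2_gene))
        for g in design.reference_genes
    }
    truth["reference_baseline"] = ref_base

    log2E = math.log2(params.efficiency_true)
    rows = []
    wid = 0
    for a in design.accessions:
        for t in design.treatments_per_accession[a]:
            for b in range(1, design.n_bio_reps + 1):
                for g in design.genes:
                    if g in ref_base:
                        y = (
                            params.grand_mean_log2
                            + ref_base[g]
                            + (noise_rng.normal(0.0, params.ref_residual_sd)
                               if params.ref_residual_sd > 0 else 0.0)
                        )
                    else:
                        y = expr.loc[(g, a, t, b)]
                    ct = (params.ct_offset - y) / log2E
                    # extreme draws would leave the cycle window; keep the
                    # curve generable and record the true (unclipped) value
                    ct = min(max(ct, 0.5), params.curve.n_cycles - 0.5)
                    dimer = (
                        params.primer_dimer_rate > 0
                        and curve_rng.random() < params.primer_dimer_rate
                    )
                    for k in range(1, design.n_tech_reps + 1):
                        wid += 1
                        rows.append((f"W{wid:06d}", g, a, t, b, k, ct, dimer))
    info = pd.DataFrame(
        rows,
        columns=["well", "gene", "accession", "treatment", "bio_rep",
                 "tech_rep", "ct_true", "primer_dimer"],
    )
    info["efficiency_true"] = params.efficiency_true
    info["plate"] = "P" + (1 + np.arange(len(info)) // 384).astype(str)
    tm_map = _default_tm_map(design)

    amp_frames, melt_frames = [], []
    for rec in info.itertuples(index=False):
        cycles, fluor = gen_amp_curve(
            params.efficiency_true, rec.ct_true, params.curve, curve_rng
        )
        amp_frames.append(
            pd.DataFrame({"well": rec.well, "cycle": cycles.astype(int), "fluorescence": fluor})
        )
        temps, mf = gen_melt_curve(
            tm_map[rec.gene], params.curve, curve_rng, primer_dimer=rec.primer_dimer
        )
        melt_frames.append(
            pd.DataFrame({"well": rec.well, "temperature": temps, "fluorescence": mf})
        )
    wells = pd.concat(amp_frames, ignore_index=True)
    melts = pd.concat(melt_frames, ignore_index=True)
    labels = info[["well", "plate", "gene", "accession", "treatment", "bio_rep", "tech_rep"]]
    wells = labels.merge(wells, on="well")
    melts = labels[["well", "plate", "gene"]].merge(melts, on="well")
    return SimulatedExperiment(
        wells=wells, melts=melts, well_info=info, truth=truth, expected_tm=tm_map
    )


# ---------------------------------------------------------------------------
# transcriptome matrices with a clinal gene set


@dataclass(frozen=True)
class ClinalMatrixParams:
    n_accessions: int = 96
    n_genes: int = 3000
    focal_set_size: int = 150
    covariate_name: str = "temperature_seasonality"
    covariate_range: tuple[float, float] = (15.0, 40.0)
    focal_slope: float = -0.1
    background_slope_sd: float = 0.02
    gene_mean_mu: float = 8.0
    gene_mean_sd: float = 2.0
    noise_sd: float = 1.0
    n_populations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.focal_set_size > self.n_genes:
            raise ValueError("focal_set_size exceeds n_genes")
        if self.n_populations not in (1, 2):
            raise ValueError("n_populations must be 1 or 2")


_CLIMATE_COLUMNS = (
    "latitude",
    "min_temp_coldest_month",
    "precip_driest_month",
    "temperature_seasonality",
)


def gen_expression_matrix(
    params: ClinalMatrixParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Gene x accession expression matrix in which a focal gene set carries
    a clinal slope against a climate covariate.

    Entry y_ga = m_g + b_g x_a + eps, with b_g = focal_slope for the focal
    set and b_g ~ N(0, background_slope_sd^2) otherwise.  All four climate
    covariates are driven by one latent gradient (they are highly
    correlated in real origin climates); the named covariate is an exact
    affine map of the latent so its values lie strictly inside the
    configured range.  With two populations, accessions split into labeled
    halves of the gradient (``south``/``north`` by increasing latitude).

    Returns (matrix, climate table, gene-set labels, population labels).
    """
    if params.covariate_name not in _CLIMATE_COLUMNS:
        raise ValueError(f"unknown covariate {params.covariate_name!r}")
    eff_rng, noise_rng = _rng_streams(params.seed, 2)
    n_a, n_g = params.n_accessions, params.n_genes
    u = eff_rng.uniform(1e-6, 1.0 - 1e-6, n_a)  # latent climate gradient
    jitter = lambda: eff_rng.normal(0.0, 0.02, n_a)
    lo, hi = params.covariate_range
    climate = pd.DataFrame(
        {
            "latitude": 40.0 + 25.0 * (u + jitter()),
            "min_temp_coldest_month": 10.0 - 25.0 * (u + jitter()),
            "precip_driest_month": 70.0 - 50.0 * (u + jitter()),
            "temperature_seasonality": 15.0 + 25.0 * (u + jitter()),
        },
        index=pd.Index([f"acc{i:03d}" for i in range(1, n_a + 1)], name="accession"),
    )
    climate[params.covariate_name] = lo + (hi - lo) * u
    x = climate[params.covariate_name].to_numpy()

    genes = pd.Index([f"g{i:05d}" for i in range(1, n_g + 1)], name="gene")
    focal = eff_rng.choice(n_g, size=params.focal_set_size, replace=False)
    is_focal = np.zeros(n_g, bool)
    is_focal[focal] = True
    m = eff_rng.normal(params.gene_mean_mu, params.gene_mean_sd, n_g)
    b = eff_rng.normal(0.0, params.background_slope_sd, n_g)
    b[is_focal] = params.focal_slope
    Y = m[:, None] + b[:, None] * x[None, :]
    if params.noise_sd > 0:
        Y = Y + noise_rng.normal(0.0, params.noise_sd, Y.shape)
    matrix = pd.DataFrame(Y, index=genes, columns=climate.index)
    labels = pd.Series(np.where(is_focal, "focal", "background"), index=genes, name="set")
    pops = pd.Series(
        np.where(u < 0.5, "south", "north"), index=climate.index, name="population"
    )
    if params.n_populations == 1:
        pops[:] = "all"
    return matrix, climate, labels, pops


def gen_de_calls(
    set_sizes: Mapping[str, int],
    category_probs: Mapping[str, tuple[float, float, float]],
    seed: int,
    contrast: str = "contrast1",
) -> pd.DataFrame:
    """Multinomial up / no-change / down calls per gene set for a contrast."""
    rng = np.random.default_rng(seed)
    frames = []
    for s, n in set_sizes.items():
        p = np.asarray(category_probs[s], float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("category probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities for set {s!r} do not sum to 1")
        cats = rng.choice(["up", "nc", "down"], size=n, p=p)
        frames.append(
            pd.DataFrame(
                {
                    "gene": [f"{s}_{i:05d}" for i in range(1, n + 1)],
                    "contrast": contrast,
                    "category": cats,
                    "set": s,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_cfu(
    group_means_log10: Mapping[tuple[str, str], float],
    sd: float,
    n_per_group: int,
    seed: int,
) -> pd.DataFrame:
    """Colony-forming-unit titers per (treatment, strain) group: log10 CFU
    drawn Normal(mean, sd^2)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)
    rows = []
    for (treatment, strain), mu in group_means_log10.items():
        logs = rng.normal(mu, sd, n_per_group)
        for i, lg in enumerate(logs, 1):
            rows.append((treatment, strain, i, 10.0 ** lg))
    return pd.DataFrame(rows, columns=["treatment", "strain", "replicate", "cfu"])
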