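"""Raw qPCR well fluorescence to per-replicate log2 normalized expression.

The quantification chain per well is:

1. baseline correction — subtract the mean fluorescence of the early
   cycles (default 1-8) from the whole curve;
2. efficiency and Ct — the per-cycle amplification ratio E comes from the
   best log-linear window of the corrected curve (>= 4 consecutive cycles
   maximizing R^2, restricted to 5-60 % of the plateau); Ct is the
   fractional cycle at which the corrected curve crosses an absolute
   fluorescence threshold, found by log-linear interpolation (exact for an
   exponential curve);
3. melt QC — wells whose dissociation peak sits below the expected product
   Tm (non-specific amplification / primer dimers) or whose melt curve has
   multiple comparable peaks are flagged and excluded;
4. relative quantity RQ = 1 / E^Ct;
5. normalization — technical replicates are aggregated by the median RQ,
   the target RQ is divided by the geometric mean of the surviving
   reference-gene RQs of the same biological replicate, and the result is
   reported as log2.

Wells with an efficiency outside [1.5, 2.2] are flagged but retained: the
primer-validation efficiency range describes dilution-series behaviour,
not a per-well rejection rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "QuantConfig",
    "baseline_correct",
    "estimate_efficiency_ct",
    "melt_tm",
    "dissociation_qc",
    "melt_filter",
    "relative_quantity",
    "normalize_and_log",
    "quantify_plates",
    "NoAmplificationError",
]

QC_FLAGS = ("low_tm", "irregular_melt", "no_amplification", "efficiency_out_of_range")


class NoAmplificationError(ValueError):
    """The corrected curve never crosses the threshold, or no usable
    log-linear window exists."""


@dataclass(frozen=True)
class QuantConfig:
    baseline_cycles: tuple[int, int] = (1, 8)
    threshold: float | None = None          # absolute; None = threshold_fraction of plateau
    threshold_fraction: float = 0.10        # of the median plateau across the plate
    window_min_cycles: int = 4
    window_lo_frac: float = 0.05
    window_hi_frac: float = 0.60
    efficiency_range: tuple[float, float] = (1.5, 2.2)
    melt_tolerance: float = 1.0             # degrees C below expected Tm
    peak_rel_height: float = 0.30           # secondary-peak rejection level
    peak_min_prominence: float = 0.5
    tech_rep_agg: str = "median"


def baseline_correct(
    cycles: np.ndarray, fluorescence: np.ndarray, baseline_cycles: tuple[int, int] = (1, 8)
) -> np.ndarray:
    """Subtract the mean fluorescence over the baseline cycle range."""
    cycles = np.asarray(cycles)
    fluorescence = np.asarray(fluorescence, float)
    lo, hi = baseline_cycles
    mask = (cycles >= lo) & (cycles <= hi)
    if not mask.any():
        raise ValueError("baseline cycle range selects no cycles")
    return fluorescence - fluorescence[mask].mean()


def _best_loglinear_window(
    cycles: np.ndarray, f: np.ndarray, lo: float, hi: float, min_len: int
) -> tuple[float, float] | None:
    """Least-squares slope (log10 F on cycle) over the best window.

    Candidate windows are runs of >= min_len consecutive cycles whose
    corrected fluorescence lies in [lo, hi] and is positive; the window
    maximizing R^2 wins (ties: earliest, then longest — resolved by
    iteration order with a strict improvement test).
    """
    positive = f > 0
    in_band = positive & (f >= lo) & (f <= hi)
    band_idx = np.flatnonzero(in_band)
    if len(band_idx) == 0:
        return None
    runs = np.split(band_idx, np.flatnonzero(np.diff(band_idx) != 1) + 1)

    def fit(sel: np.ndarray) -> tuple[float, float]:
        cc = cycles[sel]
        ll = np.log10(f[sel])
        vc = cc - cc.mean()
        vl = ll - ll.mean()
        sxx, syy, sxy = vc @ vc, vl @ vl, vc @ vl
        slope = sxy / sxx
        r2 = 1.0 if syy <= 1e-30 else (sxy * sxy) / (sxx * syy)
        return r2, slope

    best = None  # (r2, slope)
    for run in runs:
        if len(run) < min_len:
            continue
        for start in range(0, len(run) - min_len + 1):
            for stop in range(start + min_len, len(run) + 1):
                r2, slope = fit(run[start:stop])
                if best is None or r2 > best[0] + 1e-12:
                    best = (r2, slope)
    if best is not None:
        return best
    # no in-band run reaches min_len (a steep curve can cross the whole band
    # in < min_len cycles): extend the band run outward, preferring earlier
    # cycles where the curve is closest to exponential
    for run in runs:
        sel = list(run)
        while len(sel) < min_len and sel[0] > 0 and positive[sel[0] - 1]:
            sel.insert(0, sel[0] - 1)
        while len(sel) < min_len and sel[-1] + 1 < len(f) and positive[sel[-1] + 1]:
            sel.append(sel[-1] + 1)
        if len(sel) < min_len:
            continue
        r2, slope = fit(np.asarray(sel))
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, slope)
    return best


def estimate_efficiency_ct(
    cycles: np.ndarray,
    corrected: np.ndarray,
    threshold: float,
    config: QuantConfig = QuantConfig(),
) -> tuple[float, float, set[str]]:
    """Amplification efficiency and quantification cycle of one corrected curve.

    Returns (E, Ct, flags).  E = 10^slope of the best log-linear window;
    Ct is the fractional threshold crossing by log-linear interpolation.

    Raises
    ------
    NoAmplificationError
        if the curve never reaches the threshold or no log-linear window of
        the required length exists.
    """
    cycles = np.asarray(cycles, float)
    f = np.asarray(corrected, float)
    plateau = float(f.max())
    if plateau <= threshold:
        raise NoAmplificationError("curve never crosses the threshold")
    win = _best_loglinear_window(
        cycles, f, config.window_lo_frac * plateau, config.window_hi_frac * plateau,
        config.window_min_cycles,
    )
    if win is None:
        raise NoAmplificationError(
            f"fewer than {config.window_min_cycles} usable cycles for the "
            f"log-linear efficiency window"
        )
    _, slope = win
    eff = float(10.0 ** slope)
    above = np.flatnonzero(f >= threshold)
    i = above[0]
    if i == 0:
        ct = float(cycles[0])
    else:
        f0, f1 = f[i - 1], f[i]
        if f0 <= 0:
            # fall back to linear interpolation when the previous cycle is
            # at or below the corrected baseline
            ct = float(cycles[i - 1] + (threshold - f0) / (f1 - f0))
        else:
            ct = float(
                cycles[i - 1]
                + (math.log(threshold) - math.log(f0)) / (math.log(f1) - math.log(f0))
            )
    flags: set[str] = set()
    lo, hi = config.efficiency_range
    if not (lo <= eff <= hi):
        flags.add("efficiency_out_of_range")
    return eff, ct, flags


def melt_tm(temperatures: np.ndarray, fluorescence: np.ndarray) -> float:
    """Observed melting temperature: the global maximum of -dF/dT."""
    t = np.asarray(temperatures, float)
    f = np.asarray(fluorescence, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    d = -np.gradient(f, t)
    return float(t[np.argmax(d)])


def dissociation_qc(
    temperatures: np.ndarray,
    fluorescence: np.ndarray,
    rel_height: float = 0.30,
    min_prominence: float = 0.5,
) -> bool:
    """True when the dissociation curve looks like a single clean product.

    Fails (returns False) when -dF/dT has two or more local maxima each
    exceeding ``rel_height`` of the global maximum, or when the global
    maximum is below ``min_prominence`` (no product melted at all).
    """
    t = np.asarray(temperatures, float)
    f = np.asarray(fluorescence, float)
    if len(t) < 20:
        raise ValueError("need at least 20 temperature points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    d = -np.gradient(f, t)
    top = d.max()
    if top < min_prominence:
        return False
    peaks, _ = signal.find_peaks(d, height=rel_height * top)
    return len(peaks) < 2


def relative_quantity(efficiency: float, ct: float) -> float:
    """RQ = 1 / E^Ct: the relative template quantity implied by the
    quantification cycle at the given amplification efficiency."""
    if efficiency <= 1.0:
        raise ValueError("efficiency must exceed 1")
    if not math.isfinite(ct):
        raise ValueError("Ct must be finite")
    return float(efficiency ** (-ct))


def melt_filter(
    quant: pd.DataFrame,
    melts: pd.DataFrame,
    expected_tm: Mapping[str, float],
    tolerance: float = 1.0,
    rel_height: float = 0.30,
    min_prominence: float = 0.5,
) -> pd.DataFrame:
    """Attach melt-derived QC flags to a per-well quant table.

    ``low_tm``: observed Tm below expected - tolerance (non-specific
    product); ``irregular_melt``: missing melt curve, multiple comparable
    peaks, or no discernible peak.  Returns the table with ``tm_observed``
    and updated ``flags`` columns.
    """
    out = quant.copy()
    tms, extra = [], []
    grouped = dict(iter(melts.groupby("well"))) if len(melts) else {}
    for rec in out.itertuples(index=False):
        fl = set()
        g = grouped.get(rec.well)
        if g is None:
            tms.append(np.nan)
            fl.add("irregular_melt")
        else:
            t = g["temperature"].to_numpy()
            f = g["fluorescence"].to_numpy()
            tm = melt_tm(t, f)
            tms.append(tm)
            if rec.gene not in expected_tm:
                raise KeyError(f"no expected Tm for gene {rec.gene!r}")
            if tm < expected_tm[rec.gene] - tolerance:
                fl.add("low_tm")
            if not dissociation_qc(t, f, rel_height, min_prominence):
                fl.add("irregular_melt")
        extra.append(fl)
    out["tm_observed"] = tms
    out["flags"] = [set(a) | b for a, b in zip(out["flags"], extra)]
    return out


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def normalize_and_log(
    quant: pd.DataFrame,
    reference_genes: Iterable[str],
    min_references: int = 2,
    agg: str = "median",
) -> pd.DataFrame:
    """Per-biological-replicate log2 normalized relative quantities.

    Technical replicates are aggregated first (median RQ by default);
    within each accession x treatment x biological replicate the target RQ
    is divided by the geometric mean of the surviving reference-gene RQs
    (at least ``min_references`` required) and reported as log2.
    Rows with failed QC (non-empty flags) must be removed beforehand.
    """
    refs = set(reference_genes)
    if (quant["rq"] <= 0).any():
        raise ValueError("all RQs must be positive")
    aggfun = {"median": np.median, "mean": np.mean}[agg]
    per_bio = (
        quant.groupby(["gene", "accession", "treatment", "bio_rep"], sort=True)["rq"]
        .apply(lambda v: aggfun(v.to_numpy()))
        .reset_index()
    )
    rows = []
    for (acc, trt, bio), grp in per_bio.groupby(["accession", "treatment", "bio_rep"], sort=True):
        is_ref = grp["gene"].isin(refs)
        ref_rqs = grp.loc[is_ref, "rq"].to_numpy()
        if len(ref_rqs) < min_references:
            raise ValueError(
                f"only {len(ref_rqs)} reference RQs for accession={acc!r} "
                f"treatment={trt!r} bio_rep={bio}; need >= {min_references}"
            )
        gm = _geomean(ref_rqs)
        for g, rq in grp.loc[~is_ref, ["gene", "rq"]].itertuples(index=False):
            rows.append((g, acc, trt, bio, math.log2(rq / gm)))
    return pd.DataFrame(rows, columns=["gene", "accession", "treatment", "bio_rep", "value"])


def quantify_plates(
    wells: pd.DataFrame,
    melts: pd.DataFrame,
    expected_tm: Mapping[str, float],
    reference_genes: Iterable[str],
    config: QuantConfig = QuantConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: long plate export -> (normalized expression, QC report).

    ``wells`` is long format (plate, well, gene, accession, treatment,
    bio_rep, tech_rep, cycle, fluorescence); ``melts`` parallels it with
    temperature.  The Ct threshold defaults to ``threshold_fraction`` of
    the median per-well plateau across the plate.
    """
    label_cols = ["well", "plate", "gene", "accession", "treatment", "bio_rep", "tech_rep"]
    labels = wells[label_cols].drop_duplicates("well").reset_index(drop=True)
    corrected: dict[str, np.ndarray] = {}
    plateaus = {}
    cyc: dict[str, np.ndarray] = {}
    for well, g in wells.groupby("well"):
        c = g["cycle"].to_numpy(float)
        f = baseline_correct(c, g["fluorescence"].to_numpy(float), config.baseline_cycles)
        corrected[well] = f
        cyc[well] = c
        plateaus[well] = f.max()
    threshold = config.threshold
    if threshold is None:
        threshold = config.threshold_fraction * float(np.median(list(plateaus.values())))
    recs = []
    for rec in labels.itertuples(index=False):
        flags: set[str] = set()
        eff = ct = rq = np.nan
        try:
            eff, ct, flags = estimate_efficiency_ct(
                cyc[rec.well], corrected[rec.well], threshold, config
            )
            rq = relative_quantity(eff, ct)
        except NoAmplificationError:
            flags = {"no_amplification"}
        recs.append((*rec, eff, ct, rq, flags))
    quant = pd.DataFrame(recs, columns=label_cols + ["efficiency", "ct", "rq", "flags"])
    quant = melt_filter(
        quant, melts, expected_tm, config.melt_tolerance,
        config.peak_rel_height, config.peak_min_prominence,
    )
    qc_report = quant[["well", "plate", "gene", "accession", "treatment",
                       "bio_rep", "tech_rep", "efficiency", "ct", "tm_observed"]].copy()
    qc_report["flags"] = quant["flags"].map(lambda s: ";".join(sorted(s)))
    # efficiency_out_of_range wells are reported but retained
    drop = quant["flags"].map(lambda s: bool(s - {"efficiency_out_of_range"}))
    retained = quant[~drop]
    norm = normalize_and_log(retained, reference_genes, agg=config.tech_rep_agg)
    return norm, qc_report
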