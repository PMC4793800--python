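"""File readers/writers, run configuration and pipeline orchestration.

Conventions: internal genomic coordinates are 0-based half-open regardless
of the source format (GFF3's 1-based closed intervals are converted on
read and restored on write); chromosome names are normalized by stripping
a ``Chr``/``chr`` prefix, with the mapping logged.  Expression matrices
are TSV with the gene id in the first column and accessions as headers.
Every pipeline run writes a provenance record (config hash, seed, package
version, input checksums) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import gffutils
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_matrix",
    "write_matrix",
    "read_climate",
    "read_de_calls",
    "bundled_meta_study_counts",
    "RunConfig",
    "load_config",
    "run_pipeline",
    "DataError",
]

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def _normalize_chrom(name: str) -> str:
    if name.lower().startswith("chr"):
        return name[3:]
    return name


def read_annotation(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Gene annotation from GFF3 or BED as (gene, chrom, start, end, strand).

    Coordinates are normalized to 0-based half-open: GFF3's 1-based closed
    start is decremented; BED passes through.  ``fmt`` defaults from the
    file suffix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    fmt = fmt.lower()
    if fmt == "gff3":
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        types = set(db.featuretypes())
        ftype = "gene" if "gene" in types else None
        rows = []
        for feat in db.all_features(featuretype=ftype):
            gid = feat.attributes.get("ID", [feat.id])[0]
            rows.append(
                (gid, _normalize_chrom(feat.seqid), feat.start - 1, feat.end, feat.strand)
            )
        if not rows:
            raise DataError(f"no features parsed from {path}")
        out = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
    elif fmt == "bed":
        try:
            raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise DataError(f"cannot parse BED file {path}: {exc}") from exc
        if raw.shape[1] < 3:
            raise DataError(f"BED file {path} has fewer than 3 columns")
        out = pd.DataFrame(
            {
                "gene": raw[3] if raw.shape[1] > 3 else [f"feature{i}" for i in range(len(raw))],
                "chrom": raw[0].astype(str).map(_normalize_chrom),
                "start": raw[1].astype(int),
                "end": raw[2].astype(int),
                "strand": raw[5] if raw.shape[1] > 5 else ".",
            }
        )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    if (out["start"] < 0).any() or (out["start"] >= out["end"]).any():
        bad = out[(out["start"] < 0) | (out["start"] >= out["end"])].iloc[0]
        raise DataError(f"malformed interval for gene {bad['gene']!r}")
    return out


def write_annotation(annot: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write annotation back out (GFF3 restored to 1-based closed)."""
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    fmt = fmt.lower()
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for r in annot.itertuples(index=False):
                fh.write(
                    f"{r.chrom}\trgene_env\tgene\t{r.start + 1}\t{r.end}\t.\t"
                    f"{r.strand}\t.\tID={r.gene}\n"
                )
        elif fmt == "bed":
            for r in annot.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t0\t{r.strand}\n")
        else:
            raise ValueError(f"unknown annotation format {fmt!r}")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x accession expression matrix from TSV (gene ids in column 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"duplicate gene id {dup!r} in {path}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise DataError(
                f"non-numeric cell at gene {df.index[bad.argmax()]!r}, column {col!r}"
            )
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_climate(path: str | Path) -> pd.DataFrame:
    """Per-accession climate table, indexed by accession; duplicate
    accessions are rejected."""
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise DataError(f"duplicated accessions in climate table {path}")
    return df


def read_de_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "contrast", "category"}
    if not required <= set(df.columns):
        raise DataError(f"DE-call table {path} lacks columns {required - set(df.columns)}")
    return df


def bundled_meta_study_counts() -> pd.DataFrame:
    """The bundled per-perturbation response-count table: numbers of R-,
    positionally matched control, and stress-response genes scored
    up / no-change / down across 15 published environmental perturbations."""
    path = Path(__file__).parent / "data" / "meta_study_counts.tsv"
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    stages: tuple[str, ...] = ("simulate", "qpcr", "lmm")
    simulate: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)
    lmm: dict = field(default_factory=dict)
    log_level: str = "INFO"

    _KNOWN = {"seed", "out_dir", "stages", "simulate", "qpcr", "lmm", "log_level"}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise DataError("config must set an explicit seed")
        kwargs = dict(d)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def config_hash(config: RunConfig) -> str:
    return _sha256(json.dumps(asdict(config), sort_keys=True).encode())[:16]


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the requested stages in dependency order.

    simulate -> synthetic plate exports; qpcr -> normalized expression +
    QC report; lmm -> variance components and ANOVA of the fixed design.
    Identical config and inputs yield byte-identical outputs.  Returns a
    mapping of artifact name to path.
    """
    from . import mixed_models as mm
    from . import qpcr_quant as qq
    from . import synthetic_data as sd

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    order = [s for s in ("simulate", "qpcr", "lmm") if s in config.stages]

    design = params = None
    if "simulate" in order:
        sim_cfg = dict(config.simulate)
        design = _small_design(sim_cfg.pop("n_accessions", 4), sim_cfg.pop("n_genes", 5))
        params = sd.SimulationParams(seed=config.seed, **sim_cfg)
        exp = sd.gen_qpcr_experiment(design, params)
        exp.wells.to_csv(out / "plates.csv", index=False)
        exp.melts.to_csv(out / "melts.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(_jsonable(exp.truth), fh, indent=1, sort_keys=True)
        with open(out / "expected_tm.yaml", "w") as fh:
            yaml.safe_dump(exp.expected_tm, fh)
        artifacts.update(
            plates=str(out / "plates.csv"), melts=str(out / "melts.csv"),
            truth=str(out / "truth.json"), expected_tm=str(out / "expected_tm.yaml"),
        )

    if "qpcr" in order:
        plates_path = config.qpcr.get("plates", artifacts.get("plates"))
        melts_path = config.qpcr.get("melts", artifacts.get("melts"))
        tm_path = config.qpcr.get("expected_tm", artifacts.get("expected_tm"))
        for name, p in [("plates", plates_path), ("melts", melts_path),
                        ("expected_tm", tm_path)]:
            if p is None or not Path(p).exists():
                raise DataError(f"qpcr stage requires upstream artifact {name!r}")
        wells = pd.read_csv(plates_path)
        melts = pd.read_csv(melts_path)
        with open(tm_path) as fh:
            tm = yaml.safe_load(fh)
        refs = config.qpcr.get(
            "reference_genes",
            list(design.reference_genes) if design else ["PP2A", "HEL", "bHLH"],
        )
        norm, qc = qq.quantify_plates(wells, melts, tm, refs, qq.QuantConfig())
        norm.to_csv(out / "normalized_expression.tsv", sep="\t", index=False)
        qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        artifacts.update(
            normalized=str(out / "normalized_expression.tsv"),
            qc=str(out / "qc_report.tsv"),
        )

    if "lmm" in order:
        data_path = config.lmm.get("data", artifacts.get("normalized"))
        if data_path is None or not Path(data_path).exists():
            raise DataError("lmm stage requires upstream artifact 'normalized'")
        data = pd.read_csv(data_path, sep="\t")
        spec = mm.ModelSpec(
            fixed=tuple(config.lmm.get("fixed", ("accession", "treatment", "accession:treatment"))),
            random=tuple(config.lmm.get("random", ("gene", "gene:accession"))),
        )
        fit = mm.fit_lmm(data, spec)
        props = mm.variance_proportions(fit)
        anova = mm.anova_table(fit, data)
        with open(out / "lmm_fit.json", "w") as fh:
            json.dump(
                {
                    "fixed_estimates": fit.fixed_estimates,
                    "variance_estimates": fit.variance_estimates,
                    "proportions": props.proportions,
                    "reml_criterion": fit.reml_criterion,
                    "converged": fit.converged,
                },
                fh, indent=1, sort_keys=True,
            )
        anova.rows.to_csv(out / "anova.tsv", sep="\t", index=False)
        artifacts.update(fit=str(out / "lmm_fit.json"), anova=str(out / "anova.tsv"))

    checksums = {}
    for name, p in artifacts.items():
        checksums[name] = _sha256(Path(p).read_bytes())
    from . import __version__

    provenance = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": order,
        "checksums": checksums,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    artifacts["provenance"] = str(out / "provenance.json")
    return artifacts


def _small_design(n_accessions: int, n_genes: int):
    from . import synthetic_data as sd

    full = sd.QpcrDesign.default()
    accs = full.accessions[:n_accessions]
    return sd.QpcrDesign(
        accessions=accs,
        treatments_per_accession={a: full.treatments_per_accession[a][:2] for a in accs},
        target_genes=full.target_genes[:n_genes],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
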