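import numpy as np
import pandas as pd
import pytest

from rgene_env import synthetic_data as sd


@pytest.fixture(scope="session")
def small_design() -> sd.QpcrDesign:
    """4 accessions x 2 treatments, 5 target genes + 3 references."""
    full = sd.QpcrDesign.default()
    accs = full.accessions[:4]
    return sd.QpcrDesign(
        accessions=accs,
        treatments_per_accession={a: ("control", "cold_shock") for a in accs},
        target_genes=full.target_genes[:5],
    )


@pytest.fixture(scope="session")
def quiet_params() -> sd.SimulationParams:
    """Low-variance, noise-free parameters for exact round-trip checks."""
    return sd.SimulationParams(
        seed=42,
        sigma2_gene=2.0,
        sigma2_gene_accession=0.5,
        sigma2_residual=0.2,
        accession_effect_sd=0.5,
        interaction_sd=0.3,
        ref_residual_sd=0.0,
        curve=sd.CurveParams(noise_sd=0.0),
    )


@pytest.fixture(scope="session")
def sim_experiment(small_design, quiet_params) -> sd.SimulatedExperiment:
    return sd.gen_qpcr_experiment(small_design, quiet_params)


@pytest.fixture(scope="session")
def reduced_coverage_design() -> sd.QpcrDesign:
    """Unbalanced design with fewer accessions: 4 full x 8 treatments plus
    2 x 2, all 13 target genes — used for simulation-heavy checks."""
    accs = ("Col-0", "Cvi-0", "Est-1", "Fei-0", "Kin-0", "Kno-11")
    tpa = {a: sd.TREATMENTS for a in accs[:4]}
    tpa.update({a: sd.TREATMENTS[:2] for a in accs[4:]})
    return sd.QpcrDesign(
        accessions=accs,
        treatments_per_accession=tpa,
        target_genes=tuple(f"R{i:02d}" for i in range(1, 14)),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
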