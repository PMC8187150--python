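import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import episig as ep

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """The standard simulated panel: 3 disorders x 20 cases, 100 controls,
    200 signature probes each at delta 0.15, 20,000 background probes."""
    return ep.simulate_cohort(ep.default_config(seed=42))


@pytest.fixture(scope="session")
def default_kdb(default_cohort):
    c = default_cohort
    return ep.build_kdb(
        c.beta, c.sheet, annotation=c.annotation, cv_folds=10, seed=42,
        version="sim-default",
    )


@pytest.fixture(scope="session")
def small_config():
    """A reduced two-disorder panel with mosaic, dilution, locus-aberrant
    and replicate samples, for fast unit tests."""
    return ep.SimulationConfig(
        n_background_probes=1500,
        disorders=(
            ep.DisorderSim("SYND_A", n_signature_probes=60, delta=0.20,
                           n_cases=10, n_test=5),
            ep.DisorderSim("SYND_B", n_signature_probes=60, delta=0.15,
                           n_cases=10, n_test=5),
        ),
        n_controls=30,
        n_test_controls=10,
        technical_sd=0.01,
        mosaic_samples=(ep.MosaicSim("SYND_A", 0.5),),
        dilution_samples=(ep.DilutionSim("SYND_A", 0.5),),
        imprinted_loci=(
            ep.LocusSim("ICR_A", "imprinted_dmr", 10,
                        (ep.AberrantSim("hypo", 0.9),)),
        ),
        repeat_loci=(
            ep.LocusSim("TNR_X", "repeat_locus", 10,
                        (ep.AberrantSim("hyper", 1.0),)),
        ),
        replicate_pairs=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ep.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_kdb(small_cohort):
    c = small_cohort
    return ep.build_kdb(
        c.beta, c.sheet, annotation=c.annotation, cv_folds=5, seed=3,
        version="sim-small",
    )


@pytest.fixture()
def tiny_signature():
    """A handcrafted three-probe signature for store round-trip tests."""
    return ep.Episignature(
        disorder_id="TOY",
        version="9",
        probe_ids=["cg1", "cg2", "cg3"],
        control_mean=np.array([0.2, 0.5, 0.8]),
        case_mean=np.array([0.4, 0.6, 0.7]),
        delta=np.array([0.2, 0.1, -0.1]),
        selection_stat=np.array([3.0, 2.0, 1.0]),
        n_cases=8,
        n_controls=20,
    )


def make_beta(values, probes=None, samples=None) -> ep.BetaMatrix:
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ep.BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))
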