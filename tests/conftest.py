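import numpy as np
import pytest

import bloodspec as bs


@pytest.fixture
def fingerprint_axis():
    """4 cm^-1 axis over the fingerprint region, 226 points."""
    return 900.0 + 4.0 * np.arange(226)


@pytest.fixture
def full_axis():
    """4 cm^-1 axis over 400-4000 cm^-1, 901 points."""
    return 400.0 + 4.0 * np.arange(901)


def make_dataset(axis, rows, metas):
    return bs.SpectralDataset(np.asarray(axis, float), np.asarray(rows, float), list(metas))


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def tiny_dataset(fingerprint_axis):
    """4 spectra, 2 subjects x 2 replicates, one Gaussian band each."""
    rng = np.random.default_rng(42)
    rows = []
    metas = []
    for subj, group in (("S1", "HC"), ("S2", "CVID")):
        for rep in (1, 2):
            amp = 0.5 + 0.1 * rng.standard_normal()
            rows.append(amp * np.exp(-0.5 * ((fingerprint_axis - 1300) / 40) ** 2))
            metas.append(
                bs.SampleMeta(subj, group, "complications" if group == "CVID" else "none_assigned",
                              "serum", 1, rep)
            )
    return make_dataset(fingerprint_axis, rows, metas)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared across tests (seed 11)."""
    ds, truth = bs.generate(bs.default_config(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def small_sim():
    """A reduced study for fast classification tests: 10+4+6 subjects,
    2x2 replicates."""
    import dataclasses

    cfg = dataclasses.replace(
        bs.default_config(seed=5), n_hc=10, n_cvid_non=4, n_cvid_comp=6,
        spots=2, points_per_spot=2,
    )
    ds, truth = bs.generate(cfg)
    return cfg, ds, truth
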