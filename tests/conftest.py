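"""Shared fixtures: small simulated bundles and analyzed plates."""

import warnings

import pytest

import dropgate as dg


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Three-well bundle: two healthy PN/PP wells and one under-filled well
    that must fail QC. Returns (directory, specs)."""
    directory = tmp_path_factory.mktemp("bundle")
    specs = {
        "A01": dg.SimParams(seed=1, n_droplets=8000, lambda_wt=0.5, lambda_mut=0.05),
        "A02": dg.SimParams(seed=2, n_droplets=8000, lambda_wt=0.4, lambda_mut=0.1),
        "B01": dg.SimParams(seed=3, n_droplets=1200),
    }
    dg.simulate_plate_bundle(specs, directory, prefix="FIX")
    return directory, specs


@pytest.fixture(scope="session")
def fresh_plate(sim_bundle):
    directory, _ = sim_bundle
    return dg.new_plate(directory, assay_type="fam_positive_pnpp")


@pytest.fixture(scope="session")
def analyzed_plate(fresh_plate):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dg.analyze(fresh_plate)
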