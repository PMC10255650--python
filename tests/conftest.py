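import numpy as np
import pandas as pd
import pytest

import uavpheno as u


@pytest.fixture(scope="session")
def gconf():
    return u.default_genetic_config()


@pytest.fixture
def make_obs():
    """Build TraitObservations from a (g, r) value matrix."""

    def _make(matrix, trait="x", trial=""):
        matrix = np.asarray(matrix, dtype=float)
        g, r = matrix.shape
        return u.TraitObservations(
            trait=trait,
            genotype=np.repeat([f"G{i:03d}" for i in range(g)], r),
            replicate=np.tile(np.arange(1, r + 1), g),
            value=matrix.ravel(),
            trial=trial,
        )

    return _make


@pytest.fixture(scope="session")
def planted_spectra():
    """400 samples with random band reflectances and a planted linear
    GY = 2000 + 8000 * ND(840, 650) link (noise-free)."""
    rng = np.random.default_rng(42)
    n = 400
    bands = {
        450: 0.02 + 0.08 * rng.random(n),
        560: 0.05 + 0.10 * rng.random(n),
        650: 0.03 + 0.20 * rng.random(n),
        730: 0.15 + 0.15 * rng.random(n),
        840: 0.25 + 0.30 * rng.random(n),
    }
    nd = (bands[840] - bands[650]) / (bands[840] + bands[650])
    df = pd.DataFrame({f"b{b}": v for b, v in bands.items()})
    df["sample_id"] = [f"s{i}" for i in range(n)]
    df["plot_id"] = df["sample_id"]
    df["is_soil"] = False
    df["GY"] = 2000.0 + 8000.0 * nd
    return df


@pytest.fixture
def small_run_config(tmp_path):
    """Reduced pipeline configuration that runs in seconds."""

    def _make(seed=1, outdir=None, **over):
        kwargs = dict(
            seed=seed,
            outdir=str(outdir or tmp_path / "run"),
            trials=[u.TrialConfig("CVT1", 10), u.TrialConfig("CVT2", 12)],
            missions=[
                u.MissionConfig("M1", "PS", "milk", 0.010, 1.0),
                u.MissionConfig("M2", "P4M", "milk", 0.008, 1.0),
            ],
            n_soil=20,
            cv_folds=5,
            ml_methods=["plsr", "krr"],
            parametric_families=["R", "ND", "SR"],
        )
        kwargs.update(over)
        return u.RunConfig(**kwargs)

    return _make
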