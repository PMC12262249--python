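import pytest

from mmscreen import codec, lineage


@pytest.fixture(scope="session")
def small_codebook() -> codec.Codebook:
    """1,000-entry 30-bit codebook shared across fast tests."""
    return codec.sample_codebook(1000, 30, seed=101)


@pytest.fixture(scope="session")
def scheme() -> codec.ReadoutScheme:
    return codec.make_readout_scheme(n_bits=30, seed=102)


@pytest.fixture(scope="session")
def noiseless_cells():
    """Deterministic growth at 2 dbl/h: zero measurement, division and septum noise."""
    cfg = lineage.SimConfig(
        n_trenches_per_sgrna=3, measurement_cv=0.0, division_cv=0.0, seed=103
    )
    strain = lineage.StrainEffect(
        sgrna_id="clean", strength=0.0,
        baseline={**lineage.BASELINE, "growth_rate": 2.0, "septum_sd": 0.0},
    )
    return lineage.simulate_experiment(cfg, [strain])
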