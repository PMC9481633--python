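import pytest

from beeload import pipeline, simulate


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("bundle")


@pytest.fixture(scope="session")
def clean_bundle(bundle_dir):
    """Bundle with no use missingness: ground truth is exactly recoverable."""
    cfg = simulate.SimConfig(seed=20260930, n_states=2, missing_rate_use=0.0)
    return simulate.generate_fixture_bundle(cfg, bundle_dir / "clean")


@pytest.fixture(scope="session")
def clean_result(clean_bundle):
    bundle, _ = clean_bundle
    return pipeline.run(
        bundle.use,
        bundle.census,
        bundle.survey,
        bundle.ecotox,
        bundle.ppdb,
        bundle.crop_key,
        bundle.compound_key,
        max_year=None,
        interpolate=False,
    )
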