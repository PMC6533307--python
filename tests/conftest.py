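import pytest

from phenolprofiler import io as pio
from phenolprofiler import rsm


@pytest.fixture(scope="session")
def extraction_design():
    """The packaged 20-run CCC design with total-phenolic responses."""
    return pio.load_extraction_design()


@pytest.fixture(scope="session")
def fitted_surface(extraction_design):
    return rsm.fit_quadratic(extraction_design)


@pytest.fixture(scope="session")
def spectral_trees():
    """The 23 packaged spectral trees."""
    return pio.load_spectral_trees()


@pytest.fixture(scope="session")
def reference_annotations():
    """Published (identification, group) per peak id."""
    return pio.load_reference_annotations()


@pytest.fixture(scope="session")
def trees_by_id(spectral_trees):
    return {t.peak_id: t for t in spectral_trees}
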