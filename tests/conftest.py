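import numpy as np
import pytest

from glycosite import identify, pipeline, synth


@pytest.fixture(scope="session")
def library():
    from glycosite.glyco import default_library

    return default_library()


@pytest.fixture(scope="session")
def glycan_index():
    """Structure index over the default library (built once; ~40k structures)."""
    return identify.GlycanIndex()


@pytest.fixture(scope="session")
def default_noise_result(glycan_index):
    """The default synthetic study (200 glycopeptides, seed 1, default noise)
    run end-to-end; shared by recovery, quantification and categorization
    tests."""
    return pipeline.run_pipeline(synth.StudyDesign(), seed=1, index=glycan_index)


@pytest.fixture(scope="session")
def small_study():
    """Small noise-free study for spectra-level tests."""
    return synth.generate_study(synth.StudyDesign(n_glycopeptides=8, noise=False), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
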