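import numpy as np
import pytest

from idrfold import SyntheticProteomeSpec, gen_proteome_tracks


@pytest.fixture(scope="session")
def small_proteome():
    """A 40-protein synthetic proteome at the default study conditions."""
    spec = SyntheticProteomeSpec(n_proteins=40, length_range=(300, 600), seed=1)
    tracks, truth = gen_proteome_tracks(spec)
    return spec, tracks, truth


@pytest.fixture(scope="session")
def track_map(small_proteome):
    _, tracks, _ = small_proteome
    return {t.protein_id: t for t in tracks}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
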