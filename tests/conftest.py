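import numpy as np
import pytest

from chemmap import ScreenSimConfig


@pytest.fixture
def null_screen_config():
    """Reduced screen with all positional effects planted at zero."""
    return ScreenSimConfig(
        n_targets=2,
        sites_per_target=2,
        duplexes_per_site=15,
        doses_nM=(0.1,),
        replicates=2,
        gamma_sense=np.zeros(21),
        gamma_antisense=np.zeros(23),
        seed=0,
    )


@pytest.fixture
def tiny_screen_config():
    """Single-duplex, noise-free screen for exact-value checks."""
    return ScreenSimConfig(
        n_targets=1,
        sites_per_target=1,
        duplexes_per_site=1,
        doses_nM=(0.1,),
        replicates=1,
        noise_sd=0.0,
        site_sd=0.0,
        target_sd=0.0,
        patterns=[("M" * 21, "M" * 23)],
        seed=0,
    )
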