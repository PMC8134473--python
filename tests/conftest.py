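import numpy as np
import pytest

from arrkit import DiversitySeries, rescale_series


@pytest.fixture
def flat_series():
    """Constant-richness series: 400 species from 290 Ma to the present,
    stem origin at 300 Ma."""
    ages = np.arange(290.0, -1.0, -10.0)
    return rescale_series(
        DiversitySeries(
            clade="flat",
            stem_age_ma=300.0,
            ages_ma=ages,
            raw_richness=np.full(len(ages), 400.0),
            rescale_mode="none",
        )
    )


@pytest.fixture
def exponential_series():
    """Deterministic pure-exponential growth at r = 0.02 from a single
    stem lineage, origin at 300 Ma (the ARR model's own world, eps = 0)."""
    ages = np.arange(290.0, -1.0, -10.0)
    elapsed = 300.0 - ages
    n = np.maximum(1, np.rint(np.exp(0.02 * elapsed)))
    return rescale_series(
        DiversitySeries(
            clade="exp_true",
            stem_age_ma=300.0,
            ages_ma=ages,
            raw_richness=n,
            rescale_mode="none",
        )
    )
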