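import numpy as np
import pytest

from neurolipidomics.fatty_acids import profile_from_mol_percent
from neurolipidomics.reference import GM_MEDIAN_MOLPCT, WM_MEDIAN_MOLPCT


@pytest.fixture(scope="session")
def gm_profile():
    """Grey-matter median composition of the middle-aged control group."""
    return profile_from_mol_percent(GM_MEDIAN_MOLPCT, sample_id="GM-median", region="GM")


@pytest.fixture(scope="session")
def wm_profile():
    """White-matter median composition of the middle-aged control group."""
    return profile_from_mol_percent(WM_MEDIAN_MOLPCT, sample_id="WM-median", region="WM")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_molpct(rng, n=26):
    """Random 26-species composition summing to 100."""
    from neurolipidomics.species import DEFAULT_PANEL_LABELS

    v = rng.uniform(0.05, 10.0, n)
    v = 100.0 * v / v.sum()
    return dict(zip(DEFAULT_PANEL_LABELS, v))
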