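import hypothesis
from hypothesis import strategies as st

from dmimap.cytology import SUBDIVISIONS, CytoBand, CytoInterval, band_sort_key

hypothesis.settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=100
)
hypothesis.settings.load_profile("default")


# --- shared strategies over a small explicit band axis -----------------------

def euchromatic_bands(max_division: int = 20, max_band: int = 6):
    """Fully specified euchromatic bands."""
    return st.builds(
        CytoBand,
        division=st.integers(1, max_division),
        subdivision=st.sampled_from(SUBDIVISIONS),
        band=st.integers(1, max_band),
    )


def h_bands():
    return st.builds(
        CytoBand, division=st.integers(25, 29), heterochromatin=st.just(True)
    )


def any_bands():
    return st.one_of(euchromatic_bands(), h_bands())


@st.composite
def intervals(draw, bands=None):
    bands = bands or euchromatic_bands()
    a, b = draw(bands), draw(bands)
    if band_sort_key(a) > band_sort_key(b):
        a, b = b, a
    return CytoInterval(a, b)
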