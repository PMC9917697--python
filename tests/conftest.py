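import numpy as np
import pytest

from mvpipeline.cohort import default_config, generate_cohort
from mvpipeline.scoring import (
    EchoFeatures,
    LeafletMorphology,
    LeafletMotion,
)

try:
    from hypothesis import strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


@pytest.fixture(scope="session")
def small_cohort():
    """143-patient default synthetic cohort, seed 0 (shared read-only)."""
    return generate_cohort(default_config(n_patients=143, seed=0))


@pytest.fixture(scope="session")
def medium_cohort():
    """600-patient default synthetic cohort, seed 0 (shared read-only)."""
    return generate_cohort(default_config(n_patients=600, seed=0))


if HAVE_HYPOTHESIS:

    def echo_features_strategy():
        bools = st.booleans()
        return st.builds(
            EchoFeatures,
            prolapse_p1=bools,
            prolapse_p2=bools,
            prolapse_p3=bools,
            prolapse_a1=bools,
            prolapse_a2=bools,
            prolapse_a3=bools,
            prolapse_anterolateral_commissure=bools,
            prolapse_posteromedial_commissure=bools,
            ruptured_chordae=bools,
            leaflet_morphology=st.sampled_from(list(LeafletMorphology)),
            calc_leaflet=bools,
            calc_annulus=bools,
            calc_chordae=bools,
            commissure_fusion=bools,
            vegetation_class=st.integers(0, 2),
            perforation_cleft_class=st.integers(0, 2),
            leaflet_motion=st.sampled_from(list(LeafletMotion)),
        )
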