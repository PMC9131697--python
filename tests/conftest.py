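import numpy as np
import pytest

import issmap as im


@pytest.fixture(scope="session")
def profiles124():
    """The full 124-gene, 13-type oligodendrocyte-style panel."""
    return im.make_reference_profiles(seed=1)


@pytest.fixture(scope="session")
def demo():
    """A small simulated brain section plus its panel (shared, read-only)."""
    tissue, profiles = im.preset_tissue("demo", seed=3)
    return tissue, profiles


@pytest.fixture(scope="session")
def typed_demo(demo):
    """The demo section run through assignment, typing, and calling."""
    tissue, profiles = demo
    assignment, counts = im.assign_spots_to_cells(
        tissue.spots, tissue.cells, 15.0, gene_ids=profiles.gene_ids)
    posterior = im.compute_type_posteriors(counts, profiles)
    typing = im.TypingResult(counts, posterior, assignment)
    called = im.call_cells(typing, tissue.cells, profiles.pan_marker)
    return {"tissue": tissue, "profiles": profiles, "typing": typing,
            "called": called}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
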