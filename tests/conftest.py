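import warnings

import pytest

from condensekit import synthetic as syn


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # empty-mask warnings are part of tested behaviour; keep other tests quiet
    with warnings.catch_warnings():
        warnings.simplefilter("default")
        yield


@pytest.fixture(scope="session")
def condensate_scene_e3():
    """Poisson-noise condensate field with enrichment E = 3 (shared)."""
    spec = syn.CondensateSceneSpec(
        enrichment=3.0, noise_model="poisson", background_level=100.0, seed=3
    )
    return syn.make_condensate_image(spec)


@pytest.fixture(scope="session")
def brightfield_pair():
    """Matched droplet (20 in focus) and droplet-free field sets sharing the
    same speckle pattern."""
    droplet_spec = syn.BrightfieldSceneSpec(n_fields=5, n_droplets_in_focus=20, seed=1)
    empty_spec = syn.BrightfieldSceneSpec(n_fields=5, n_droplets_in_focus=0, seed=1)
    return syn.make_brightfield_set(droplet_spec), syn.make_brightfield_set(empty_spec)
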