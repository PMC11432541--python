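import pytest

from sbsfold import (
    BinderEnsemble,
    PolymerSpec,
    ProfileParams,
    SimulationParams,
    init_saw,
    make_binding_profile,
    place_binders,
)


@pytest.fixture(scope="session")
def tiny_system():
    """A small heterogeneous bead+binder system used by energy/force tests."""
    spec = make_binding_profile(
        ProfileParams(
            n_beads=30, n_types=3, n_domains=3, domain_length_mean=12.0,
            overlap_prob=0.4, inert_frac=0.1, seed=5,
        )
    )
    params = SimulationParams(box_edge=8.0, seed=3)
    binders = BinderEnsemble.uniform(spec.type_catalog, 0.08, 4.0)
    conf = place_binders(init_saw(spec, params, 1), binders, spec, params, 2)
    return spec, binders, params, conf


@pytest.fixture(scope="session")
def homopolymer_small():
    spec = PolymerSpec.homopolymer(40)
    params = SimulationParams(box_edge=12.0, seed=9)
    return spec, params
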