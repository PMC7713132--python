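import numpy as np
import pytest

from mirsort import homology, simulate


@pytest.fixture(scope="session")
def annotation_scenario():
    """100 hairpins: 70 bona fide + 10 starless + 20 single-criterion
    failures, with full IP/IgG libraries (seeded)."""
    return simulate.simulate_annotation_scenario(seed=11)


@pytest.fixture(scope="session")
def origin_bundle():
    """Origin scenario: 10 planted homology transcripts among 90 decoys,
    with predicted sites and extended guides."""
    hairpins, transcripts, truth = simulate.simulate_origin_scenario(seed=7)
    guides = {h.id: h.guide_seq for h in hairpins}
    sites = homology.predict_targets(guides, transcripts)
    ext = {h.id: homology.extended_guide(h) for h in hairpins}
    return hairpins, transcripts, truth, sites, ext


@pytest.fixture(scope="session")
def preference_bundle():
    """IP simulation at default depth for occupancy recovery."""
    design = simulate.SimulationDesign()
    rng = np.random.default_rng(11)
    hairpins, truth = simulate.generate_hairpins(design, rng)
    libraries, stacks = simulate.simulate_ip_libraries(design, hairpins, truth, rng)
    return design, hairpins, truth, libraries, stacks


def small_design(**overrides):
    """A fast design for property tests."""
    defaults = dict(
        n_hairpins=10,
        stages=("planula",),
        ip_depth=200_000,
        expression_rpm_range=(300.0, 3000.0),
    )
    defaults.update(overrides)
    return simulate.SimulationDesign(**defaults)
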