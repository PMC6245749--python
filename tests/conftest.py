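import pytest

import aerotree as at

AGES = (5.0, 10.0, 25.0)


@pytest.fixture(scope="session")
def adult_tree():
    return at.build_adult_tree()


@pytest.fixture(scope="session")
def trees():
    return {age: at.build_tree(age) for age in AGES}


@pytest.fixture(scope="session")
def dpi_profiles():
    return {age: at.dpi_profile(at.maneuver_defaults(age, at.Device.DPI))
            for age in AGES}


@pytest.fixture(scope="session")
def neb_profiles():
    return {age: at.nebulizer_profile(
        at.maneuver_defaults(age, at.Device.NEBULIZER)) for age in AGES}


@pytest.fixture(scope="session")
def contexts(trees):
    """StokesContext per (age, device) from the default trees/maneuvers."""
    out = {}
    for age in AGES:
        for device in (at.Device.DPI, at.Device.NEBULIZER):
            params = at.maneuver_defaults(age, device)
            out[(age, device)] = at.make_context(trees[age], params)
    return out
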