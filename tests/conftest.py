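import pytest

from yalicraft import (
    FixtureSpec,
    assemble_lvl1,
    assemble_lvl2,
    build_fixture_toolkit,
)


@pytest.fixture(scope="session")
def toolkit():
    """The default synthetic toolkit (built once per session)."""
    return build_fixture_toolkit(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def cfg(toolkit):
    return toolkit.config


@pytest.fixture(scope="session")
def lvl1_hrgfp(toolkit, cfg):
    """A single-TU integrative vector: TEF1 promoter driving hrGFP."""
    return assemble_lvl1(toolkit["pA1US1.1"], toolkit.entry("TEF1"),
                         toolkit.entry("hrGFP"), toolkit.entry("Tsyn1"), cfg)


@pytest.fixture(scope="session")
def lvl2_zeta(toolkit, cfg):
    """A three-TU Zeta vector analogous to pZUA2.3-HPD1-ARO4-ARO7."""
    donors = [
        assemble_lvl1(toolkit["pZUA1.1"], toolkit.entry("TEF1"),
                      toolkit.entry("HPD1"), toolkit.entry("Tsyn1"), cfg),
        assemble_lvl1(toolkit["pZUA1.2"], toolkit.entry("ALK1"),
                      toolkit.entry("ARO4"), toolkit.entry("Tsyn2"), cfg),
        assemble_lvl1(toolkit["pZUA1.3"], toolkit.entry("RPL25"),
                      toolkit.entry("ARO7"), toolkit.entry("Tsyn1"), cfg),
    ]
    return assemble_lvl2(toolkit["pZUA2.3"], donors, cfg)
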