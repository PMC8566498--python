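import pytest

from oxpclib.library import (
    ModCatalogueEntry,
    build_entry,
    default_catalogue,
    expand_catalogue,
    parse_acyl,
    parse_shorthand,
)


def entry_from_name(name: str):
    """Build a standalone library entry from a shorthand name."""
    sn1, sn2, link = parse_shorthand(name)
    return build_entry(sn1, ModCatalogueEntry(sn2=sn2, sn_known=(link == "/")))


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def pc160_library(catalogue):
    """The bundled catalogue expanded over palmitoyl sn-1 only."""
    return expand_catalogue(catalogue, [parse_acyl("16:0")])


@pytest.fixture(scope="session")
def full_library(catalogue):
    return expand_catalogue(catalogue, [parse_acyl(c) for c in ("16:0", "18:0", "18:1")])
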