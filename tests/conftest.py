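"""Shared fixtures: small synthetic systems built once per session."""

import numpy as np
import pytest

from oligotop import (WT_SPEC, build_barrel, build_bilayer, build_chain,
                      build_coil_system, build_hairpin, make_ensemble)
from oligotop.structgen import BETA_PHI_PSI


@pytest.fixture(scope="session")
def extended_chain():
    return build_chain(WT_SPEC, [BETA_PHI_PSI] * 7)


@pytest.fixture(scope="session")
def helix_chain():
    from oligotop import ChainSpec

    return build_chain(ChainSpec("A" * 12), [(-57.0, -47.0)] * 12)


@pytest.fixture(scope="session")
def ap_pair():
    """Two-stranded antiparallel in-register sheet."""
    return build_bilayer(WT_SPEC, m=2, n=0, orientation="antiparallel")


@pytest.fixture(scope="session")
def barrel6():
    return build_barrel(WT_SPEC, n_strands=6)


@pytest.fixture(scope="session")
def bilayer42():
    return build_bilayer(WT_SPEC, m=4, n=2)


@pytest.fixture(scope="session")
def bilayer33():
    return build_bilayer(WT_SPEC, m=3, n=3)


@pytest.fixture(scope="session")
def monolayer6():
    return build_bilayer(WT_SPEC, m=6, n=0)


@pytest.fixture(scope="session")
def coil_hexamer():
    return build_coil_system(WT_SPEC, 6, seed=11)


@pytest.fixture(scope="session")
def hairpin():
    return build_hairpin(WT_SPEC, 4)


@pytest.fixture(scope="session")
def mixed_ensemble():
    """Small barrel + 4+2 + 3+3 mixture with mild thermal noise."""
    return make_ensemble([
        ("barrel", {"spec": WT_SPEC, "n_strands": 6}, 5, 0.02, 1),
        ("bilayer", {"spec": WT_SPEC, "m": 4, "n": 2}, 5, 0.02, 2),
        ("bilayer", {"spec": WT_SPEC, "m": 3, "n": 3}, 5, 0.02, 3),
    ], temperature=310.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
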