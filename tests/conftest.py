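"""Shared fixtures: small simulated libraries and reference sets."""

from __future__ import annotations

import numpy as np
import pytest

from m1aseq.io_formats import ReferenceSet
from m1aseq.simulate import (
    LibraryLayout,
    ModificationProfile,
    SiteSignature,
    fixed_spikein_reference,
    standard_conditions,
)

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def spikein():
    return fixed_spikein_reference()


@pytest.fixture(scope="session")
def spikein_refs(spikein):
    return ReferenceSet([(spikein.name, spikein.seq)])


@pytest.fixture(scope="session")
def psii_profile(spikein):
    """The treated-library emission spectrum observed on the fixed spike-in."""
    return ModificationProfile(
        (SiteSignature(spikein.name, spikein.site, {"T": 0.577, "G": 0.068}, 0.0),)
    )


@pytest.fixture(scope="session")
def conditions():
    return standard_conditions(error_rate=0.001)


@pytest.fixture(scope="session")
def clean_conditions():
    """Error-free variants for exact truth-table comparisons."""
    return standard_conditions(error_rate=0.0)


@pytest.fixture()
def layout():
    return LibraryLayout()
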