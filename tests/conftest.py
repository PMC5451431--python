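"""Shared fixtures: tiny deterministic genomes, markers and read sets."""

import numpy as np
import pytest

from kmergt import simgen, variantdb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_reference():
    """A 60 kb three-chromosome random reference (autosome, chrX, chrY)."""
    return simgen.generate_reference(
        {"chr1": 40_000, "chrX": 12_000, "chrY": 8_000}, seed=11)


@pytest.fixture(scope="session")
def toy_variants(toy_reference):
    return simgen.place_markers(toy_reference, 300, seed=12, k=25)


@pytest.fixture(scope="session")
def toy_markers(toy_reference, toy_variants):
    markers, _ = variantdb.build_marker_db(
        toy_reference, toy_variants, [], variantdb.DBConfig(k=25))
    return markers


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
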