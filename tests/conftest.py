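"""Shared fixtures: the default synthetic corpus and its design matrix."""

from __future__ import annotations

import numpy as np
import pytest

from usvkit import build_design_matrix, generate_corpus


@pytest.fixture(scope="session")
def full_corpus():
    """Default study corpus: 25 calls per class, seed 42, SNR 20 dB."""
    return generate_corpus(25, 42, snr_db=20.0)


@pytest.fixture(scope="session")
def full_dm(full_corpus):
    return build_design_matrix(full_corpus)


@pytest.fixture(scope="session")
def small_corpus():
    """A light corpus (3 calls per class) for fast pipeline tests."""
    return generate_corpus(3, 7, snr_db=20.0)


@pytest.fixture(scope="session")
def small_dm(small_corpus):
    return build_design_matrix(small_corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
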