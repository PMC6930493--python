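"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from hepseq.nomenclature import GAGSequence, Residue, ResidueClass, parse_sequence

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Random valid residues / sequences
# ---------------------------------------------------------------------------


@st.composite
def uronic_residues(draw, allow_delta: bool = False):
    if allow_delta and draw(st.booleans()):
        return Residue(ResidueClass.DELTA_URONIC, epimer="unknown", sulfo_2O=draw(st.booleans()))
    return Residue(
        ResidueClass.URONIC,
        epimer=draw(st.sampled_from(["I", "G", "unknown"])),
        sulfo_2O=draw(st.booleans()),
    )


@st.composite
def amine_residues(draw, allow_amol: bool = False):
    if allow_amol and draw(st.booleans()):
        return Residue(ResidueClass.ANHYDROMANNITOL, sulfo_6O=draw(st.booleans()))
    return Residue(
        ResidueClass.HEXOSAMINE,
        n_substituent=draw(st.sampled_from(["NS", "NAc", "NH2"])),
        sulfo_3O=draw(st.booleans()),
        sulfo_6O=draw(st.booleans()),
    )


@st.composite
def gag_sequences(draw, min_len: int = 1, max_len: int = 8):
    """Random valid chains: alternating classes, ΔU only first, aM.ol only last."""
    n = draw(st.integers(min_len, max_len))
    starts_uronic = draw(st.booleans())
    residues = []
    for i in range(n):
        uronic_slot = (i % 2 == 0) == starts_uronic
        if uronic_slot:
            residues.append(draw(uronic_residues(allow_delta=(i == 0))))
        else:
            residues.append(draw(amine_residues(allow_amol=(i == n - 1))))
    return GAGSequence(tuple(residues))


def random_sequence(rng: random.Random, min_len: int = 2, max_len: int = 8) -> GAGSequence:
    """Plain-random valid chain (for seeded bulk property checks)."""
    n = rng.randint(min_len, max_len)
    starts_uronic = rng.random() < 0.5
    residues = []
    for i in range(n):
        uronic_slot = (i % 2 == 0) == starts_uronic
        if uronic_slot:
            if i == 0 and rng.random() < 0.3:
                residues.append(
                    Residue(ResidueClass.DELTA_URONIC, epimer="unknown", sulfo_2O=rng.random() < 0.5)
                )
            else:
                residues.append(
                    Residue(
                        ResidueClass.URONIC,
                        epimer=rng.choice(["I", "G", "unknown"]),
                        sulfo_2O=rng.random() < 0.5,
                    )
                )
        else:
            if i == n - 1 and rng.random() < 0.3:
                residues.append(Residue(ResidueClass.ANHYDROMANNITOL, sulfo_6O=rng.random() < 0.5))
            else:
                residues.append(
                    Residue(
                        ResidueClass.HEXOSAMINE,
                        n_substituent=rng.choice(["NS", "NS", "NAc"]),
                        sulfo_3O=rng.random() < 0.3,
                        sulfo_6O=rng.random() < 0.6,
                    )
                )
    return GAGSequence(tuple(residues))


# ---------------------------------------------------------------------------
# Reference species
# ---------------------------------------------------------------------------


@pytest.fixture
def octamer_g():
    return parse_sequence("G–ANS3S6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S")


@pytest.fixture
def octamer_i2s():
    return parse_sequence("I2S–ANS6S–I2S–ANS6S–I2S–ANS6S–I2S–aM.ol6S")


@pytest.fixture
def octamer_minor_1():
    return parse_sequence("I2S–ANS6S–G–ANS3S6S–I2S–ANS6S–I2S–aM.ol6S")


@pytest.fixture
def octamer_minor_2():
    return parse_sequence("I2S–ANS6S–I2S–ANS6S–G–ANS3S6S–I2S–aM.ol6S")
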