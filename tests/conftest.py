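"""Shared fixtures: small reaction networks, sensors and oracle helpers."""

import numpy as np
import pytest

import crnobserver as co


@pytest.fixture(scope="session")
def birth_death():
    """Birth-death X with k=10, gamma=1, cap 30 (three-band sensor regime)."""
    net = co.builtin("birth_death")
    space = net.state_space()
    A = co.build_generator(net, space)
    return net, space, A


@pytest.fixture(scope="session")
def three_band():
    return co.three_band_partition("X")


@pytest.fixture(scope="session")
def two_state():
    """A two-state switch (X in {0,1}) with rates 1.2 up / 0.8 down."""
    net = co.ReactionNetwork(
        name="switch",
        species=[co.Species("X", cap=1)],
        reactions=[
            co.Reaction(name="on", changes={"X": +1}, rate=1.2),
            co.Reaction(name="off", changes={"X": -1}, rate=0.8),
        ],
        initial_condition=co.InitialCondition(kind="point", state={"X": 0}),
    )
    space = net.state_space()
    A = co.build_generator(net, space)
    return net, space, A


@pytest.fixture(scope="session")
def tvo_trio():
    nets = [co.builtin(n) for n in ("tvo_m1", "tvo_m2", "tvo_m3")]
    return nets


def tv(p, q):
    """Total-variation distance between two (normalizable) vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return 0.5 * np.abs(p / p.sum() - q / q.sum()).sum()


@pytest.fixture(scope="session")
def tv_dist():
    return tv
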