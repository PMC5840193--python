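"""Shared fixtures: synthetic structures are built once per session."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from abflex.synth import ToyLoopSpec, make_toy_loop


@pytest.fixture(scope="session")
def loop_plain():
    """Length-10 loop with no hydrogen bonds (flat dilution profile)."""
    return make_toy_loop(ToyLoopSpec(loop_length=10, seed=11))


@pytest.fixture(scope="session")
def loop_bonded():
    """Length-10 loop with one engineered -4.0 kcal/mol backbone bond."""
    return make_toy_loop(ToyLoopSpec(loop_length=10, hbond_plan=((5, 1, -4.0),), seed=5))


@pytest.fixture(scope="session")
def loop_two_energy():
    """Length-12 loop with bonds at two distinct energies (-2.0, -5.5)."""
    return make_toy_loop(
        ToyLoopSpec(loop_length=12, hbond_plan=((5, 1, -2.0), (12, 8, -5.5)), seed=3)
    )


@pytest.fixture(scope="session")
def sweep_loops(loop_plain, loop_bonded, loop_two_energy):
    """Five loops of varied length and bond content for sweep validation."""
    extra1 = make_toy_loop(ToyLoopSpec(loop_length=8, hbond_plan=((6, 2, -3.2),), seed=21))
    extra2 = make_toy_loop(ToyLoopSpec(loop_length=12, hbond_plan=((5, 1, -6.5),), seed=22))
    return [loop_plain, loop_bonded, loop_two_energy, extra1, extra2]
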