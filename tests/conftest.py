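"""Shared fixtures: small landscapes, short pull protocols, toy trajectories."""

import numpy as np
import pytest

from smd_unbind import AtomSpec, PullProtocol, PullTrace, make_landscape


@pytest.fixture(scope="session")
def bound_well():
    """Gaussian bound well, depth 20 kJ/mol, width 0.3 nm (exact ΔG = 20)."""
    return make_landscape("bound_well_flat", {"depth": 20.0, "width": 0.3})


@pytest.fixture(scope="session")
def short_protocol():
    """Study-style protocol shrunk to 1 ns so unit tests stay fast."""
    return PullProtocol(duration=1.0, n_replicates=4, base_seed=11)


@pytest.fixture
def grid_atoms():
    """16 carbon atoms on a 3-D grid: a non-degenerate frame for superposition."""
    atoms = []
    k = 0
    for i in range(4):
        for j in range(4):
            atoms.append(AtomSpec(name=f"C{k}", element="C", resname="TOY",
                                  resid=k + 1, chain="A",
                                  position=(0.3 * i, 0.3 * j, 0.1 * ((i + j) % 3))))
            k += 1
    return atoms


def make_trace(anchor, force, spring_constant=1000.0, velocity=0.5):
    """Hand-built trace with consistent position = anchor - force/k."""
    anchor = np.asarray(anchor, dtype=float)
    force = np.asarray(force, dtype=float)
    k = spring_constant if spring_constant > 0 else 1.0
    return PullTrace(
        time=np.arange(anchor.size, dtype=float),
        anchor=anchor,
        position=anchor - force / k,
        force=force,
        spring_constant=spring_constant,
        velocity=velocity,
    )


@pytest.fixture
def trace_factory():
    return make_trace
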