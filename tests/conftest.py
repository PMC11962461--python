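"""Shared fixtures: small analytic networks and synthetic PSII mimics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import eetnet as e
from eetnet.units import thermal_energy_cm1

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: k_B T at 300 K in cm^-1
KBT300 = thermal_energy_cm1(300.0)


def two_state_network(gap_cm1: float = None) -> e.KineticNetwork:
    """Closed two-state system with E = (0, gap); downhill rate 1 ps^-1,
    uphill rate fixed by detailed balance.  Default gap = k_B T at 300 K,
    so the uphill rate is exactly exp(-1) ps^-1."""
    gap = KBT300 if gap_cm1 is None else gap_cm1
    states = pd.DataFrame(dict(
        state_id=["a", "b"], subunit=["X", "X"], monomer=[1, 1],
        pigment=["a", "b"], energy_cm1=[0.0, gap], is_chl_a=[True, True],
    ))
    k_up = np.exp(-gap / KBT300)
    rates = np.array([[0.0, 1.0], [k_up, 0.0]])
    return e.KineticNetwork(states, rates, temperature=300.0)


def random_trapped_system(seed: int, n_min: int = 8, n_max: int = 30,
                          with_losses: bool = False):
    """Random connected detailed-balanced network with 1-2 irreversible
    traps; independent test-bed for absorption statistics."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    E = rng.normal(15000.0, 120.0, size=n)
    C = np.zeros((n, n))
    idx = np.arange(n - 1)
    C[idx, idx + 1] = C[idx + 1, idx] = rng.uniform(0.2, 2.0, n - 1)  # connected chain
    extra = rng.random((n, n)) < 0.25
    w = rng.uniform(0.05, 1.0, (n, n))
    up = np.triu(extra & (w > 0), 1)
    C[up] = w[up]
    C = np.maximum(C, C.T)
    beta = 1.0 / KBT300
    K = C * np.exp(-0.5 * beta * (E[:, None] - E[None, :]))
    np.fill_diagonal(K, 0.0)
    states = pd.DataFrame(dict(
        state_id=[f"s{i}" for i in range(n)], subunit="X",
        monomer=1, pigment=[f"s{i}" for i in range(n)],
        energy_cm1=E, is_chl_a=True,
    ))
    net = e.KineticNetwork(states, K, temperature=300.0)
    n_traps = int(rng.integers(1, 3))
    donor_ids = rng.choice(n, size=n_traps, replace=False)
    donors = {m + 1: (f"s{donor_ids[m]}",) for m in range(n_traps)}
    traps = e.TrapSpec(donor_state_ids=donors,
                       trap_rate=float(rng.uniform(0.5, 2.0)))
    losses = e.LossSpec(mean_fluorescence_rate=1e-3, nonradiative_rate=2e-3) \
        if with_losses else None
    sc = e.Scenario(network=net, traps=traps, losses=losses)
    return e.build_generator(sc), net


@pytest.fixture(scope="session")
def mimic() -> e.KineticNetwork:
    """Default-size symmetric dimer mimic (142 states)."""
    return e.generate_mimic(e.MimicSpec(seed=7))


@pytest.fixture(scope="session")
def small_spec() -> e.MimicSpec:
    """Reduced mimic layout (~34 states) for tests that rebuild many networks."""
    layout = (
        e.SubunitSpec("RC", 3, 14950.0, "RC"),
        e.SubunitSpec("CP43", 4, 15000.0, "D1"),
        e.SubunitSpec("S-LHCII-B", 5, 15040.0, "D1", n_chl_b=2),
        e.SubunitSpec("CP47", 5, 15000.0, "D2"),
    )
    edges = (("RC", "CP43"), ("CP43", "S-LHCII-B"), ("RC", "CP47"))
    cross = (("CP47", "CP47"),)
    return e.MimicSpec(subunit_layout=layout, intra_edges=edges,
                       cross_edges=cross, seed=11)


@pytest.fixture(scope="session")
def small_mimic(small_spec) -> e.KineticNetwork:
    return e.generate_mimic(small_spec)
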