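"""Synthetic PSII-mimetic kinetic networks.

The generator builds dimeric, modular networks with the statistical
structure of the PSII supercomplex rate model: subunit clusters with
fast intra-cluster and slower inter-cluster transfer, near-degenerate
lowest subunit energies (a flat / shallow-funnel landscape), Gaussian
static disorder on the site energies, a charge-transfer (CT) state as
the lowest-energy reaction-center state of each monomer, and exact
detailed balance at the bath temperature.

Rates are constructed by a symmetric Boltzmann-factor split,

    k_ij = c_ij * exp(-(E_i - E_j) / (2 k_B T)),   c_ij = c_ji > 0,

which satisfies detailed balance identically for any symmetric coupling
matrix ``c`` — the generator claims the thermodynamic structure of the
real rate model, not its microscopic (Redfield/Forster) rate theory.
Nothing here is fit to the real PSII Hamiltonian and no absolute
timescale agreement with the real supercomplex is implied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph

from .network import DisorderEnsemble, KineticNetwork
from .units import DEFAULT_TEMPERATURE_K, thermal_energy_cm1


@dataclass(frozen=True)
class SubunitSpec:
    """One antenna/core subunit of a monomer."""

    name: str
    n_states: int
    mean_energy_cm1: float
    side: str  # "D1", "D2" or "RC"
    n_chl_b: int = 0  # states modelled as Chl b (blue-shifted sites)


# Default per-monomer layout: dimeric PSII-like supercomplex mimic with
# 8 subunits per monomer (~142 states total), a D1-side chain
# RC-CP43-CP26-S-LHCII and a D2-side chain RC-CP47-CP29-CP24-M-LHCII.
# Antenna lowest levels are nearly degenerate (flat landscape); Chl b
# sites sit ~400 cm^-1 above the Chl a pool; the RC carries the CT state
# as its energy minimum.
DEFAULT_LAYOUT: tuple[SubunitSpec, ...] = (
    SubunitSpec("RC", 6, 14950.0, "RC"),
    SubunitSpec("CP43", 9, 15000.0, "D1"),
    SubunitSpec("CP26", 7, 15020.0, "D1", n_chl_b=2),
    SubunitSpec("S-LHCII-B", 13, 15040.0, "D1", n_chl_b=5),
    SubunitSpec("CP47", 10, 15000.0, "D2"),
    SubunitSpec("CP29", 7, 15020.0, "D2", n_chl_b=2),
    SubunitSpec("CP24", 6, 15030.0, "D2", n_chl_b=2),
    SubunitSpec("M-LHCII-B", 13, 15040.0, "D2", n_chl_b=5),
)

DEFAULT_INTRA_EDGES: tuple[tuple[str, str], ...] = (
    ("RC", "CP43"),
    ("CP43", "CP26"),
    ("CP26", "S-LHCII-B"),
    ("RC", "CP47"),
    ("CP47", "CP29"),
    ("CP29", "CP24"),
    ("CP24", "M-LHCII-B"),
)

# Cross-monomer adjacencies as (a, b, coupling factor relative to
# inter_rate_scale).  The peripheral M trimer is the main bridge between
# the monomers; the two cores also touch, but only weakly (CP47 of one
# monomer faces CP43 of the other), which keeps the dimer connected when
# the M trimers are removed without washing out monomer identity.  Each
# pair (a, b) connects a@monomer1-b@monomer2 and b@monomer1-a@monomer2
# so the dimer stays mirror symmetric.
DEFAULT_CROSS_EDGES: tuple[tuple[str, str, float], ...] = (
    ("M-LHCII-B", "M-LHCII-B", 1.0),
    ("CP47", "CP43", 0.02),
)

_SUBUNIT_CENTERS = {
    "RC": (8.0, 10.0),
    "CP43": (-10.0, 12.0),
    "CP26": (-28.0, 14.0),
    "S-LHCII-B": (-48.0, 18.0),
    "CP47": (26.0, 8.0),
    "CP29": (44.0, 12.0),
    "CP24": (60.0, 16.0),
    "M-LHCII-B": (78.0, 6.0),
}

#: Energy offset of the CT state below the rest of the RC manifold, cm^-1.
CT_ENERGY_OFFSET_CM1 = 150.0
#: Blue shift of Chl b sites relative to the subunit Chl a mean, cm^-1.
CHL_B_SHIFT_CM1 = 400.0


@dataclass(frozen=True)
class MimicSpec:
    """Specification of a synthetic PSII-like network.

    ``subunit_layout`` describes one monomer; the dimer is built by
    duplication.  ``disorder_sigma`` is the SD of the Gaussian static
    disorder added to each site energy (cm^-1); with
    ``dimer_symmetric=True`` monomer 2 is an exact energetic and kinetic
    mirror image of monomer 1.
    """

    subunit_layout: tuple[SubunitSpec, ...] = DEFAULT_LAYOUT
    intra_rate_scale: float = 2.0    # ps^-1, within-subunit couplings
    inter_rate_scale: float = 0.1    # ps^-1, between adjacent subunits
    intra_edges: tuple[tuple[str, str], ...] = DEFAULT_INTRA_EDGES
    # (a, b) or (a, b, coupling factor) pairs linking monomer 1 to monomer 2
    cross_edges: tuple[tuple, ...] = DEFAULT_CROSS_EDGES
    disorder_sigma: float = 80.0     # cm^-1
    temperature: float = DEFAULT_TEMPERATURE_K
    dimer_symmetric: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intra_rate_scale <= 0 or self.inter_rate_scale <= 0:
            raise ValueError("rate scales must be positive")
        if self.disorder_sigma < 0:
            raise ValueError("disorder_sigma must be >= 0")
        rc = [s for s in self.subunit_layout if s.side == "RC"]
        if len(rc) != 1:
            raise ValueError("layout must contain exactly one RC subunit per monomer")


def _monomer_tables(spec: MimicSpec, rng_struct: np.random.Generator) -> pd.DataFrame:
    """Static (disorder-free) state table for monomer 1."""
    rows = []
    for su in spec.subunit_layout:
        cx, cy = _SUBUNIT_CENTERS.get(su.name, (0.0, 0.0))
        jitter = rng_struct.uniform(-4, 4, size=(su.n_states, 3))
        dip = rng_struct.lognormal(mean=0.0, sigma=0.3, size=su.n_states)
        for i in range(su.n_states):
            is_ct = su.side == "RC" and i == su.n_states - 1
            is_b = (not is_ct) and i >= su.n_states - su.n_chl_b - (1 if su.side == "RC" else 0)
            if su.side == "RC":
                is_b = False
            if is_ct:
                pigment = "CT"
            elif is_b:
                pigment = f"Chl b {601 + i}"
            else:
                pigment = f"Chl a {601 + i}"
            rows.append(dict(
                state_id=f"{su.name}_m1_{i:02d}",
                subunit=su.name,
                monomer=1,
                pigment=pigment,
                energy_cm1=su.mean_energy_cm1,  # disorder added later
                x=cx + jitter[i, 0], y=cy + jitter[i, 1], z=jitter[i, 2],
                dipole_sq=dip[i] * (0.8 if is_b else 1.0),
                is_chl_a=not (is_b or is_ct),
            ))
    return pd.DataFrame(rows)


def _draw_energies(spec: MimicSpec, mono: pd.DataFrame,
                   rng_energy: np.random.Generator) -> np.ndarray:
    """Site energies for one monomer: subunit mean (+ Chl b shift)
    + Gaussian disorder; the CT state is pinned below the RC manifold."""
    base = mono["energy_cm1"].to_numpy(float).copy()
    is_b = np.array([p.startswith("Chl b") for p in mono["pigment"]])
    base[is_b] += CHL_B_SHIFT_CM1
    E = base + rng_energy.normal(0.0, spec.disorder_sigma, size=len(base))
    rc_mask = (mono["subunit"] == _rc_name(spec)).to_numpy()
    ct_mask = (mono["pigment"] == "CT").to_numpy()
    rc_chl = rc_mask & ~ct_mask
    if rc_chl.any():
        E[ct_mask] = E[rc_chl].min() - CT_ENERGY_OFFSET_CM1
    return E


def _rc_name(spec: MimicSpec) -> str:
    return next(s.name for s in spec.subunit_layout if s.side == "RC")


def _log_uniform(rng: np.random.Generator, scale: float, size) -> np.ndarray:
    """Couplings drawn log-uniform over [scale/3, 3*scale]."""
    return scale * np.exp(rng.uniform(-np.log(3.0), np.log(3.0), size=size))


def _coupling_matrix(spec: MimicSpec, mono: pd.DataFrame,
                     rng_struct: np.random.Generator) -> np.ndarray:
    """Symmetric coupling matrix for the full dimer (2n x 2n)."""
    n = len(mono)
    su = mono["subunit"].to_numpy()
    blocks = {name: np.flatnonzero(su == name) for name in {s.name for s in spec.subunit_layout}}

    c1 = np.zeros((n, n))
    for name, idx in sorted(blocks.items()):
        m = len(idx)
        w = _log_uniform(rng_struct, spec.intra_rate_scale, (m, m))
        w = np.triu(w, 1)
        c1[np.ix_(idx, idx)] = w + w.T
    for a, b in spec.intra_edges:
        ia, ib = blocks[a], blocks[b]
        w = _log_uniform(rng_struct, spec.inter_rate_scale, (len(ia), len(ib)))
        c1[np.ix_(ia, ib)] = w
        c1[np.ix_(ib, ia)] = w.T

    C = np.zeros((2 * n, 2 * n))
    C[:n, :n] = c1
    if spec.dimer_symmetric:
        C[n:, n:] = c1
    else:
        # redraw monomer-2 internals with the same statistics
        c2 = np.zeros((n, n))
        for name, idx in sorted(blocks.items()):
            m = len(idx)
            w = np.triu(_log_uniform(rng_struct, spec.intra_rate_scale, (m, m)), 1)
            c2[np.ix_(idx, idx)] = w + w.T
        for a, b in spec.intra_edges:
            ia, ib = blocks[a], blocks[b]
            w = _log_uniform(rng_struct, spec.inter_rate_scale, (len(ia), len(ib)))
            c2[np.ix_(ia, ib)] = w
            c2[np.ix_(ib, ia)] = w.T
        C[n:, n:] = c2

    for edge in spec.cross_edges:
        a, b = edge[0], edge[1]
        factor = edge[2] if len(edge) > 2 else 1.0
        ia, ib = blocks[a], blocks[b]
        w = _log_uniform(rng_struct, factor * spec.inter_rate_scale,
                         (len(ia), len(ib)))
        if a == b:
            w = 0.5 * (w + w.T)  # mirror swap transposes this block
        C[np.ix_(ia, ib + n)] = w
        C[np.ix_(ib + n, ia)] = w.T
        # mirror image: b@m1 - a@m2 with the same couplings
        C[np.ix_(ib, ia + n)] = w.T
        C[np.ix_(ia + n, ib)] = w
    return C


def _rates_from_couplings(C: np.ndarray, E: np.ndarray, temperature: float) -> np.ndarray:
    """Detailed-balanced rates via the symmetric Boltzmann-factor split."""
    beta = 1.0 / thermal_energy_cm1(temperature)
    dE = E[:, None] - E[None, :]          # E_i - E_j
    K = C * np.exp(-0.5 * beta * dE)
    np.fill_diagonal(K, 0.0)
    return K


def _check_connected(C: np.ndarray) -> None:
    n_comp, _ = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(C > 0), directed=False)
    if n_comp != 1:
        raise ValueError(
            f"generated coupling graph is disconnected ({n_comp} components); "
            "check intra_edges/cross_edges")


def _build(spec: MimicSpec, realization: int) -> KineticNetwork:
    rng_struct = np.random.default_rng((spec.seed, 12345))
    mono = _monomer_tables(spec, rng_struct)
    n = len(mono)

    rng_e1 = np.random.default_rng((spec.seed, 777, realization, 1))
    E1 = _draw_energies(spec, mono, rng_e1)
    if spec.dimer_symmetric:
        E2 = E1.copy()
    else:
        rng_e2 = np.random.default_rng((spec.seed, 777, realization, 2))
        E2 = _draw_energies(spec, mono, rng_e2)

    mono2 = mono.copy()
    mono2["state_id"] = [s.replace("_m1_", "_m2_") for s in mono["state_id"]]
    mono2["monomer"] = 2
    mono2[["x", "y"]] = -mono2[["x", "y"]]  # C2 point reflection
    states = pd.concat([mono, mono2], ignore_index=True)
    E = np.concatenate([E1, E2])
    states["energy_cm1"] = E

    C = _coupling_matrix(spec, mono, rng_struct)
    _check_connected(C)
    K = _rates_from_couplings(C, E, spec.temperature)
    return KineticNetwork(states, K, temperature=spec.temperature)


def generate_mimic(spec: MimicSpec = MimicSpec()) -> KineticNetwork:
    """Generate one synthetic PSII-mimic network (realization 0 of the
    disorder ensemble defined by ``spec``).  Deterministic in ``spec.seed``."""
    return _build(spec, realization=0)


def generate_disorder_ensemble(spec: MimicSpec, n: int) -> DisorderEnsemble:
    """``n`` networks sharing topology and couplings, differing only in
    the Gaussian site-energy draw (static disorder realizations)."""
    if n < 1:
        raise ValueError("need n >= 1 realizations")
    nets = tuple(_build(spec, realization=k) for k in range(n))
    return DisorderEnsemble(nets, seed=spec.seed)


def mirror_permutation(net: KineticNetwork) -> np.ndarray:
    """Index permutation swapping the two monomers of a dimer built by
    :func:`generate_mimic` (state *i* of monomer 1 <-> state *i* of
    monomer 2, same subunit and in-subunit index)."""
    ids = list(net.state_ids)
    perm = np.empty(len(ids), dtype=int)
    lookup = {s: k for k, s in enumerate(ids)}
    for k, s in enumerate(ids):
        if "_m1_" in s:
            other = s.replace("_m1_", "_m2_")
        elif "_m2_" in s:
            other = s.replace("_m2_", "_m1_")
        else:
            raise ValueError(f"state {s!r} has no monomer tag")
        perm[k] = lookup[other]
    return perm


def generate_control_landscape(
    kind: str,
    n_states: int,
    params: dict | None = None,
    seed: int = 0,
) -> KineticNetwork:
    """Control chain landscapes for contrasting funnel vs flat dynamics.

    ``kind="funnel"``: strictly decreasing energies toward the
    trap-adjacent final state; ``kind="flat"``: all energies equal.
    Both use the same couplings at a given seed (matched connectivity)
    and are exactly detailed balanced.
    """
    if n_states < 3:
        raise ValueError("need n_states >= 3")
    if kind not in ("funnel", "flat"):
        raise ValueError(f"kind must be 'funnel' or 'flat', got {kind!r}")
    params = dict(params or {})
    step = params.pop("step_cm1", 150.0)
    base = params.pop("base_energy_cm1", 15000.0)
    scale = params.pop("rate_scale", 1.0)
    temperature = params.pop("temperature", DEFAULT_TEMPERATURE_K)
    if params:
        raise ValueError(f"unknown params: {sorted(params)}")

    rng = np.random.default_rng((seed, 2024))
    C = np.zeros((n_states, n_states))
    for off in (1, 2):  # nearest and next-nearest neighbours along the chain
        w = _log_uniform(rng, scale if off == 1 else scale / 4, n_states - off)
        idx = np.arange(n_states - off)
        C[idx, idx + off] = w
        C[idx + off, idx] = w

    if kind == "funnel":
        E = base + step * np.arange(n_states)[::-1].astype(float)
    else:
        E = np.full(n_states, base)

    states = pd.DataFrame(dict(
        state_id=[f"s{i}" for i in range(n_states)],
        subunit="chain",
        monomer=1,
        pigment=[f"s{i}" for i in range(n_states)],
        energy_cm1=E,
        is_chl_a=True,
    ))
    K = _rates_from_couplings(C, E, temperature)
    return KineticNetwork(states, K, temperature=temperature)
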