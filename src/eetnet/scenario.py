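"""Experimental scenarios: from a closed network to an open-system generator.

A :class:`Scenario` bundles everything that turns the closed,
detailed-balanced EET network into the open system of a given
experimental condition:

* irreversible reaction-center traps (one per monomer, fed by the
  lowest-energy RC state — the charge-transfer state — by default, with
  a phenomenological rate);
* fluorescence loss, distributed over states proportionally to the
  squared transition dipole and rescaled so the state-average rate
  equals a target mean, plus a uniform nonradiative loss;
* RC closure (trap rate set to zero; the RC pigments keep transferring);
* antenna-complement edits (e.g. removing the M-LHCII trimers and CP24
  to go from a C2S2M2- to a C2S2-type supercomplex).

:func:`build_generator` returns an :class:`OpenSystem`: the transient
block of the generator over the kept excitonic states plus explicit
inflow rates into four absorbing sinks (trap 1, trap 2, fluorescence,
nonradiative), so total probability over kept states and sinks is
conserved under propagation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph
import yaml

from .network import KineticNetwork

logger = logging.getLogger("eetnet")

SINK_LABELS = ("trap_1", "trap_2", "fluorescence", "nonradiative")

#: Default phenomenological trap (charge-separation) rate, ps^-1.
DEFAULT_TRAP_RATE_PS = 1.0
#: Default mean fluorescence lifetime, ns (mean rate = 1/16 ns^-1 = 6.25e-5 ps^-1).
DEFAULT_FL_LIFETIME_NS = 16.0
#: Default nonradiative lifetime, ns (rate = 1/2 ns^-1 = 5e-4 ps^-1).
DEFAULT_NR_LIFETIME_NS = 2.0


@dataclass(frozen=True)
class TrapSpec:
    """Irreversible RC traps, one per monomer.

    ``donor_state_ids`` maps monomer -> state ids feeding that trap;
    ``None`` selects the lowest-energy RC-subunit state of each monomer
    (the charge-transfer state).  ``open_monomers`` flags whether each
    monomer's trap is active; a closed RC keeps its states in the
    network but drains nothing.
    """

    donor_state_ids: dict[int, tuple[str, ...]] | None = None
    trap_rate: float = DEFAULT_TRAP_RATE_PS
    open_monomers: dict[int, bool] = field(default_factory=lambda: {1: True, 2: True})
    trap_position: tuple[float, float, float] | None = None
    rc_subunit: str = "RC"

    def __post_init__(self) -> None:
        if self.trap_rate <= 0:
            raise ValueError("trap_rate must be positive")

    def resolve_donors(self, net: KineticNetwork) -> dict[int, tuple[str, ...]]:
        if self.donor_state_ids is not None:
            donors = {int(m): tuple(v) for m, v in self.donor_state_ids.items()}
        else:
            donors = {}
            df = net.states
            for m in sorted(df["monomer"].unique()):
                rc = df[(df["monomer"] == m) & (df["subunit"] == self.rc_subunit)]
                if rc.empty:
                    raise ValueError(f"no {self.rc_subunit!r} subunit states in monomer {m}")
                donors[int(m)] = (str(rc.loc[rc["energy_cm1"].idxmin(), "state_id"]),)
        for m, ids in donors.items():
            for s in ids:
                net.index_of(s)  # raises on unknown ids
        return donors


@dataclass(frozen=True)
class LossSpec:
    """Fluorescence + nonradiative loss channels.

    Per-state fluorescence rates are proportional to ``dipole_sq`` and
    rescaled so their state-average equals ``mean_fluorescence_rate``;
    states without dipole metadata fall back to the uniform mean.  The
    nonradiative rate applies uniformly.
    """

    mean_fluorescence_rate: float = 1.0 / (DEFAULT_FL_LIFETIME_NS * 1000.0)  # ps^-1
    nonradiative_rate: float = 1.0 / (DEFAULT_NR_LIFETIME_NS * 1000.0)       # ps^-1

    def __post_init__(self) -> None:
        if self.mean_fluorescence_rate < 0 or self.nonradiative_rate < 0:
            raise ValueError("loss rates must be >= 0")

    def per_state_fluorescence(self, net: KineticNetwork) -> np.ndarray:
        d = net.states["dipole_sq"].to_numpy(float)
        if not np.isfinite(d).all():
            if np.isfinite(d).any():
                warnings.warn("some states lack dipole_sq; using uniform fluorescence rates")
            w = np.ones(net.n_states)
        else:
            w = d
        if w.mean() == 0:
            w = np.ones(net.n_states)
        return self.mean_fluorescence_rate * w / w.mean()


@dataclass(frozen=True)
class Scenario:
    """A network plus the condition that opens it."""

    network: KineticNetwork
    traps: TrapSpec = TrapSpec()
    losses: LossSpec | None = None
    removed_subunits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        known = set(self.network.states["subunit"])
        unknown = [s for s in self.removed_subunits if s not in known]
        if unknown:
            raise ValueError(f"removed subunits not in network: {unknown}")


def close_rc(sc: Scenario, monomer: int) -> Scenario:
    """Deactivate one monomer's RC trap (states stay in the network)."""
    if monomer not in (1, 2):
        raise ValueError("monomer must be 1 or 2")
    flags = dict(sc.traps.open_monomers)
    flags[monomer] = False
    return replace(sc, traps=replace(sc.traps, open_monomers=flags))


def remove_subunits(sc: Scenario, names) -> Scenario:
    """Delete whole subunits (e.g. the M-LHCII trimers for C2S2)."""
    return replace(sc, removed_subunits=tuple(sc.removed_subunits) + tuple(names))


def reduced_network(sc: Scenario) -> KineticNetwork:
    """The closed network with the scenario's removed subunits deleted
    (rows/columns dropped, diagonal rebuilt).  Detailed balance of the
    remaining closed part is preserved by construction."""
    if not sc.removed_subunits:
        return sc.network
    keep = ~sc.network.states["subunit"].isin(sc.removed_subunits).to_numpy()
    idx = np.flatnonzero(keep)
    K = sc.network.rates[np.ix_(idx, idx)].copy()
    np.fill_diagonal(K, 0.0)
    states = sc.network.states.iloc[idx].reset_index(drop=True)
    return KineticNetwork(states, K, temperature=sc.network.temperature)


@dataclass(frozen=True)
class OpenSystem:
    """Open-system generator: transient block + explicit absorbing sinks.

    ``transient[i, j]`` is the generator restricted to kept states (its
    diagonal includes all sink outflows); ``sink_rates[s, j]`` is the
    rate from kept state *j* into sink *s*, ordered as
    :data:`SINK_LABELS`.  The extended generator over kept states plus
    sinks has exactly zero column sums, so propagation conserves total
    probability.
    """

    states: pd.DataFrame
    transient: np.ndarray
    sink_rates: np.ndarray
    temperature: float
    scenario: Scenario | None = None

    @property
    def n_states(self) -> int:
        return self.transient.shape[0]

    @property
    def state_ids(self) -> np.ndarray:
        return self.states["state_id"].to_numpy()

    @property
    def energies(self) -> np.ndarray:
        return self.states["energy_cm1"].to_numpy(float)

    @property
    def has_losses(self) -> bool:
        return bool(self.sink_rates[2:].sum() > 0)

    @property
    def open_traps(self) -> tuple[int, ...]:
        return tuple(m for m in (1, 2) if self.sink_rates[m - 1].sum() > 0)

    def extended_generator(self) -> np.ndarray:
        n = self.n_states
        G = np.zeros((n + 4, n + 4))
        G[:n, :n] = self.transient
        G[n:, :n] = self.sink_rates
        return G

    def index_of(self, state_id: str) -> int:
        hits = np.flatnonzero(self.state_ids == state_id)
        if len(hits) == 0:
            raise KeyError(f"unknown state_id {state_id!r}")
        return int(hits[0])

    def stranded_states(self) -> tuple[str, ...]:
        """Kept states from which no sink is reachable."""
        n = self.n_states
        feeds = np.flatnonzero(self.sink_rates.sum(axis=0) > 0)
        if len(feeds) == 0:
            return tuple(self.state_ids)
        off = self.transient.copy()
        np.fill_diagonal(off, 0.0)
        # edge j -> i where off[i, j] > 0; reachability *to* a feeding
        # state is reachability *from* it in the reversed graph.
        rev = scipy.sparse.csr_matrix((off > 0))  # rev[i, j]: edge j->i, i.e. reversed i->j
        reach = np.zeros(n, dtype=bool)
        reach[feeds] = True
        frontier = feeds
        while len(frontier):
            nxt = np.unique(rev[frontier].nonzero()[1])
            nxt = nxt[~reach[nxt]]
            reach[nxt] = True
            frontier = nxt
        return tuple(self.state_ids[~reach])


def build_generator(sc: Scenario, require_absorbing: bool = True) -> OpenSystem:
    """Assemble the open-system generator of a scenario.

    Raises if ``require_absorbing`` and the scenario has neither an open
    trap nor loss channels; warns if any kept state cannot reach a sink
    (e.g. after a subunit removal disconnects part of the antenna).
    """
    net = reduced_network(sc)
    n = net.n_states
    T = net.rates.copy()
    R = np.zeros((4, n))

    donors = sc.traps.resolve_donors(net)
    for m, ids in donors.items():
        if m not in (1, 2):
            raise ValueError("traps are defined for monomers 1 and 2")
        if not sc.traps.open_monomers.get(m, True):
            continue
        for s in ids:
            j = net.index_of(s)
            R[m - 1, j] += sc.traps.trap_rate

    if sc.losses is not None:
        R[2] = sc.losses.per_state_fluorescence(net)
        R[3] = sc.losses.nonradiative_rate

    if require_absorbing and R.sum() == 0:
        raise ValueError(
            "scenario has no absorbing channel: all traps closed and no losses"
        )

    T[np.diag_indices(n)] -= R.sum(axis=0)
    sys = OpenSystem(net.states, T, R, temperature=net.temperature, scenario=sc)
    if R.sum() > 0:
        stranded = sys.stranded_states()
        if stranded:
            warnings.warn(
                f"{len(stranded)} states cannot reach any sink "
                f"(e.g. {list(stranded[:4])}); absorption statistics will be singular"
            )
    return sys


# ----------------------------------------------------------------------------
# Scenario config files
# ----------------------------------------------------------------------------

def scenario_from_config(net: KineticNetwork, config: str | Path | dict) -> Scenario:
    """Build a Scenario from a YAML config (or an equivalent dict).

    Recognized keys: ``temperature_K``; ``trap: {rate_ps, open: [bool,
    bool], donors: {1: [...], 2: [...]}}``; ``losses:
    {mean_fl_lifetime_ns, nr_lifetime_ns}`` or ``losses: null``;
    ``remove_subunits: [...]``.
    """
    if isinstance(config, (str, Path)):
        cfg = yaml.safe_load(Path(config).read_text()) or {}
    else:
        cfg = dict(config)

    if "temperature_K" in cfg:
        net = replace(net, temperature=float(cfg["temperature_K"]))

    trap_cfg = cfg.get("trap", {}) or {}
    open_flags = trap_cfg.get("open", [True, True])
    donors = trap_cfg.get("donors")
    traps = TrapSpec(
        donor_state_ids={int(k): tuple(v) for k, v in donors.items()} if donors else None,
        trap_rate=float(trap_cfg.get("rate_ps", DEFAULT_TRAP_RATE_PS)),
        open_monomers={1: bool(open_flags[0]), 2: bool(open_flags[1])},
    )

    losses = None
    if cfg.get("losses") is not None:
        loss_cfg = cfg["losses"]
        losses = LossSpec(
            mean_fluorescence_rate=1.0 / (1000.0 * float(
                loss_cfg.get("mean_fl_lifetime_ns", DEFAULT_FL_LIFETIME_NS))),
            nonradiative_rate=1.0 / (1000.0 * float(
                loss_cfg.get("nr_lifetime_ns", DEFAULT_NR_LIFETIME_NS))),
        )

    return Scenario(
        network=net,
        traps=traps,
        losses=losses,
        removed_subunits=tuple(cfg.get("remove_subunits", []) or ()),
    )
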