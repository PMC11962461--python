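"""Master-equation propagation and absorption statistics.

The population vector evolves as ``P(t) = exp(G t) P(0)`` where ``G``
is either the closed network generator or the extended open-system
generator (kept states + four absorbing sinks).  Propagation uses the
action of the matrix exponential per time interval (scaling-and-squaring
on the interval generator), which is robust for the non-symmetric,
possibly defective generators that arise from detailed-balanced rate
matrices with traps; no eigendecomposition is assumed.

Absorption statistics (splitting probabilities, mean first passage
times, lifetimes) are computed by linear solves on the transient block:
with ``T`` the transient generator and ``R`` the sink-inflow rates,

    absorption probabilities   b = R (-T)^{-1} p(0)
    mean absorption time     tau = 1^T (-T)^{-1} p(0)

:func:`gillespie_simulate` provides an exact stochastic realization of
the same continuous-time chain as an independent cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.special

from .network import KineticNetwork, boltzmann_equilibrium
from .scenario import SINK_LABELS, OpenSystem
from .units import KB_CM1_PER_K

logger = logging.getLogger("eetnet")

#: Populations more negative than this are treated as round-off and clipped.
CLIP_TOL = 1e-12


def default_time_grid(n_points: int = 600, t_min: float = 1e-2,
                      t_max: float = 1e5) -> np.ndarray:
    """t = 0 plus ``n_points`` log-spaced times over [t_min, t_max] ps,
    spanning sub-ps equilibration through fluorescence decay."""
    return np.concatenate([[0.0], np.logspace(np.log10(t_min), np.log10(t_max), n_points)])


# ----------------------------------------------------------------------------
# Initial conditions
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class InitialCondition:
    """A probability vector over the network states."""

    weights: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or np.any(w < 0) or not np.isfinite(w).all():
            raise ValueError("initial condition must be a nonnegative finite vector")
        s = w.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"initial condition must sum to 1, got {s}")
        w = w / s
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)


def delta_initial_condition(sys_or_net, state_id: str) -> InitialCondition:
    """Delta distribution on one state."""
    n = sys_or_net.n_states
    w = np.zeros(n)
    w[sys_or_net.index_of(state_id)] = 1.0
    return InitialCondition(w, label=state_id)


def initial_condition_for_pigment(
    net,
    pigment_label: str,
    localization_map: pd.DataFrame | None = None,
    subunit: str | None = None,
    monomer: int | None = None,
) -> InitialCondition:
    """Delta on the exciton state most localized in the named pigment.

    Without a ``localization_map`` the network is taken to be in the
    site basis (or the state metadata's ``pigment`` column identifies
    the dominant site): the state whose pigment matches is selected,
    optionally filtered by ``subunit``/``monomer`` (e.g. "Chl a 610"
    appears in several LHCII subunits).  With a map (rows = states,
    columns = site labels, rows summing to 1) the state with maximal
    localization weight on the named site is selected.  Exact ties break
    to the lowest state index with a warning.
    """
    df = net.states
    if localization_map is not None:
        if pigment_label not in localization_map.columns:
            raise KeyError(f"site {pigment_label!r} not in localization map")
        col = localization_map[pigment_label].to_numpy(float)
        if len(col) != len(df):
            raise ValueError("localization map rows do not match network states")
        best = col.max()
        hits = np.flatnonzero(col == best)
    else:
        mask = (df["pigment"] == pigment_label).to_numpy()
        if subunit is not None:
            mask &= (df["subunit"] == subunit).to_numpy()
        if monomer is not None:
            mask &= (df["monomer"] == monomer).to_numpy()
        hits = np.flatnonzero(mask)
        if len(hits) == 0:
            raise KeyError(f"no state with pigment {pigment_label!r}")
    if len(hits) > 1:
        warnings.warn(
            f"{len(hits)} states tie for pigment {pigment_label!r}; "
            f"using lowest index {hits[0]}"
        )
    w = np.zeros(len(df))
    w[hits[0]] = 1.0
    return InitialCondition(w, label=pigment_label)


def uniform_chl_a_condition(net) -> InitialCondition:
    """Excitation spread uniformly over all Chl a states."""
    mask = net.states["is_chl_a"].to_numpy(bool)
    if not mask.any():
        raise ValueError("network has no Chl a states")
    return InitialCondition(mask / mask.sum(), label="uniform Chl a")


# ----------------------------------------------------------------------------
# Propagation
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationTrajectory:
    """P(t) on a time grid, kept states and sink masses separately."""

    times: np.ndarray               # (T,)
    populations: np.ndarray         # (T, N) kept excitonic states
    sink_mass: np.ndarray           # (T, 4) trap1, trap2, fluor, nonrad
    state_table: pd.DataFrame
    sink_labels: tuple[str, ...] = SINK_LABELS
    generator_ext: np.ndarray | None = None  # for continuous-time refinement

    @property
    def survival(self) -> np.ndarray:
        return self.populations.sum(axis=1)

    @property
    def total(self) -> np.ndarray:
        return self.survival + self.sink_mass.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ps": self.times}
        for k, sid in enumerate(self.state_table["state_id"]):
            cols[sid] = self.populations[:, k]
        for k, lab in enumerate(self.sink_labels):
            cols[lab] = self.sink_mass[:, k]
        return pd.DataFrame(cols)


def _extended(sys_or_net) -> tuple[np.ndarray, pd.DataFrame, float]:
    """(extended generator, state table, temperature) for OpenSystem or
    closed KineticNetwork inputs."""
    if isinstance(sys_or_net, OpenSystem):
        return sys_or_net.extended_generator(), sys_or_net.states, sys_or_net.temperature
    if isinstance(sys_or_net, KineticNetwork):
        n = sys_or_net.n_states
        G = np.zeros((n + 4, n + 4))
        G[:n, :n] = sys_or_net.rates
        return G, sys_or_net.states, sys_or_net.temperature
    raise TypeError(f"expected OpenSystem or KineticNetwork, got {type(sys_or_net)}")


def _reversible_spectral_factors(K: np.ndarray, energies: np.ndarray,
                                 temperature: float):
    """Symmetrized spectral factorization of a closed detailed-balanced
    generator (reversible CTMC), or None if K is not symmetrizable.

    With pi the Boltzmann distribution and D = diag(sqrt(pi)),
    S = D^-1 K D is symmetric iff K satisfies detailed balance; its
    (real, nonpositive) eigensystem then propagates without the
    round-off accumulation of sequential interval exponentials, which
    keeps the free-energy series monotone to ~1e-11 k_B T.
    """
    beta = 1.0 / (KB_CM1_PER_K * temperature)
    logw = -beta * energies
    pi = np.exp(logw - scipy.special.logsumexp(logw))
    dh = np.sqrt(pi)
    S = K * (dh[None, :] / dh[:, None])
    scale = np.abs(S).max()
    if scale == 0 or np.abs(S - S.T).max() > 1e-8 * scale:
        return None
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    return dh, np.minimum(w, 0.0), V


def _propagate_spectral(factors, P0: np.ndarray, times: np.ndarray) -> np.ndarray:
    # propagate the deviation from equilibrium: it carries no component
    # along the stationary mode analytically, so the equilibrium part is
    # exact and late times are free of amplified eigenvector round-off
    dh, w, V = factors
    pi = dh * dh
    mass0 = P0.sum(axis=0)
    Peq = pi[:, None] * mass0[None, :]
    Q0 = V.T @ ((P0 - Peq) / dh[:, None])
    out = np.empty((len(times),) + P0.shape)
    for k, t in enumerate(times):
        if t == 0.0:
            out[k] = P0
        else:
            out[k] = Peq + dh[:, None] * (V @ (np.exp(w * t)[:, None] * Q0))
    return out


def _propagate_columns(G: np.ndarray, P0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """exp(G t) applied to the columns of P0 at each time; returns
    (T, n, m).  Each interval uses a dense matrix exponential of the
    interval generator (backward-stable scaling and squaring)."""
    if not np.isfinite(G).all():
        raise ValueError("generator contains non-finite entries")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be ascending")
    out = np.empty((len(times),) + P0.shape)
    P = P0.copy()
    t_prev = 0.0
    for k, t in enumerate(times):
        dt = t - t_prev
        if dt > 0:
            P = scipy.linalg.expm(G * dt) @ P
        out[k] = P
        t_prev = t
    return out


def propagate(sys_or_net, ic: InitialCondition, times: np.ndarray | None = None) -> PopulationTrajectory:
    """Propagate the master equation, ``P(t) = exp(G t) P(0)``.

    Accepts an :class:`OpenSystem` (kept states + sinks) or a closed
    :class:`KineticNetwork`.  The t=0 row reproduces the initial
    condition exactly; small negative round-off populations are clipped
    to zero.
    """
    if times is None:
        times = default_time_grid()
    times = np.asarray(times, dtype=float)
    G, states, temperature = _extended(sys_or_net)
    n = G.shape[0] - 4
    if len(ic.weights) != n:
        raise ValueError("initial condition length does not match network size")

    factors = None
    if not G[n:, :n].any():  # closed system: try the reversible spectral path
        factors = _reversible_spectral_factors(
            G[:n, :n], states["energy_cm1"].to_numpy(float), temperature)
    if factors is not None:
        if np.any(np.diff(times) < 0) or np.any(times < 0):
            raise ValueError("times must be nonnegative ascending")
        kept = _propagate_spectral(factors, ic.weights[:, None], times)[:, :, 0]
        traj = np.hstack([kept, np.zeros((len(times), 4))])
    else:
        p0 = np.concatenate([ic.weights, np.zeros(4)])
        traj = _propagate_columns(G, p0[:, None], times)[:, :, 0]

    neg = traj < 0
    if neg.any():
        worst = traj.min()
        if worst < -1e-9:
            warnings.warn(f"large negative population {worst:.2e} clipped")
        else:
            logger.debug("clipped %d negative round-off populations (min %.1e)",
                         int(neg.sum()), worst)
        traj = np.where(neg & (traj > -CLIP_TOL * 10), 0.0, np.clip(traj, 0.0, None))
    return PopulationTrajectory(
        times=np.asarray(times, float),
        populations=traj[:, :n],
        sink_mass=traj[:, n:],
        state_table=states,
        generator_ext=G,
    )


# ----------------------------------------------------------------------------
# Absorption statistics
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class FateSummary:
    """Where an initial excitation ends up, and how fast."""

    p_trap1: float
    p_trap2: float
    p_fluor: float
    p_nonrad: float
    mfpt_trap: float = np.nan            # ps; only defined without losses
    same_monomer_fraction: float = np.nan

    @property
    def p_trapped(self) -> float:
        return self.p_trap1 + self.p_trap2

    def as_dict(self) -> dict:
        return dict(p_trap1=self.p_trap1, p_trap2=self.p_trap2,
                    p_fluor=self.p_fluor, p_nonrad=self.p_nonrad,
                    mfpt_trap=self.mfpt_trap,
                    same_monomer_fraction=self.same_monomer_fraction)


def _check_reachable(sys: OpenSystem, ic: InitialCondition | None = None) -> None:
    stranded = sys.stranded_states()
    if stranded:
        raise np.linalg.LinAlgError(
            f"transient block is singular: no sink reachable from states {list(stranded[:8])}"
            + ("..." if len(stranded) > 8 else "")
        )


def splitting_probabilities(sys: OpenSystem, ic: InitialCondition) -> FateSummary:
    """Per-sink absorption probabilities by committor-style linear solve.

    Solves ``(-T) x = p(0)`` and returns ``b = R x`` (trap 1, trap 2,
    fluorescence, nonradiative).  Without loss channels the mean first
    passage time to the traps, ``1^T x``, is filled in as well.  For a
    delta initial condition the same-monomer trapping fraction
    ``p_same / (p_trap1 + p_trap2)`` is reported.
    """
    _check_reachable(sys, ic)
    if len(ic.weights) != sys.n_states:
        raise ValueError("initial condition length does not match system size")
    x = scipy.linalg.solve(-sys.transient, ic.weights)
    b = sys.sink_rates @ x
    mfpt = float(x.sum()) if not sys.has_losses else np.nan

    same = np.nan
    if b[0] + b[1] > 0:
        support = np.flatnonzero(ic.weights > 0)
        monomers = sys.states["monomer"].to_numpy(int)[support]
        if len(set(monomers)) == 1:
            m = int(monomers[0])
            same = float(b[m - 1] / (b[0] + b[1]))
    return FateSummary(float(b[0]), float(b[1]), float(b[2]), float(b[3]),
                       mfpt_trap=mfpt, same_monomer_fraction=same)


def mean_first_passage_time(sys: OpenSystem, ic: InitialCondition) -> float:
    """Mean first passage time (ps) to any open trap, losses disabled.

    Equals the time integral of the surviving probability because trap
    absorption is certain without losses.
    """
    if sys.has_losses:
        raise ValueError("MFPT to the traps is defined without loss channels; "
                         "rebuild the scenario with losses=None")
    if not sys.open_traps:
        raise ValueError("no open trap")
    _check_reachable(sys, ic)
    x = scipy.linalg.solve(-sys.transient, ic.weights)
    return float(x.sum())


@dataclass(frozen=True)
class LifetimeResult:
    """Excitation lifetime by two estimators (ps)."""

    mean_residence_ps: float
    tail_fit_ps: float


def excitation_lifetime(sys: OpenSystem, ic: InitialCondition,
                        times: np.ndarray | None = None) -> LifetimeResult:
    """Mean excitonic residence time with all sinks active.

    The primary estimator is the exact linear-solve integral
    ``tau = 1^T (-T)^{-1} p(0)``; a single-exponential fit to the tail
    of the surviving population N(t) (over the last decade of times
    before N falls below 1e-12) is reported alongside, since a
    "fluorescence lifetime" is often quoted as a tail decay constant.
    """
    if sys.sink_rates.sum() == 0:
        raise ValueError("lifetime diverges: no sinks")
    _check_reachable(sys, ic)
    x = scipy.linalg.solve(-sys.transient, ic.weights)
    tau = float(x.sum())

    traj = propagate(sys, ic, times)
    N = traj.survival
    ok = N > 1e-12
    t_hi = traj.times[ok].max()
    sel = ok & (traj.times >= t_hi / 10.0) & (traj.times > 0)
    if sel.sum() >= 3:
        slope = np.polyfit(traj.times[sel], np.log(N[sel]), 1)[0]
        tail = float(-1.0 / slope) if slope < 0 else np.nan
    else:
        tail = np.nan
    return LifetimeResult(mean_residence_ps=tau, tail_fit_ps=tail)


# ----------------------------------------------------------------------------
# Kinetic Monte Carlo oracle
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class GillespieResult:
    """Fate statistics from exact stochastic simulation."""

    n_traj: int
    fate_counts: np.ndarray          # (4,) per SINK_LABELS
    first_passage_mean: float        # ps, over trap-absorbed trajectories
    first_passage_se: float
    checkpoint_occupancy: dict       # time -> (N+4,) frequency vector

    @property
    def fate_freq(self) -> np.ndarray:
        return self.fate_counts / self.n_traj

    @property
    def fate_se(self) -> np.ndarray:
        p = self.fate_freq
        return np.sqrt(p * (1 - p) / self.n_traj)


def gillespie_simulate(
    sys: OpenSystem,
    ic: InitialCondition,
    n_traj: int,
    seed: int,
    checkpoint_times: Sequence[float] = (),
) -> GillespieResult:
    """Exact stochastic simulation of the continuous-time chain.

    Trajectories hop with exponential waiting times at the state's total
    exit rate and land on neighbours/sinks with probability proportional
    to the corresponding rates.  Fixed ``seed`` gives bit-identical
    results.  ``checkpoint_times`` records the occupancy distribution
    (kept states + sinks) at those times for trajectory-level
    cross-checks against :func:`propagate`.
    """
    if n_traj < 1:
        raise ValueError("need n_traj >= 1")
    rng = np.random.default_rng(seed)
    n = sys.n_states
    off = sys.transient.copy()
    np.fill_diagonal(off, 0.0)
    # destination matrix: (n+4, n) column j = rates out of j
    dest = np.vstack([off, sys.sink_rates])
    exit_rate = dest.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.cumsum(dest, axis=0) / exit_rate
    cum = cum.T  # (n, n+4) for fancy indexing by current state

    state = rng.choice(n, size=n_traj, p=ic.weights)
    t = np.zeros(n_traj)
    absorbed_sink = np.full(n_traj, -1)
    absorb_time = np.full(n_traj, np.inf)
    cps = np.asarray(sorted(checkpoint_times), dtype=float)
    occupancy = {float(c): np.zeros(n + 4) for c in cps}

    active = np.arange(n_traj)
    while len(active):
        s = state[active]
        stuck = exit_rate[s] <= 0
        if stuck.any():
            raise np.linalg.LinAlgError(
                "trajectory stuck in a state with no exit; transient block singular")
        dt = rng.exponential(1.0 / exit_rate[s])
        u = rng.random(len(active))
        nxt = (u[:, None] < cum[s]).argmax(axis=1)
        for c in cps:  # record occupancy for checkpoints crossed by this hold
            hit = (t[active] <= c) & (t[active] + dt > c)
            if hit.any():
                np.add.at(occupancy[float(c)], s[hit], 1)
        t[active] += dt
        to_sink = nxt >= n
        if to_sink.any():
            gone = active[to_sink]
            absorbed_sink[gone] = nxt[to_sink] - n
            absorb_time[gone] = t[gone]
            for c in cps:  # absorbed trajectories occupy their sink afterwards
                late = c >= t[gone]
                np.add.at(occupancy[float(c)], n + (nxt[to_sink] - n)[late], 1)
        state[active[~to_sink]] = nxt[~to_sink]
        active = active[~to_sink]

    fate_counts = np.bincount(absorbed_sink, minlength=4).astype(float)
    trap_mask = absorbed_sink < 2
    if trap_mask.any():
        fp = absorb_time[trap_mask]
        fp_mean = float(fp.mean())
        fp_se = float(fp.std(ddof=1) / np.sqrt(len(fp))) if len(fp) > 1 else np.nan
    else:
        fp_mean, fp_se = np.nan, np.nan
    for c in cps:
        occupancy[float(c)] /= n_traj
    return GillespieResult(n_traj, fate_counts, fp_mean, fp_se, occupancy)


# ----------------------------------------------------------------------------
# Convenience
# ----------------------------------------------------------------------------

def equilibrium_distance(net: KineticNetwork, p: np.ndarray) -> float:
    """Max-norm distance of ``p`` from the Boltzmann equilibrium."""
    return float(np.abs(p - boltzmann_equilibrium(net)).max())
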