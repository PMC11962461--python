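"""Time-resolved free-energy decomposition of EET dynamics.

From a population trajectory the module computes

    S(t) = -k_B sum_j p_j(t) ln p_j(t)        (Shannon entropy, k_B units)
    H(t) =      sum_j p_j(t) E_j              (mean energy, cm^-1)
    dG(t) = dH(t) - T dS(t)                   (free energy change)

with changes taken relative to the initial condition.  The time of the
entropy maximum is the *population contraction time*: before it the
ensemble spreads over the near-degenerate landscape, after it the
trajectories funnel onto increasingly common pathways toward the trap.
The enthalpy-peak time marks the switch from uphill to downhill
ensemble energy flow.

Under irreversible traps the default ("raw") mode evaluates S on the
unnormalized surviving excitonic populations: the entropy then rises
from 0 (delta start), peaks, and decays back to 0 as the population
absorbs, which gives a well-defined maximum.  A "conditional" mode that
renormalizes S by the surviving mass is available for comparison.  The
enthalpy is always the conditional mean energy of the *surviving*
excitations: unlike the raw sum, this is invariant to the arbitrary
energy zero (a flat landscape gives dH = 0 identically even while the
trap drains mass) and stays on the ~100 cm^-1 scale of real transfer
steps.  Sinks are excluded from S and H throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.special

from .dynamics import PopulationTrajectory
from .units import KB_CM1_PER_K

logger = logging.getLogger("eetnet")

_NEG_TOL = 1e-9  # entries below -_NEG_TOL are an error, above are clipped


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy -sum p ln p in units of k_B, with 0 ln 0 = 0.

    ``p`` need not be normalized (raw mode evaluates the surviving,
    unnormalized populations).  Multiply by ``KB_CM1_PER_K * T`` for the
    cm^-1 scale of -T dS.
    """
    p = np.asarray(p, dtype=float)
    if p.min() < -_NEG_TOL:
        raise ValueError(f"negative probability {p.min():g} beyond clip tolerance")
    p = np.clip(p, 0.0, None)
    return float(-scipy.special.xlogy(p, p).sum())


def enthalpy(p: np.ndarray, energies: np.ndarray) -> float:
    """Mean energy sum_j p_j E_j in cm^-1 (reference-free)."""
    p = np.asarray(p, dtype=float)
    E = np.asarray(energies, dtype=float)
    if p.shape != E.shape:
        raise ValueError(f"length mismatch: p has {p.shape}, energies {E.shape}")
    return float(p @ E)


@dataclass(frozen=True)
class ThermoTrajectory:
    """S(t), H(t) and the free-energy decomposition on a time grid."""

    times: np.ndarray            # ps
    entropy: np.ndarray          # k_B units
    enthalpy: np.ndarray         # cm^-1
    dH: np.ndarray               # cm^-1
    minus_TdS: np.ndarray        # cm^-1
    dG: np.ndarray               # cm^-1
    temperature: float           # K
    normalization_mode: str      # "raw" | "conditional"
    # context for continuous-time refinement of extracted times
    generator_ext: np.ndarray | None = None
    populations_ext: np.ndarray | None = None  # (T, N+4) raw extended populations
    energies: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(dict(
            time_ps=self.times, S_kB=self.entropy, H_cm1=self.enthalpy,
            dH_cm1=self.dH, minus_TdS_cm1=self.minus_TdS, dG_cm1=self.dG,
        ))


_MASS_FLOOR = 1e-30


def _entropy_of(P: np.ndarray, mode: str) -> np.ndarray:
    """Shannon entropy (k_B) per row; mode selects raw vs mass-normalized."""
    P = np.clip(P, 0.0, None)
    if mode == "conditional":
        mass = P.sum(axis=1)
        safe = np.where(mass > _MASS_FLOOR, mass, 1.0)
        P = P / safe[:, None]
        P[mass <= _MASS_FLOOR] = 0.0
    elif mode != "raw":
        raise ValueError(f"unknown mode {mode!r}")
    return -scipy.special.xlogy(P, P).sum(axis=1)


def _conditional_enthalpy(P: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Mean energy of the surviving excitations per row (cm^-1).

    Rows whose surviving mass has fully decayed carry the last defined
    value forward (the conditional mean is then constant anyway)."""
    P = np.clip(P, 0.0, None)
    mass = P.sum(axis=1)
    safe = np.where(mass > _MASS_FLOOR, mass, 1.0)
    H = (P @ E) / safe
    dead = mass <= _MASS_FLOOR
    if dead.any():
        for k in np.flatnonzero(dead):
            H[k] = H[k - 1] if k > 0 else E @ P[0]
    return H


def free_energy_series(
    traj: PopulationTrajectory,
    net_or_energies,
    temperature: float | None = None,
    mode: str = "raw",
) -> ThermoTrajectory:
    """Compute S, H, dH, -T dS and dG along a population trajectory.

    ``net_or_energies`` supplies the state energies (a KineticNetwork,
    an OpenSystem, or a plain cm^-1 array); temperature defaults to the
    network's.  dH is evaluated against mean-centered energies with an
    explicit mass correction, which keeps the tiny free-energy steps
    near equilibrium well above round-off even though the absolute
    energies are ~15000 cm^-1.
    """
    if hasattr(net_or_energies, "energies"):
        E = np.asarray(net_or_energies.energies, dtype=float)
        if temperature is None:
            temperature = net_or_energies.temperature
    else:
        E = np.asarray(net_or_energies, dtype=float)
        if temperature is None:
            raise ValueError("temperature required when passing raw energies")
    if traj.populations.shape[1] != len(E):
        raise ValueError("energies do not match trajectory states")

    S = _entropy_of(traj.populations, mode)
    # centered energies keep the tiny near-equilibrium dH steps well
    # above round-off even though absolute energies are ~15000 cm^-1
    Ec = E - E.mean()
    H = _conditional_enthalpy(traj.populations, E)
    dH = _conditional_enthalpy(traj.populations, Ec)
    dH = dH - dH[0]
    dS = S - S[0]
    minus_TdS = -temperature * KB_CM1_PER_K * dS
    dG = dH + minus_TdS

    pop_ext = None
    if traj.generator_ext is not None:
        pop_ext = np.hstack([traj.populations, traj.sink_mass])
    return ThermoTrajectory(
        times=traj.times, entropy=S, enthalpy=H, dH=dH,
        minus_TdS=minus_TdS, dG=dG, temperature=float(temperature),
        normalization_mode=mode,
        generator_ext=traj.generator_ext, populations_ext=pop_ext, energies=E,
    )


# ----------------------------------------------------------------------------
# Extracted times
# ----------------------------------------------------------------------------

_INV_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_max(f, a: float, b: float, tol: float) -> float:
    """Golden-section maximization of a unimodal f on [a, b] to +-tol."""
    x1 = b - _INV_GOLDEN * (b - a)
    x2 = a + _INV_GOLDEN * (b - a)
    f1, f2 = f(x1), f(x2)
    while (b - a) > tol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + _INV_GOLDEN * (b - a)
            f2 = f(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - _INV_GOLDEN * (b - a)
            f1 = f(x1)
    return 0.5 * (a + b)


def _series_value_at(thermo: ThermoTrajectory, which: str, k_left: int, t: float) -> float:
    """Continuous-time S or dH at time t >= times[k_left], by propagating
    the stored population from the bracketing grid point."""
    G = thermo.generator_ext
    p_left = thermo.populations_ext[k_left]
    dt = t - thermo.times[k_left]
    p = scipy.linalg.expm(G * dt) @ p_left if dt > 0 else p_left
    n = len(thermo.energies)
    kept = np.clip(p[:n], 0.0, None)
    if which == "S":
        if thermo.normalization_mode == "conditional":
            m = kept.sum()
            kept = kept / m if m > _MASS_FLOOR else kept * 0.0
        return float(-scipy.special.xlogy(kept, kept).sum())
    # conditional mean of the centered energies; matches the dH series
    # of free_energy_series up to the constant t=0 reference
    m = kept.sum()
    Ec = thermo.energies - thermo.energies.mean()
    return float(kept @ Ec / m) if m > _MASS_FLOOR else 0.0


def _refined_peak(thermo: ThermoTrajectory, series: np.ndarray, which: str,
                  refine: bool, tol_ps: float) -> tuple[float, float]:
    """(time, series value) of the global maximum, golden-refined."""
    t = thermo.times
    idx = int(np.argmax(series))  # first index at ties -> earliest
    if idx == 0:
        return 0.0, float(series[0])
    if idx == len(t) - 1:
        raise ValueError(
            f"{which} maximum at the final grid point t={t[-1]:g} ps is not "
            "bracketed: extend time grid"
        )
    if not refine or thermo.generator_ext is None or thermo.populations_ext is None:
        return float(t[idx]), float(series[idx])
    a, b = float(t[idx - 1]), float(t[idx + 1])
    f = lambda x: _series_value_at(thermo, which, idx - 1, x)
    t_star = _golden_max(f, a, b, tol_ps)
    val = f(t_star)
    if which == "dH":
        # reference the same t=0 value the grid series uses
        val -= _series_value_at(thermo, which, 0, float(t[0]))
    return float(t_star), float(val)


def contraction_time(thermo: ThermoTrajectory, refine: bool = True,
                     tol_ps: float = 0.1) -> float:
    """Population contraction time: the time of the entropy maximum (ps).

    The grid argmax is refined by golden-section search on the
    continuously propagated entropy within the bracketing interval.  If
    the entropy is maximal at t=0 (monotone non-increasing series) the
    contraction time is 0; a maximum at the final grid point raises.
    """
    t_star, _ = _refined_peak(thermo, thermo.entropy, "S", refine, tol_ps)
    return t_star


def enthalpy_peak(thermo: ThermoTrajectory, refine: bool = True,
                  tol_ps: float = 0.1) -> tuple[float, float]:
    """(time ps, dH value cm^-1) of the enthalpy-change maximum."""
    t_star, val = _refined_peak(thermo, thermo.dH, "dH", refine, tol_ps)
    if t_star == 0.0:
        return 0.0, float(thermo.dH[0])
    return t_star, val


@dataclass(frozen=True)
class ThermoSummary:
    """Headline extracted observables of one thermo trajectory."""

    contraction_time_ps: float
    enthalpy_peak_ps: float
    enthalpy_peak_cm1: float
    entropy_max_kB: float

    def as_dict(self) -> dict:
        return dict(contraction_time_ps=self.contraction_time_ps,
                    enthalpy_peak_ps=self.enthalpy_peak_ps,
                    enthalpy_peak_cm1=self.enthalpy_peak_cm1,
                    entropy_max_kB=self.entropy_max_kB)


def summarize(thermo: ThermoTrajectory, refine: bool = True) -> ThermoSummary:
    tc = contraction_time(thermo, refine=refine)
    tp, vp = enthalpy_peak(thermo, refine=refine)
    return ThermoSummary(
        contraction_time_ps=tc,
        enthalpy_peak_ps=tp,
        enthalpy_peak_cm1=vp,
        entropy_max_kB=float(thermo.entropy.max()),
    )
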