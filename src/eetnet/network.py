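"""Kinetic networks for excitation energy transfer (EET).

A :class:`KineticNetwork` couples a per-state metadata table (exciton
states with their protein subunit, monomer, dominant pigment, energy,
coordinates and transition-dipole strength) to a rate matrix ``K`` whose
element ``K[i, j]`` is the transfer rate from state *j* to state *i* in
ps^-1.  Internally the matrix is always kept in *generator* convention:
the diagonal holds minus the column sums of the off-diagonal rates, so
that the master equation reads ``dp/dt = K p`` and the columns of a
closed network sum to zero.

Closed (trap-free) networks are required to satisfy detailed balance
with respect to the Boltzmann distribution of the state energies,

    k_ij / k_ji = exp(-(E_i - E_j) / k_B T),

which is what licenses the thermodynamic reading of the dynamics.
:func:`check_detailed_balance` verifies this pairwise condition and
:func:`boltzmann_equilibrium` returns the stationary distribution it
implies.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import scipy.special

from .units import DEFAULT_TEMPERATURE_K, thermal_energy_cm1

logger = logging.getLogger("eetnet")

#: Canonical column order of the on-disk state table (TSV with header).
STATE_TABLE_COLUMNS = (
    "state_id",
    "subunit",
    "monomer",
    "pigment",
    "energy_cm1",
    "x",
    "y",
    "z",
    "dipole_sq",
    "is_chl_a",
)

_REQUIRED_COLUMNS = ("state_id", "subunit", "monomer", "pigment", "energy_cm1")


@dataclass(frozen=True)
class StateRecord:
    """Metadata for a single exciton state."""

    state_id: str
    subunit: str
    monomer: int
    pigment: str
    energy_cm1: float
    x: float = np.nan
    y: float = np.nan
    z: float = np.nan
    dipole_sq: float = np.nan
    is_chl_a: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy_cm1):
            raise ValueError(f"state {self.state_id}: energy must be finite")
        if self.monomer not in (1, 2):
            raise ValueError(f"state {self.state_id}: monomer must be 1 or 2")
        if np.isfinite(self.dipole_sq) and self.dipole_sq < 0:
            raise ValueError(f"state {self.state_id}: dipole_sq must be >= 0")


def _states_frame(states) -> pd.DataFrame:
    """Normalize a list of StateRecord or a DataFrame to the canonical table."""
    if isinstance(states, pd.DataFrame):
        df = states.copy().reset_index(drop=True)
    else:
        df = pd.DataFrame([s.__dict__ for s in states])
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"state table missing columns: {missing}")
    for c in ("x", "y", "z", "dipole_sq"):
        if c not in df.columns:
            df[c] = np.nan
    if "is_chl_a" not in df.columns:
        df["is_chl_a"] = False
    df = df[list(STATE_TABLE_COLUMNS)]
    df["state_id"] = df["state_id"].astype(str)
    df["monomer"] = df["monomer"].astype(int)
    df["is_chl_a"] = df["is_chl_a"].astype(bool)
    df["energy_cm1"] = df["energy_cm1"].astype(float)
    dup = df["state_id"][df["state_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate state_id: {sorted(set(dup))}")
    if not df["monomer"].isin((1, 2)).all():
        raise ValueError("monomer must be 1 or 2 for every state")
    if not np.isfinite(df["energy_cm1"].to_numpy()).all():
        raise ValueError("state energies must be finite")
    d = df["dipole_sq"].to_numpy(float)
    if np.any(d[np.isfinite(d)] < 0):
        raise ValueError("dipole_sq must be >= 0")
    return df


def normalize_generator(rates: np.ndarray) -> np.ndarray:
    """Return ``rates`` with the diagonal rebuilt as minus the column sums.

    Accepts either a pure-rate matrix (zero diagonal) or a generator
    (diagonal already holding the negative outflow); the off-diagonal
    part is taken as-is and the diagonal is always re-derived, which
    removes a silent failure mode when file conventions are mixed up.
    """
    K = np.array(rates, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"rate matrix must be square, got shape {K.shape}")
    if not np.isfinite(K).all():
        raise ValueError("rate matrix contains NaN/Inf")
    off = K.copy()
    np.fill_diagonal(off, 0.0)
    if off.min() < 0:
        i, j = np.unravel_index(np.argmin(off), off.shape)
        raise ValueError(
            f"negative rate k[{i},{j}] = {off[i, j]:g} (off-diagonal rates must be >= 0)"
        )
    # sort each column before summing so the rebuilt diagonal is invariant
    # to row ordering (keeps mirror-symmetric dimers bit-exactly symmetric)
    np.fill_diagonal(off, -np.sort(off, axis=0).sum(axis=0))
    return off


@dataclass(frozen=True)
class KineticNetwork:
    """A validated EET rate network in generator convention.

    Parameters
    ----------
    states : DataFrame
        Per-state metadata with the :data:`STATE_TABLE_COLUMNS` columns,
        row order matching the rate-matrix order.
    rates : ndarray, shape (N, N)
        ``rates[i, j]`` = transfer rate j -> i, ps^-1, generator diagonal.
    temperature : float
        Bath temperature in K used for detailed balance and equilibrium.
    """

    states: pd.DataFrame
    rates: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        df = _states_frame(self.states)
        K = normalize_generator(self.rates)
        if K.shape[0] != len(df):
            raise ValueError(
                f"dimension mismatch: rate matrix is {K.shape[0]}x{K.shape[1]} "
                f"but state table has {len(df)} rows"
            )
        K.setflags(write=False)
        object.__setattr__(self, "states", df)
        object.__setattr__(self, "rates", K)

    # -- convenience views -------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def state_ids(self) -> np.ndarray:
        return self.states["state_id"].to_numpy()

    @property
    def energies(self) -> np.ndarray:
        return self.states["energy_cm1"].to_numpy(float)

    @property
    def subunits(self) -> np.ndarray:
        return self.states["subunit"].to_numpy()

    @property
    def monomers(self) -> np.ndarray:
        return self.states["monomer"].to_numpy(int)

    def state_records(self) -> tuple[StateRecord, ...]:
        return tuple(StateRecord(**row) for row in self.states.to_dict("records"))

    def index_of(self, state_id: str) -> int:
        hits = np.flatnonzero(self.state_ids == state_id)
        if len(hits) == 0:
            raise KeyError(f"unknown state_id {state_id!r}")
        return int(hits[0])

    def with_rates(self, rates: np.ndarray) -> "KineticNetwork":
        return replace(self, rates=rates)


@dataclass(frozen=True)
class DisorderEnsemble:
    """A set of static-disorder realizations sharing one state list."""

    realizations: tuple[KineticNetwork, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.realizations) < 1:
            raise ValueError("ensemble needs at least one realization")
        ids0 = self.realizations[0].state_ids
        for k, net in enumerate(self.realizations[1:], start=1):
            if net.n_states != len(ids0) or not np.array_equal(net.state_ids, ids0):
                raise ValueError(f"realization {k} has a mismatched state ordering")
        object.__setattr__(self, "realizations", tuple(self.realizations))

    @property
    def n_realizations(self) -> int:
        return len(self.realizations)


# ----------------------------------------------------------------------------
# Detailed balance and equilibrium
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class DetailedBalanceReport:
    """Result of the pairwise detailed-balance check."""

    passed: bool
    worst_deviation: float          # max |(k_ij/k_ji) / boltzmann - 1|
    worst_pair: tuple[str, str] | None
    n_pairs_checked: int
    one_sided_pairs: tuple[tuple[str, str], ...]  # k_ij>0 but k_ji==0

    def __bool__(self) -> bool:  # allows `assert check_detailed_balance(net)`
        return self.passed


def check_detailed_balance(net: KineticNetwork, tol: float = 1e-9) -> DetailedBalanceReport:
    """Check k_ij/k_ji = exp(-(E_i-E_j)/k_B T) for every two-sided pair.

    One-sided pairs (forward rate positive, reverse zero) are collected
    in the report rather than failed: an irreversible trap is the only
    sanctioned source of such edges and the caller decides whether they
    are expected.
    """
    beta = 1.0 / thermal_energy_cm1(net.temperature)
    K = net.rates
    E = net.energies
    off = K.copy()
    np.fill_diagonal(off, 0.0)
    fwd = off > 0
    both = fwd & fwd.T
    iu = np.triu(both, k=1)
    i_idx, j_idx = np.nonzero(iu)
    ids = net.state_ids
    one_sided_mask = fwd & ~fwd.T
    os_i, os_j = np.nonzero(one_sided_mask)
    one_sided = tuple((str(ids[j]), str(ids[i])) for i, j in zip(os_i, os_j))

    if len(i_idx) == 0:
        return DetailedBalanceReport(True, 0.0, None, 0, one_sided)

    ratio = off[i_idx, j_idx] / off[j_idx, i_idx]
    expected = np.exp(-beta * (E[i_idx] - E[j_idx]))
    dev = np.abs(ratio / expected - 1.0)
    w = int(np.argmax(dev))
    worst = float(dev[w])
    worst_pair = (str(ids[i_idx[w]]), str(ids[j_idx[w]]))  # lower index first
    return DetailedBalanceReport(worst <= tol, worst, worst_pair, len(i_idx), one_sided)


def boltzmann_equilibrium(net: KineticNetwork) -> np.ndarray:
    """Boltzmann distribution pi_i ∝ exp(-E_i / k_B T) over the states."""
    beta = 1.0 / thermal_energy_cm1(net.temperature)
    logw = -beta * net.energies
    return np.exp(logw - scipy.special.logsumexp(logw))


def validate_network(
    net: KineticNetwork,
    tol: float = 1e-9,
    allowed_one_sided: Iterable[tuple[str, str]] = (),
) -> DetailedBalanceReport:
    """Full validation of a closed network: detailed balance plus the rule
    that one-sided rates are allowed only for designated (trap) transitions.
    """
    report = check_detailed_balance(net, tol=tol)
    if not report.passed:
        raise ValueError(
            f"detailed balance violated: worst pair {report.worst_pair} "
            f"deviates by {report.worst_deviation:.3g} (tol {tol:g})"
        )
    allowed = {tuple(p) for p in allowed_one_sided}
    bad = [p for p in report.one_sided_pairs if p not in allowed]
    if bad:
        raise ValueError(
            f"one-sided rates outside designated trap transitions: {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )
    return report


def average_rate_matrices(ens: DisorderEnsemble) -> KineticNetwork:
    """Element-wise mean of the off-diagonal rates across realizations.

    The disorder-averaged matrix is the conventional single-matrix
    surrogate for the ensemble; the diagonal is rebuilt from the
    averaged off-diagonal rates.  State energies are averaged alongside
    (each realization is detailed balanced with respect to its own
    energies; the averaged matrix is only approximately so and the
    ensemble-mean energies are the natural partner for its
    thermodynamic series).
    """
    mats = np.stack([r.rates for r in ens.realizations])
    mean = mats.mean(axis=0)
    np.fill_diagonal(mean, 0.0)
    first = ens.realizations[0]
    states = first.states.copy()
    states["energy_cm1"] = np.mean(
        [r.energies for r in ens.realizations], axis=0)
    return KineticNetwork(states, mean, temperature=first.temperature)


# ----------------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _read_matrix(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".mtx", ".mm"):
        M = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(M):
            M = M.toarray()
        return np.asarray(M, dtype=float)
    first = path.open().readline()
    delim = "," if ("," in first and "\t" not in first) else None
    return np.loadtxt(path, delimiter=delim, ndmin=2)


def read_network(
    rate_matrix_path: str | Path,
    state_table_path: str | Path,
    temperature: float = DEFAULT_TEMPERATURE_K,
    transpose: bool = False,
    allow_one_sided: bool = True,
) -> KineticNetwork:
    """Read a rate matrix (dense TSV/CSV or Matrix Market) plus state table.

    The on-disk dense convention is column-source: column *j* holds the
    outflows of state *j*, i.e. entry ``[i][j]`` is the rate j -> i,
    matching the internal convention.  Set ``transpose=True`` for files
    written row-source.  Zero or generator diagonals are both accepted;
    the diagonal is always rebuilt.  With ``allow_one_sided=False`` any
    pair with a forward rate but no reverse rate raises (use for closed,
    trap-free matrices).
    """
    rate_matrix_path = Path(rate_matrix_path)
    state_table_path = Path(state_table_path)
    M = _read_matrix(rate_matrix_path)
    if transpose:
        M = M.T
    states = pd.read_csv(state_table_path, sep="\t")
    net = KineticNetwork(states, M, temperature=temperature)
    if not allow_one_sided:
        off = net.rates.copy()
        np.fill_diagonal(off, 0.0)
        bad = np.nonzero((off > 0) & (off.T == 0))
        if len(bad[0]):
            i, j = int(bad[0][0]), int(bad[1][0])
            raise ValueError(
                f"one-sided rate {net.state_ids[j]} -> {net.state_ids[i]} "
                "in a closed network"
            )
    census = net.states["subunit"].value_counts().to_dict()
    logger.info(
        "read network: N=%d, rates=%s (sha256 %s), states=%s (sha256 %s), "
        "energy range [%.1f, %.1f] cm^-1, subunits %s",
        net.n_states, rate_matrix_path, _sha256(rate_matrix_path),
        state_table_path, _sha256(state_table_path),
        net.energies.min(), net.energies.max(), census,
    )
    return net


def write_network(
    net: KineticNetwork,
    rate_matrix_path: str | Path,
    state_table_path: str | Path,
) -> None:
    """Write the generator-convention matrix as dense TSV (17 significant
    digits, bit-exact round trip) and the state table as TSV."""
    np.savetxt(rate_matrix_path, net.rates, delimiter="\t", fmt="%.17g")
    net.states.to_csv(state_table_path, sep="\t", index=False)
    logger.info("wrote network N=%d to %s / %s", net.n_states,
                rate_matrix_path, state_table_path)
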