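"""Continuous-time simulation of extracted eigencircuits with rectification.

A circuit's weight matrix W describes one discrete interaction step of
T = 10 ms. To simulate at a finer sampling period Delta = 1 ms, the step is
interpolated through the principal fractional matrix power

    r_{t+Delta} = W^(Delta/T) f(r_t + u_t),

with f a pointwise nonlinearity (rectification by default) and u_t step
stimuli. For circuits with negative or complex eigenvalues the fractional
power is genuinely complex: each eigenmode advances by a fraction of its
rotation angle per sample. The simulator therefore iterates the complex
(rotation-preserving) propagator by default, rectifying on the real part of
the state and reporting the real part as activity; composing Delta-steps
over one full T recovers the matrix W exactly in the linear regime. A
"real" state mode that iterates the real-part propagator matrix instead is
available for comparison, as is an optional membrane leak exp(-Delta/tau).

Before simulation the circuit matrix is rescaled so its maximum eigenvalue
(largest real part) equals 1: mutual-inhibition circuits then keep a
marginally stable competition mode, which is what sustains a winner's
response for the whole stimulus; rescaling by spectral radius is available
as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .exceptions import ConfigError, DefectiveMatrixError

__all__ = [
    "StepStimulus",
    "CircuitProtocol",
    "CircuitTrajectory",
    "PropagatorInfo",
    "build_propagator",
    "simulate_circuit",
    "run_opponent_motion",
    "run_wta",
    "opponent_motion_fixture",
    "mutual_inhibition_fixture",
    "OPPONENT_ROLES",
]


@dataclass
class StepStimulus:
    """A step input: ``amplitude`` to ``neurons`` during [onset, onset+duration)."""

    neurons: Sequence[int]
    onset: float = 0.0
    duration: float = 150.0
    amplitude: float = 0.01

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigError("stimulus amplitudes must be >= 0")
        if self.duration <= 0:
            raise ConfigError("stimulus durations must be > 0")


@dataclass
class CircuitProtocol:
    """Specification of a continuous-time circuit simulation.

    Times are in milliseconds. ``T`` is the discrete interaction step of the
    weight matrix (default 10 ms), ``delta`` the sampling period (default
    1 ms), ``tau`` the membrane time constant used when ``leak`` is on.
    ``scaling``: "max_eigenvalue" rescales the largest eigenvalue (real
    part) to 1, "radius" the spectral radius to 1, None leaves W as given.
    ``state``: "rotational" (complex propagator, default) or "real"
    (real-part propagator matrix).
    """

    W_sub: np.ndarray
    delta: float = 1.0
    T: float = 10.0
    tau: float = 0.5
    nonlinearity: str = "rectify"
    stimuli: Sequence[StepStimulus] = field(default_factory=list)
    horizon: float = 150.0
    leak: bool = False
    scaling: str | None = "max_eigenvalue"
    state: str = "rotational"

    def __post_init__(self):
        self.W_sub = np.atleast_2d(np.asarray(self.W_sub, dtype=float))
        if self.W_sub.shape[0] != self.W_sub.shape[1]:
            raise ConfigError("circuit matrix must be square")
        if self.delta > self.T:
            raise ConfigError("sampling period delta must not exceed T")
        if self.nonlinearity not in ("rectify", "identity"):
            raise ConfigError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.scaling not in ("max_eigenvalue", "radius", None):
            raise ConfigError(f"unknown scaling {self.scaling!r}")
        if self.state not in ("rotational", "real"):
            raise ConfigError(f"unknown state mode {self.state!r}")


@dataclass
class CircuitTrajectory:
    """Simulated activity: ``states[t]`` is the circuit state at ``times[t]``."""

    times: np.ndarray
    states: np.ndarray
    protocol: CircuitProtocol

    def window_mean(self, start: float, stop: float) -> np.ndarray:
        """Per-neuron mean activity over times in [start, stop)."""
        sel = (self.times >= start) & (self.times < stop)
        if not sel.any():
            raise ConfigError("empty averaging window")
        return self.states[sel].mean(axis=0)


@dataclass
class PropagatorInfo:
    """Diagnostics of the fractional-power propagator."""

    imag_residual: float
    recon_residual: float
    eig_condition: float
    leak_factor: float


def _scale_circuit(W: np.ndarray, scaling: str | None) -> np.ndarray:
    if scaling is None or not W.any():
        return W
    vals = np.linalg.eigvals(W)
    if scaling == "radius":
        denom = np.abs(vals).max()
    else:
        denom = vals.real.max()
        if denom <= 1e-12:  # no growing mode: fall back to radius
            denom = np.abs(vals).max()
    return W / denom


def _complex_propagator(
    W: np.ndarray, delta: float, T: float, cond_limit: float = 1e12
):
    vals, V = scipy.linalg.eig(W)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > cond_limit:
        raise DefectiveMatrixError(
            f"eigenvector matrix condition {cond:.2e} exceeds {cond_limit:.0e}: "
            "the circuit matrix is (numerically) non-diagonalizable; add a "
            "small random jitter to its entries"
        )
    s = delta / T
    frac = np.where(vals == 0, 0.0, vals.astype(complex) ** s)
    P = V @ (frac[:, None] * scipy.linalg.inv(V))
    return P, vals, cond


def build_propagator(
    W_sub: np.ndarray,
    delta: float = 1.0,
    T: float = 10.0,
    tau: float = 0.5,
    leak: bool = False,
) -> tuple[np.ndarray, PropagatorInfo]:
    """Real-part fractional-power propagator P ~ Re(W^(Delta/T)).

    Computed by eigendecomposition with the principal branch of the
    logarithm for each eigenvalue. The returned info reports the imaginary
    residual discarded by the real-part projection and the reconstruction
    residual ||P_c^(T/Delta) - W|| / ||W|| of the full complex propagator.
    With ``leak`` the result is multiplied by exp(-Delta/tau).
    """
    W = np.atleast_2d(np.asarray(W_sub, dtype=float))
    P_c, _, cond = _complex_propagator(W, delta, T)
    norm_p = np.linalg.norm(P_c) or 1.0
    imag_residual = float(np.linalg.norm(P_c.imag) / norm_p)
    steps = T / delta
    if abs(steps - round(steps)) < 1e-9:
        recon = np.linalg.matrix_power(P_c, int(round(steps)))
        recon_residual = float(
            np.linalg.norm(recon - W) / max(np.linalg.norm(W), 1e-300)
        )
    else:
        recon_residual = float("nan")
    leak_factor = float(np.exp(-delta / tau)) if leak else 1.0
    return leak_factor * P_c.real, PropagatorInfo(
        imag_residual=imag_residual,
        recon_residual=recon_residual,
        eig_condition=float(cond),
        leak_factor=leak_factor,
    )


def _input_matrix(protocol: CircuitProtocol, n_steps: int, n: int) -> np.ndarray:
    U = np.zeros((n_steps, n))
    for stim in protocol.stimuli:
        lo = int(np.ceil(stim.onset / protocol.delta - 1e-9))
        hi = int(np.ceil((stim.onset + stim.duration) / protocol.delta - 1e-9))
        idx = np.asarray(tuple(stim.neurons), dtype=int)
        U[max(lo, 0) : min(hi, n_steps), idx] += stim.amplitude
    return U


def simulate_circuit(
    protocol: CircuitProtocol, r0: np.ndarray | None = None
) -> CircuitTrajectory:
    """Iterate r_{t+Delta} = P f(r_t + u_t) over the protocol horizon.

    With the identity nonlinearity and no input, the rotational state mode
    reproduces the closed-form eigenmode evolution lambda^(t Delta / T) v
    exactly. Under rectification the reported (real-part) activity is
    clamped at zero going into each propagation step.
    """
    n = protocol.W_sub.shape[0]
    W = _scale_circuit(protocol.W_sub, protocol.scaling)
    P_c, _, _ = _complex_propagator(W, protocol.delta, protocol.T)
    leak = np.exp(-protocol.delta / protocol.tau) if protocol.leak else 1.0

    rotational = protocol.state == "rotational"
    P = leak * (P_c if rotational else P_c.real)
    rectify = protocol.nonlinearity == "rectify"

    n_steps = int(round(protocol.horizon / protocol.delta))
    U = _input_matrix(protocol, n_steps, n)
    if r0 is None:
        r = np.zeros(n, dtype=complex if rotational else float)
    else:
        r = np.asarray(r0).astype(complex if rotational else float)
        if r.shape != (n,):
            raise ConfigError(f"r0 must have shape ({n},)")

    states = np.empty((n_steps, n))
    for t in range(n_steps):
        x = r + U[t]
        if rectify:
            if rotational:
                x = np.where(x.real > 0, x, 0)
            else:
                x = np.maximum(x, 0.0)
        r = P @ x
        states[t] = r.real
    times = protocol.delta * np.arange(1, n_steps + 1)
    return CircuitTrajectory(times=times, states=states, protocol=protocol)


# ---------------------------------------------------------------------------
# in-paper circuit fixtures
# ---------------------------------------------------------------------------

#: Roles of the opponent-motion (horizontal-system) eigencircuit members.
OPPONENT_ROLES: Mapping[str, int] = {
    "VCH": 0,
    "DCH": 1,
    "LPi15": 2,
    "Am1": 3,
    "other": 4,
}


def opponent_motion_fixture() -> np.ndarray:
    """All-inhibitory opponent-motion circuit (lobula-plate CH-cell motif).

    Topology: VCH and DCH do not inhibit each other; both are inhibited by
    Am1 and LPi15; Am1 receives recurrent inhibition from VCH and DCH while
    LPi15 does not; a fifth, unnamed member carries weak reciprocal
    inhibition that keeps the matrix diagonalizable. Rows are postsynaptic,
    columns presynaptic; magnitudes are synthetic (order-of-magnitude
    placeholders for signed synapse counts, not measured values).
    """
    W = np.zeros((5, 5))
    W[0, 2] = W[1, 2] = -1.0  # LPi15 -> VCH, DCH (unreciprocated)
    W[0, 3] = W[1, 3] = -1.0  # Am1 -> VCH, DCH
    W[3, 0] = W[3, 1] = -1.0  # VCH, DCH -> Am1 (recurrent)
    W[0, 4] = W[1, 4] = -0.4  # fifth member -> VCH, DCH
    W[4, 0] = W[4, 1] = -0.4
    W[2, 4] = W[4, 2] = -0.2  # fifth member <-> LPi15
    W[3, 4] = W[4, 3] = -0.1  # fifth member <-> Am1
    return W


def mutual_inhibition_fixture(n: int = 9, weight: float = 1.0) -> np.ndarray:
    """Complete mutual inhibition (ellipsoid-body ring-neuron motif)."""
    if n < 2:
        raise ConfigError("need at least 2 neurons")
    return -weight * (np.ones((n, n)) - np.eye(n))


def run_opponent_motion(
    W: np.ndarray | None = None,
    roles: Mapping[str, int] | None = None,
    condition: str = "contralateral",
    amplitude: float = 0.01,
    duration: float = 150.0,
    **protocol_kw,
) -> tuple[CircuitTrajectory, dict]:
    """Simulate back-to-front-motion drive of the opponent-motion circuit.

    ``contralateral`` applies a 150 ms step (amplitude 0.01) to VCH and DCH
    only (BTF motion seen by one eye); ``bilateral`` applies the same step
    to every neuron. Returns the trajectory and each neuron's mean activity
    during the stimulation window, keyed by role.
    """
    if W is None:
        W = opponent_motion_fixture()
        roles = dict(OPPONENT_ROLES)
    if roles is None:
        raise ConfigError("a role -> index mapping is required with a custom matrix")
    for role in ("VCH", "DCH"):
        if role not in roles:
            raise ConfigError(f"role {role!r} missing from the role mapping")
    n = np.atleast_2d(W).shape[0]
    if condition == "contralateral":
        targets = [roles["VCH"], roles["DCH"]]
    elif condition == "bilateral":
        targets = list(range(n))
    else:
        raise ConfigError(f"unknown condition {condition!r}")
    protocol = CircuitProtocol(
        W_sub=W,
        stimuli=[StepStimulus(neurons=targets, onset=0.0, duration=duration, amplitude=amplitude)],
        horizon=duration,
        **protocol_kw,
    )
    traj = simulate_circuit(protocol)
    means = traj.window_mean(0.0, duration)
    index_to_role = {v: k for k, v in roles.items()}
    summary = {
        index_to_role.get(i, f"neuron_{i}"): float(means[i]) for i in range(n)
    }
    return traj, summary


def run_wta(
    W: np.ndarray | None = None,
    winner: int = 0,
    winner_amplitude: float = 0.01,
    loser_amplitude: float = 0.006,
    duration: float = 150.0,
    **protocol_kw,
) -> tuple[CircuitTrajectory, dict]:
    """Winner-take-all protocol on a mutually inhibitory circuit.

    All neurons receive a 150 ms step of amplitude 0.006 while the winner
    receives 0.01. The summary reports each neuron's mean activity over the
    final third of stimulation plus the winner-to-best-loser ratio.
    """
    if W is None:
        W = mutual_inhibition_fixture()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n = W.shape[0]
    if n < 2:
        raise ConfigError("winner-take-all needs >= 2 neurons")
    if not 0 <= winner < n:
        raise ConfigError(f"winner index {winner} out of range")
    losers = [i for i in range(n) if i != winner]
    protocol = CircuitProtocol(
        W_sub=W,
        stimuli=[
            StepStimulus(neurons=losers, onset=0.0, duration=duration, amplitude=loser_amplitude),
            StepStimulus(neurons=[winner], onset=0.0, duration=duration, amplitude=winner_amplitude),
        ],
        horizon=duration,
        **protocol_kw,
    )
    traj = simulate_circuit(protocol)
    late = traj.window_mean(duration * 2 / 3, duration)
    best_loser = float(late[losers].max())
    summary = {
        "late_means": late,
        "winner": winner,
        "winner_mean": float(late[winner]),
        "best_loser_mean": best_loser,
        "winner_ratio": float(late[winner] / best_loser)
        if best_loser > 0
        else float("inf"),
    }
    return traj, summary
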