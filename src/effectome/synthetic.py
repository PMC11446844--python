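"""Synthetic connectomes, prior-drawn ground-truth weight matrices, and the
confounded two-neuron scenario.

These generators emulate the statistics that make whole-brain causal
inference in the fly hard: extreme sparsity (on the order of 0.01% of
ordered neuron pairs connected), integer synapse counts at or above the
proofreading threshold, one outgoing sign per presynaptic neuron (Dale's
law), and slow unobserved common inputs that confound passive correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.signal import lfilter

from .connectome import SignedConnectome
from .dynamics import SimRecord
from .exceptions import ConfigError


@dataclass
class SynthConfig:
    """Parameters of the random signed connectome generator.

    ``sparsity`` is the independent probability that an ordered pair of
    distinct neurons connects (default 1e-4, i.e. ~0.01% of pairs, the fly
    regime). Counts are drawn as ``offset + Geometric(p)`` so every edge
    respects the synapse-count threshold; the offset doubles as the implied
    threshold. ``inhibitory_fraction`` of presynaptic neurons get negative
    outgoing sign.
    """

    d: int = 10_000
    sparsity: float = 1e-4
    inhibitory_fraction: float = 0.35
    count_offset: int = 5
    count_p: float = 0.3
    allow_autapses: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.sparsity <= 1:
            raise ConfigError("sparsity must be in [0, 1]")
        if not 0 <= self.inhibitory_fraction <= 1:
            raise ConfigError("inhibitory_fraction must be in [0, 1]")
        if self.d < 1:
            raise ConfigError("d must be >= 1")


@dataclass
class ConfounderSpec:
    """A slow unobserved common-input process.

    ``ar1``: z_t = persistence * z_{t-1} + amplitude * eta_t with standard
    normal innovations, so the stationary variance is
    amplitude^2 / (1 - persistence^2). ``smoothed-noise``: white noise
    convolved with a boxcar whose length is set by the persistence
    (1 / (1 - persistence) samples), scaled to the same stationary variance.
    ``amplitude`` is expressed in units of the private noise s.d.;
    amplitude 0 disables confounding.
    """

    process: str = "ar1"
    persistence: float = 0.995
    amplitude: float = 0.2
    targets: Sequence[int] = field(default_factory=lambda: (0, 1))

    def __post_init__(self):
        if not 0 <= self.persistence < 1:
            raise ConfigError("persistence must be in [0, 1)")
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.process not in ("ar1", "smoothed-noise"):
            raise ConfigError(f"unknown confounder process {self.process!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw a length-n stationary trace of the confounder."""
        if self.amplitude == 0:
            return np.zeros(n)
        eta = rng.standard_normal(n)
        if self.process == "ar1":
            phi = self.persistence
            z0 = rng.standard_normal() * self.amplitude / np.sqrt(1 - phi**2)
            z = lfilter([self.amplitude], [1.0, -phi], eta, zi=[phi * z0])[0]
            return z
        window = max(int(round(1.0 / (1.0 - self.persistence))), 1)
        kernel = np.ones(window) / np.sqrt(window)
        pad = rng.standard_normal(window - 1)
        smooth = np.convolve(np.concatenate([pad, eta]), kernel, mode="valid")
        target_sd = self.amplitude / np.sqrt(1 - self.persistence**2)
        return smooth * target_sd


def generate_random_connectome(cfg: SynthConfig) -> SignedConnectome:
    """Draw a sparse signed integer-count connectome.

    Each ordered pair connects independently with probability
    ``cfg.sparsity``; counts follow ``offset + Geometric(p)``; signs are
    fixed per presynaptic neuron. Deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.d
    n_pairs = d * d if cfg.allow_autapses else d * (d - 1)
    n_edges = rng.binomial(n_pairs, cfg.sparsity) if n_pairs else 0

    # sample n_edges distinct ordered pairs by index, topping up collisions
    chosen: np.ndarray = np.empty(0, dtype=np.int64)
    while len(chosen) < n_edges:
        draw = rng.integers(0, n_pairs, size=(n_edges - len(chosen)) * 2 + 8)
        chosen = np.unique(np.concatenate([chosen, draw]))[: n_edges]
    if cfg.allow_autapses:
        rows, cols = np.divmod(chosen, d)
    else:
        # index over off-diagonal slots: row i has d-1 slots
        rows, slot = np.divmod(chosen, d - 1) if d > 1 else (chosen, chosen)
        cols = slot + (slot >= rows)

    counts = cfg.count_offset + rng.geometric(cfg.count_p, size=len(rows))
    signs = np.where(rng.random(d) < cfg.inhibitory_fraction, -1.0, 1.0)
    vals = counts * signs[cols]
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(d, d))
    return SignedConnectome(
        neuron_index=np.arange(d, dtype=np.int64),
        matrix=matrix,
        threshold=cfg.count_offset,
    )


def draw_effectome_from_prior(
    conn: SignedConnectome, scale_s: float, seed: int = 0
) -> SignedConnectome:
    """Draw a ground-truth weight matrix from the connectome prior.

    Each nonzero signed count c_ij yields an independent draw from
    ``Normal(s * c_ij, |s * c_ij|)``; zero entries remain exactly zero (no
    constant is added to the variance), so the support of the draw is
    contained in the support of the connectome.
    """
    rng = np.random.default_rng(seed)
    coo = sp.coo_matrix(conn.matrix)
    mu = scale_s * coo.data
    w = mu + np.sqrt(np.abs(mu)) * rng.standard_normal(len(mu))
    matrix = sp.csr_matrix((w, (coo.row, coo.col)), shape=conn.matrix.shape)
    return SignedConnectome(
        neuron_index=conn.neuron_index.copy(),
        matrix=matrix,
        scale_factor=1.0,
        threshold=conn.threshold,
    )


def make_confounded_pair(
    confounder: ConfounderSpec | None = None,
    beta: float = 0.0,
    n_samples: int = 10_000,
    seed: int = 0,
    laser_variance: float = 1.0,
    noise_sd: float = 1.0,
    laser_weight: float = 1.0,
) -> SimRecord:
    """Simulate the two-neuron confounding scenario.

    A white-noise laser drives neuron X; X causally drives neuron Y one step
    later with weight ``beta``; a slow shared signal Z is added to both, so
    X and Y correlate even when beta = 0:

        X_t = laser_weight * L_t + Z_t + e^x_t
        Y_t = beta * X_{t-1} + Z_t + e^y_t

    The ground-truth dynamics matrix therefore has a single nonzero weight,
    beta, from X to Y.
    """
    if n_samples < 2:
        raise ConfigError("n_samples must be >= 2")
    confounder = ConfounderSpec() if confounder is None else confounder
    rng = np.random.default_rng(seed)

    L = np.sqrt(laser_variance) * rng.standard_normal(n_samples)
    z = confounder.sample(n_samples, rng) * noise_sd
    ex = noise_sd * rng.standard_normal(n_samples)
    ey = noise_sd * rng.standard_normal(n_samples)

    zx = z if 0 in tuple(confounder.targets) else 0.0
    zy = z if 1 in tuple(confounder.targets) else 0.0
    x = laser_weight * L + zx + ex
    y = np.empty(n_samples)
    y[0] = 0.0
    y[1:] = beta * x[:-1]
    y += zy + ey

    w_true = SignedConnectome(
        neuron_index=np.array([0, 1]),
        matrix=sp.csr_matrix(np.array([[0.0, 0.0], [beta, 0.0]])),
    )
    return SimRecord(
        R=np.column_stack([x, y]),
        L=L[:, None],
        W_true=w_true,
        W_lx=np.array([[laser_weight], [0.0]]),
        noise_scale=noise_sd**2,
        laser_variance=laser_variance,
        confounder_trace=z,
        source_ids=np.array([0]),
        target_ids=np.array([0, 1]),
        seed=seed,
    )
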