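"""VAR(1) simulation of neural activity under white-noise laser drive.

The model is a first-order vector autoregression

    r_t = W r_{t-1} + W_lx L_t + eps_t,

where r_t collects the activity of D neurons, W is the dynamics ("effectome")
matrix, L_t is the vector of independent white-noise laser powers driving the
opsin-expressing source neurons through W_lx, and eps_t is i.i.d. noise with
covariance c * I plus any configured slow confounder component. The laser
enters at the same tick as the noise, so its first-order effect on downstream
targets appears one step later — which is exactly what the instrumental-
variable estimators exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .connectome import SignedConnectome, spectral_radius
from .exceptions import ConfigError, StabilityError


@dataclass
class SimRecord:
    """A simulated recording with its ground truth.

    Attributes
    ----------
    R:
        T x D activity matrix (rows are time steps).
    L:
        T x n_l laser matrix; columns are mutually independent white noise.
    W_true:
        The dynamics matrix used, as a :class:`SignedConnectome`.
    W_lx:
        D x n_l laser-effect matrix.
    noise_scale:
        The c in the noise covariance c * I.
    laser_variance:
        Per-laser variance l (SNR is l / c).
    confounder_trace:
        T-vector of the shared slow signal, or None.
    source_ids / target_ids / unobserved_ids:
        Positional index sets for the X (stimulated+observed), Y (observed)
        and Z (neither) roles; sources are a subset of targets.
    """

    R: np.ndarray
    L: np.ndarray
    W_true: SignedConnectome | None = None
    W_lx: np.ndarray | sp.spmatrix | None = None
    noise_scale: float = 1.0
    laser_variance: float = 1.0
    confounder_trace: np.ndarray | None = None
    source_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    target_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    unobserved_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    seed: int | None = None
    dt_ms: float = 1.0

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim == 1:
            self.L = self.L[:, None]
        self.source_ids = np.asarray(self.source_ids, dtype=int)
        self.target_ids = np.asarray(self.target_ids, dtype=int)
        if len(self.R) != len(self.L):
            raise ConfigError("R and L must have the same number of time steps")
        if len(self.source_ids) and not np.isin(self.source_ids, self.target_ids).all():
            raise ConfigError("source neurons must be a subset of target neurons")

    @property
    def n_steps(self) -> int:
        return self.R.shape[0]

    def iv_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(L_t, X_t, Y_{t+1}) slices aligned for instrumental estimation."""
        X = self.R[:-1, self.source_ids]
        Y = self.R[1:, self.target_ids]
        L = self.L[:-1]
        return L, X, Y

    def save(self, directory) -> None:
        """Persist as a directory of delimited text + MatrixMarket files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "activity.tsv", self.R, delimiter="\t")
        np.savetxt(directory / "laser.tsv", self.L, delimiter="\t")
        if self.confounder_trace is not None:
            np.savetxt(directory / "confounder.tsv", self.confounder_trace, delimiter="\t")
        if self.W_true is not None:
            from .connectome import save_matrix

            save_matrix(self.W_true, directory / "w_true.mtx")
        if self.W_lx is not None:
            mmwrite(str(directory / "w_lx.mtx"), sp.coo_matrix(self.W_lx))
        meta = {
            "noise_scale": self.noise_scale,
            "laser_variance": self.laser_variance,
            "seed": self.seed,
            "dt_ms": self.dt_ms,
            "source_ids": ",".join(map(str, self.source_ids.tolist())),
            "target_ids": ",".join(map(str, self.target_ids.tolist())),
            "unobserved_ids": ",".join(map(str, np.asarray(self.unobserved_ids).tolist())),
        }
        with open(directory / "meta.txt", "w") as fh:
            for k, v in meta.items():
                fh.write(f"{k} = {v}\n")

    @classmethod
    def load(cls, directory) -> "SimRecord":
        directory = Path(directory)
        R = np.loadtxt(directory / "activity.tsv", delimiter="\t", ndmin=2)
        L = np.loadtxt(directory / "laser.tsv", delimiter="\t", ndmin=2)
        meta: dict[str, str] = {}
        with open(directory / "meta.txt") as fh:
            for line in fh:
                if "=" in line:
                    k, v = line.split("=", 1)
                    meta[k.strip()] = v.strip()

        def _ids(key):
            raw = meta.get(key, "")
            return np.array([int(t) for t in raw.split(",") if t != ""], dtype=int)

        w_true = None
        if (directory / "w_true.mtx").exists():
            from .connectome import load_matrix

            w_true = load_matrix(directory / "w_true.mtx")
        w_lx = None
        if (directory / "w_lx.mtx").exists():
            w_lx = np.asarray(mmread(str(directory / "w_lx.mtx")).todense())
        conf = None
        if (directory / "confounder.tsv").exists():
            conf = np.loadtxt(directory / "confounder.tsv", delimiter="\t")
        seed = meta.get("seed")
        return cls(
            R=R,
            L=L,
            W_true=w_true,
            W_lx=w_lx,
            noise_scale=float(meta.get("noise_scale", 1.0)),
            laser_variance=float(meta.get("laser_variance", 1.0)),
            confounder_trace=conf,
            source_ids=_ids("source_ids"),
            target_ids=_ids("target_ids"),
            unobserved_ids=_ids("unobserved_ids"),
            seed=None if seed in (None, "None") else int(seed),
            dt_ms=float(meta.get("dt_ms", 1.0)),
        )


def simulate_var1(
    W,
    n_steps: int,
    source_ids=None,
    W_lx=None,
    noise_scale: float = 1.0,
    laser_variance: float = 10.0,
    confounder=None,
    seed: int = 0,
    r0=None,
    burn_in: int = 0,
    allow_unstable: bool = False,
    check_stability: bool = True,
    laser: np.ndarray | None = None,
) -> SimRecord:
    """Iterate the VAR(1) model and return the recording.

    Parameters
    ----------
    W:
        Dynamics matrix (:class:`SignedConnectome` or array/sparse).
    source_ids:
        Neuron positions driven by one independent laser each; used to build
        ``W_lx`` (unit laser weight) when that matrix is not given directly.
    confounder:
        An object with ``sample(n, rng) -> array`` and ``targets`` (neuron
        positions receiving the common input), e.g.
        :class:`effectome.synthetic.ConfounderSpec`.
    laser:
        Optional pre-drawn (n_steps + burn_in) x n_l laser matrix; drawn as
        white Gaussian noise with variance ``laser_variance`` otherwise.
    check_stability:
        Refuse (``StabilityError``) when the spectral radius is >= 1 unless
        ``allow_unstable`` is set; skipping the check avoids an eigensolve
        when the caller already knows the radius.
    """
    if n_steps < 2:
        raise ConfigError("n_steps must be >= 2")
    conn = W if isinstance(W, SignedConnectome) else None
    Wm = conn.matrix if conn is not None else (
        W if sp.issparse(W) else np.atleast_2d(np.asarray(W, dtype=float))
    )
    d = Wm.shape[0]
    if sp.issparse(Wm):
        Wm = Wm.tocsr()

    if check_stability and not allow_unstable:
        rho = spectral_radius(Wm, seed=seed)
        if rho >= 1.0:
            raise StabilityError(
                f"dynamics matrix has spectral radius {rho:.4f} >= 1; pass "
                "allow_unstable=True for a finite-horizon run"
            )

    if W_lx is None:
        src = np.asarray(source_ids if source_ids is not None else [], dtype=int)
        W_lx_m = sp.csr_matrix(
            (np.ones(len(src)), (src, np.arange(len(src)))), shape=(d, max(len(src), 0))
        )
    else:
        W_lx_m = sp.csr_matrix(W_lx) if not sp.issparse(W_lx) else W_lx.tocsr()
        src = np.asarray(
            source_ids if source_ids is not None else np.unique(W_lx_m.nonzero()[0]),
            dtype=int,
        )
    n_l = W_lx_m.shape[1]

    rng = np.random.default_rng(seed)
    total = n_steps + burn_in
    if laser is None:
        L = np.sqrt(laser_variance) * rng.standard_normal((total, n_l))
    else:
        L = np.asarray(laser, dtype=float).reshape(total, n_l)

    conf_trace = None
    conf_targets = None
    if confounder is not None:
        conf_trace = np.asarray(confounder.sample(total, rng), dtype=float)
        conf_targets = np.asarray(tuple(confounder.targets), dtype=int)

    R = np.empty((n_steps, d))
    r = np.zeros(d) if r0 is None else np.asarray(r0, dtype=float).copy()
    noise_sd = float(np.sqrt(noise_scale))
    # dense laser-effect matrix for a cheap per-step GEMV (n_l is small)
    Wlx_dense = np.asarray(W_lx_m.todense()) if n_l else None
    # draw noise in chunks to amortize generator call overhead
    chunk = max(1, int(4_000_000 // max(d, 1)))
    noise_buf = np.empty((min(chunk, total), d)) if noise_sd else None
    buf_pos = chunk  # force refill on first use
    for t in range(total):
        r = Wm @ r
        if n_l:
            r += Wlx_dense @ L[t]
        if noise_sd:
            if buf_pos >= len(noise_buf):
                fill = noise_buf[: min(len(noise_buf), total - t)]
                rng.standard_normal(out=fill)
                if noise_sd != 1.0:
                    fill *= noise_sd
                buf_pos = 0
            r += noise_buf[buf_pos]
            buf_pos += 1
        if conf_trace is not None:
            r[conf_targets] += conf_trace[t]
        if t >= burn_in:
            R[t - burn_in] = r

    return SimRecord(
        R=R,
        L=L[burn_in:],
        W_true=conn
        if conn is not None
        else SignedConnectome(np.arange(d), sp.csr_matrix(Wm)),
        W_lx=W_lx_m,
        noise_scale=noise_scale,
        laser_variance=laser_variance,
        confounder_trace=None if conf_trace is None else conf_trace[burn_in:],
        source_ids=src,
        target_ids=np.arange(d),
        seed=seed,
    )


def propagate_eigenmode(lam: complex, v: np.ndarray, t: int) -> np.ndarray:
    """Closed-form eigenmode evolution: activity lambda^t v after t steps."""
    if t < 0:
        raise ConfigError("t must be a nonnegative integer")
    return (lam ** t) * np.asarray(v)


def multisynaptic_effect(W, r: np.ndarray, n: int) -> np.ndarray:
    """n-th order synaptic effect W^n r by repeated sparse application.

    n = 0 returns the input pattern itself; n = 1 the direct (monosynaptic)
    effects; larger n the effects routed through up to n synapses. The matrix
    power is never formed densely.
    """
    if n < 0:
        raise ConfigError("n must be a nonnegative integer")
    Wm = W.matrix if isinstance(W, SignedConnectome) else W
    out = np.asarray(r).astype(np.result_type(np.asarray(r).dtype, float))
    for _ in range(n):
        out = Wm @ out
    return np.asarray(out).ravel() if out.ndim > 1 else out
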