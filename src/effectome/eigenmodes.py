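"""Eigenmode decomposition of signed connectomes and eigencircuit extraction.

Under the linear model r_{t+1} = W r_t, initializing activity at an
eigenvector v_i of W makes the whole-brain pattern evolve in closed form as
r_t = lambda_i^t v_i: the eigenvalue magnitude sets how long the pattern
persists, and its angle from the positive real axis sets the speed of
rotational dynamics (0 deg = monotonic decay, 180 deg = sign flip every
step). Ranking modes by |lambda| therefore ranks candidate circuits by their
predicted total effect on the brain, and the small set of neurons carrying
most of a mode's squared loading forms its "eigencircuit".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import ArpackNoConvergence, eigs

from .connectome import SignedConnectome
from .exceptions import ConfigError, SolverError

__all__ = [
    "EigenmodeSet",
    "Eigencircuit",
    "top_modes",
    "spectrum_summary",
    "SpectrumSummary",
    "mode_correlations",
    "ModeCorrelations",
    "power_count",
    "extract_eigencircuit",
    "neuropil_localization",
]


@dataclass
class EigenmodeSet:
    """Top-k eigenpairs of a connectome, magnitude-sorted.

    ``eigenvalues[i]`` and ``eigenvectors[:, i]`` are aligned; vectors are
    unit norm with a deterministic phase (largest-magnitude entry made real
    positive). ``conjugate_partner[i]`` is the index of the complex-conjugate
    mode when both members of the pair are retained, else -1.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    conjugate_partner: np.ndarray
    residuals: np.ndarray
    neuron_index: np.ndarray
    matrix: sp.csr_matrix = field(repr=False)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def representatives(self) -> np.ndarray:
        """Indices of modes with Im(lambda) >= 0 (one per conjugate pair)."""
        scale = max(np.abs(self.eigenvalues).max(), 1e-300)
        im = self.eigenvalues.imag
        return np.flatnonzero((im >= 0) | (np.abs(im) <= 1e-12 * scale))

    def pair_multiplicity(self, i: int) -> int:
        return 2 if self.conjugate_partner[i] >= 0 else 1


def _sort_key(vals: np.ndarray) -> np.ndarray:
    """Deterministic mode order: |lambda| desc, then Re desc, then Im desc."""
    return np.lexsort((-vals.imag, -vals.real, -np.abs(vals)))


def _fix_phase(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for i in range(out.shape[1]):
        v = out[:, i]
        nrm = np.linalg.norm(v)
        if nrm == 0:
            continue
        v = v / nrm
        j = int(np.argmax(np.abs(v)))
        phase = v[j] / abs(v[j]) if v[j] != 0 else 1.0
        out[:, i] = v / phase
    return out


def top_modes(
    conn,
    k: int,
    tol: float = 1e-6,
    seed: int = 0,
    dense_cutoff: int = 300,
    maxiter: int | None = None,
) -> EigenmodeSet:
    """Largest-|lambda| eigenpairs of a (sparse) signed connectome.

    Uses a dense eigendecomposition for small matrices and seeded ARPACK
    (implicitly restarted Arnoldi, subspace max(2k + 10, 40)) otherwise.
    Residuals ||W v - lambda v|| are verified against ``tol * |lambda_1|``.
    """
    if isinstance(conn, SignedConnectome):
        matrix, index = conn.matrix, conn.neuron_index
    else:
        matrix = sp.csr_matrix(conn)
        index = np.arange(matrix.shape[0])
    d = matrix.shape[0]
    if not (1 <= k <= d):
        raise ConfigError(f"need 1 <= k <= D, got k={k}, D={d}")
    if not np.isfinite(matrix.data).all():
        raise ConfigError("matrix contains non-finite entries")

    if d <= dense_cutoff or k >= d - 1:
        vals, vecs = scipy.linalg.eig(matrix.toarray())
        order = _sort_key(vals)[:k]
        vals, vecs = vals[order], vecs[:, order]
    else:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(d)
        ncv = min(d, max(2 * k + 10, 40))
        try:
            vals, vecs = eigs(
                matrix.astype(float), k=k, which="LM", v0=v0, ncv=ncv, maxiter=maxiter
            )
        except ArpackNoConvergence as exc:
            got = len(exc.eigenvalues)
            raise SolverError(
                f"eigensolver converged only {got}/{k} modes; raise the "
                "subspace size (ncv) or the iteration limit"
            ) from exc
        order = _sort_key(vals)
        vals, vecs = vals[order], vecs[:, order]

    vecs = _fix_phase(vecs)

    # conjugate pairing: match lambda with conj(lambda) among retained modes
    partner = np.full(k, -1, dtype=int)
    used = np.zeros(k, dtype=bool)
    scale = max(np.abs(vals).max(), 1e-300)
    for i in range(k):
        if used[i] or abs(vals[i].imag) <= 1e-12 * scale:
            continue
        for j in range(i + 1, k):
            if used[j]:
                continue
            if abs(vals[j] - np.conj(vals[i])) <= 1e-8 * scale:
                partner[i], partner[j] = j, i
                used[i] = used[j] = True
                # enforce exact conjugacy of the pair's vectors
                vecs[:, j] = np.conj(vecs[:, i])
                vals = vals.copy()
                vals[j] = np.conj(vals[i])
                break

    resid = np.array(
        [np.linalg.norm(matrix @ vecs[:, i] - vals[i] * vecs[:, i]) for i in range(k)]
    )
    lam1 = np.abs(vals[0]) if k else 0.0
    if lam1 > 0 and (resid > tol * lam1).any():
        worst = float(resid.max())
        raise SolverError(
            f"eigenpair residuals up to {worst:.2e} exceed tol * |lambda_1| "
            f"= {tol * lam1:.2e}; raise the solver subspace or tolerance"
        )
    return EigenmodeSet(
        eigenvalues=vals,
        eigenvectors=vecs,
        conjugate_partner=partner,
        residuals=resid,
        neuron_index=np.asarray(index),
        matrix=matrix,
    )


@dataclass
class SpectrumSummary:
    """Per-mode spectrum table plus a power-law fit of |lambda| vs rank."""

    table: pd.DataFrame
    powerlaw_exponent: float
    powerlaw_intercept: float


def spectrum_summary(modes: EigenmodeSet) -> SpectrumSummary:
    """Magnitudes, complex-plane angles, and the rank power law.

    Angles are measured from the positive real axis and conjugate-folded
    into [0, 180] degrees: 0 deg is pure monotonic decay, 90 deg a quarter-
    turn rotation per step, 180 deg the fastest possible oscillation. The
    power law is an ordinary least-squares fit of log10|lambda_k| on
    log10 rank over all retained ranks.
    """
    if modes.n_modes < 2:
        raise ConfigError("need at least 2 modes")
    vals = modes.eigenvalues
    mags = np.abs(vals)
    angles = np.degrees(np.abs(np.angle(vals)))
    table = pd.DataFrame(
        {
            "rank": np.arange(1, modes.n_modes + 1),
            "real": vals.real,
            "imag": vals.imag,
            "magnitude": mags,
            "angle_deg": angles,
            "residual": modes.residuals,
        }
    )
    pos = mags > 0
    logr = np.log10(table["rank"].to_numpy()[pos])
    logm = np.log10(mags[pos])
    slope, intercept = np.polyfit(logr, logm, 1)
    return SpectrumSummary(
        table=table,
        powerlaw_exponent=float(slope),
        powerlaw_intercept=float(intercept),
    )


@dataclass
class ModeCorrelations:
    """Absolute correlations between split (real/imag) eigenvectors."""

    matrix: np.ndarray
    table: pd.DataFrame  # per split vector: mode rank, part, median/p99/max


def mode_correlations(
    modes: EigenmodeSet, drop_tol: float = 1e-8
) -> ModeCorrelations:
    """Pairwise |cosine| between real and imaginary eigenvector parts.

    Each conjugate-representative eigenvector is split into its real and
    imaginary parts (parts with norm below ``drop_tol`` times the vector
    norm are dropped, so real modes contribute one vector and complex pairs
    two); each part is normalized and the absolute pairwise inner product
    is returned, with per-part median, 99th-percentile and maximum
    correlation against all other parts.
    """
    if modes.n_modes < 2:
        raise ConfigError("need at least 2 modes")
    parts, ranks, labels = [], [], []
    for i in modes.representatives():
        v = modes.eigenvectors[:, i]
        nrm = np.linalg.norm(v)
        for name, comp in (("real", v.real), ("imag", v.imag)):
            cnorm = np.linalg.norm(comp)
            if cnorm > drop_tol * nrm:
                parts.append(comp / cnorm)
                ranks.append(i + 1)
                labels.append(name)
    A = np.column_stack(parts)
    C = np.abs(A.T @ A)
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, 0.0, 1.0)
    m = C.shape[0]
    rows = []
    for i in range(m):
        others = np.delete(C[i], i)
        rows.append(
            {
                "mode_rank": ranks[i],
                "part": labels[i],
                "median": float(np.median(others)) if m > 1 else np.nan,
                "p99": float(np.percentile(others, 99)) if m > 1 else np.nan,
                "max": float(others.max()) if m > 1 else np.nan,
            }
        )
    return ModeCorrelations(matrix=C, table=pd.DataFrame(rows))


def power_count(v: np.ndarray, fraction: float = 0.75) -> int:
    """Neurons needed to account for a fraction of a mode's loading power.

    Power is the squared modulus of the loading; the count is the smallest
    m such that the m largest loadings hold >= ``fraction`` of total power.
    Invariant to rescaling and to a global phase of v.
    """
    if not 0 < fraction < 1:
        raise ConfigError("fraction must be in (0, 1)")
    p = np.abs(np.asarray(v)) ** 2
    total = p.sum()
    if total == 0:
        raise ConfigError("zero vector has no loading power")
    csum = np.cumsum(np.sort(p)[::-1]) / total
    return int(np.searchsorted(csum, fraction - 1e-12) + 1)


@dataclass
class Eigencircuit:
    """The dominant neurons of one eigenmode and their weight submatrix."""

    mode_rank: int
    member_ids: np.ndarray
    member_positions: np.ndarray
    loading_shares: np.ndarray
    sub_matrix: np.ndarray
    cap_applied: bool
    eigenvalue: complex


def extract_eigencircuit(
    modes: EigenmodeSet,
    rank: int = 1,
    fraction: float = 0.75,
    max_members: int = 100,
) -> Eigencircuit:
    """Top-loading neurons of mode ``rank`` (1-based) up to a power fraction.

    Members are added in decreasing loading-power order until they hold
    ``fraction`` of the squared-modulus power, truncated at ``max_members``
    (``cap_applied`` set when truncation bites). The submatrix is the exact
    principal submatrix of the parent connectome over the members.
    """
    if not 1 <= rank <= modes.n_modes:
        raise ConfigError(f"rank must be in 1..{modes.n_modes}")
    v = modes.eigenvectors[:, rank - 1]
    p = np.abs(v) ** 2
    total = p.sum()
    if total == 0:
        raise ConfigError("zero eigenvector")
    order = np.argsort(-p, kind="stable")
    needed = power_count(v, fraction)
    cap_applied = needed > max_members
    m = min(needed, max_members)
    members = order[:m]
    sub = modes.matrix[members][:, members]
    return Eigencircuit(
        mode_rank=rank,
        member_ids=modes.neuron_index[members],
        member_positions=members,
        loading_shares=p[members] / total,
        sub_matrix=np.asarray(sub.todense(), dtype=float),
        cap_applied=cap_applied,
        eigenvalue=complex(modes.eigenvalues[rank - 1]),
    )


def neuropil_localization(
    circuit: Eigencircuit,
    synapse_table: pd.DataFrame,
    annotation: Mapping | Callable | pd.DataFrame,
) -> pd.DataFrame:
    """Fraction of within-circuit synapses per anatomical region.

    ``annotation`` maps a (pre_id, post_id) connection to a region name: a
    dict keyed by those tuples, a callable, or a DataFrame with columns
    pre_id / post_id / region. Connections without a region are aggregated
    under "unannotated"; fractions sum to 1.
    """
    members = set(np.asarray(circuit.member_ids).tolist())
    if not members:
        raise ConfigError("empty circuit")
    tab = synapse_table[
        synapse_table["pre_id"].isin(members) & synapse_table["post_id"].isin(members)
    ]
    if len(tab) == 0:
        raise ConfigError("no synapses between circuit members in the table")
    if isinstance(annotation, pd.DataFrame):
        lookup = {
            (r.pre_id, r.post_id): r.region
            for r in annotation.itertuples(index=False)
        }
        get = lookup.get
    elif callable(annotation):
        get = lambda key: annotation(*key)  # noqa: E731
    else:
        get = annotation.get
    regions = [
        get((pre, post)) or "unannotated"
        for pre, post in zip(tab["pre_id"], tab["post_id"])
    ]
    out = (
        pd.DataFrame({"region": regions, "count": tab["count"].to_numpy()})
        .groupby("region", sort=False)["count"]
        .sum()
        .reset_index()
        .sort_values("count", ascending=False, ignore_index=True)
    )
    out["fraction"] = out["count"] / out["count"].sum()
    return out
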