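"""Signed synaptic-count matrices built from connectome synapse tables.

The central object is :class:`SignedConnectome`: a sparse D x D matrix whose
entry (i, j) is the aggregate synapse count from presynaptic neuron j to
postsynaptic neuron i, multiplied by the sign implied by neuron j's
neurotransmitter (rows = postsynaptic, columns = presynaptic, so the linear
model reads ``r_{t+1} = W r_t``).

Construction follows the convention used for the FlyWire whole-brain
reconstruction: acetylcholine and dopamine are treated as excitatory (+1);
GABA, serotonin, glutamate and octopamine as inhibitory (-1); connections
with an aggregate synapse count below 5 are discarded as potentially spurious
(proofreading does not extend below that count).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from scipy.sparse.linalg import ArpackNoConvergence, eigs

from .exceptions import ConfigError, DataError, IntegrityError

logger = logging.getLogger(__name__)

#: Canonical column names of a synapse table.
SYNAPSE_COLUMNS = ("pre_id", "post_id", "count", "nt_type")

#: Column names used by the FlyWire Codex connectivity download.
CODEX_DIALECT: Mapping[str, str] = {
    "pre_id": "pre_root_id",
    "post_id": "post_root_id",
    "count": "syn_count",
    "nt_type": "nt_type",
}

#: Neurotransmitter -> weight sign. ACh and dopamine excite; GABA, serotonin,
#: glutamate and octopamine inhibit (glutamate acts on inhibitory GluCl
#: receptors in the fly).
DEFAULT_SIGN_MAP: Mapping[str, int] = {
    "ACH": +1,
    "DA": +1,
    "GABA": -1,
    "SER": -1,
    "GLUT": -1,
    "OCT": -1,
}

#: Default aggregate synapse-count threshold.
DEFAULT_THRESHOLD = 5


@dataclass
class SignedConnectome:
    """A sparse signed synaptic-count matrix with its neuron index.

    Attributes
    ----------
    neuron_index:
        Ordered array of D neuron identifiers; position in this array is the
        row/column position in ``matrix``.
    matrix:
        Sparse D x D matrix, entry (i, j) = signed aggregate synapse count
        from presynaptic neuron j to postsynaptic neuron i.
    scale_factor:
        Cumulative multiplicative rescaling applied to the raw signed counts
        (1.0 when unscaled).
    threshold:
        The synapse-count threshold used at construction, if known.
    """

    neuron_index: np.ndarray
    matrix: sp.csr_matrix
    scale_factor: float = 1.0
    threshold: int | None = None
    _positions: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.neuron_index = np.asarray(self.neuron_index)
        if not sp.issparse(self.matrix):
            self.matrix = sp.csr_matrix(np.asarray(self.matrix, dtype=float))
        else:
            self.matrix = self.matrix.tocsr().astype(float)
        d = len(self.neuron_index)
        if self.matrix.shape != (d, d):
            raise IntegrityError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{d} neuron identifiers"
            )

    @property
    def d(self) -> int:
        """Number of neurons."""
        return len(self.neuron_index)

    @property
    def nnz(self) -> int:
        return self.matrix.nnz

    def positions(self, ids: Sequence) -> np.ndarray:
        """Row/column positions of the given neuron identifiers."""
        if self._positions is None:
            object.__setattr__(
                self,
                "_positions",
                {nid: i for i, nid in enumerate(self.neuron_index.tolist())},
            )
        try:
            return np.array([self._positions[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"neuron id {exc.args[0]} not in connectome") from exc

    def with_matrix(self, matrix, **kw) -> "SignedConnectome":
        return replace(self, matrix=matrix, _positions=None, **kw)


def load_synapse_table(
    path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a delimited synapse table into canonical columns.

    Parameters
    ----------
    path:
        Delimited text file with one row per (pre, post) connection or
        synapse group.
    dialect:
        Mapping from canonical names (``pre_id``, ``post_id``, ``count``,
        ``nt_type``) to the column names used in the file. Defaults to the
        FlyWire Codex names.
    """
    dialect = dict(CODEX_DIALECT if dialect is None else dialect)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    missing = [v for v in dialect.values() if v not in raw.columns]
    if missing:
        raise ConfigError(
            f"synapse table {path} is missing mapped column(s): {missing}; "
            f"present: {list(raw.columns)}"
        )
    table = pd.DataFrame(
        {canon: raw[src] for canon, src in dialect.items()}
    )
    counts = pd.to_numeric(table["count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round())
    if bad.any():
        # +2: one for the header line, one for 1-based numbering.
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise DataError(
            f"unparseable synapse count {table['count'].iloc[line - 2]!r} "
            f"on line {line} of {path}"
        )
    table["count"] = counts.astype(np.int64)
    if (table["count"] < 1).any():
        line = int(np.flatnonzero((table["count"] < 1).to_numpy())[0]) + 2
        raise DataError(f"non-positive synapse count on line {line} of {path}")
    for col in ("pre_id", "post_id"):
        table[col] = _maybe_numeric(table[col])
    table["nt_type"] = table["nt_type"].str.strip().str.upper()
    return table[list(SYNAPSE_COLUMNS)]


def _maybe_numeric(series: pd.Series) -> pd.Series:
    """Convert to int64 identifiers when possible, else keep strings."""
    try:
        return series.astype(np.int64)
    except (ValueError, TypeError):
        return series


def _presynaptic_signs(
    table: pd.DataFrame,
    sign_map: Mapping[str, int],
    coerce_unknown: bool,
    unknown_sign: int,
) -> pd.Series:
    """Per-presynaptic-neuron sign (count-weighted majority of nt labels)."""
    known = table["nt_type"].isin(sign_map)
    if not known.all():
        labels = sorted(table.loc[~known, "nt_type"].unique())
        if not coerce_unknown:
            raise ConfigError(
                f"neurotransmitter label(s) {labels} not covered by the sign "
                "map; pass coerce_unknown=True to map them to a default sign"
            )
        logger.warning(
            "coercing unknown neurotransmitter label(s) %s to sign %+d",
            labels,
            unknown_sign,
        )
    signs = table["nt_type"].map(sign_map).fillna(unknown_sign).astype(int)
    # one sign per presynaptic neuron (Dale's law): count-weighted majority
    signed_count = signs * table["count"]
    vote = signed_count.groupby(table["pre_id"]).sum()
    per_pre = np.where(vote >= 0, 1, -1)
    return pd.Series(per_pre, index=vote.index)


def build_signed_matrix(
    table: pd.DataFrame,
    threshold: int = DEFAULT_THRESHOLD,
    sign_map: Mapping[str, int] | None = None,
    universe: Sequence | None = None,
    threshold_op: str = ">=",
    coerce_unknown: bool = False,
    unknown_sign: int = -1,
) -> SignedConnectome:
    """Aggregate, threshold and sign a synapse table.

    Duplicate (pre, post) rows are summed *before* thresholding; aggregated
    connections whose count fails ``count {threshold_op} threshold`` are
    dropped; each surviving entry is ``sign(pre) * count`` where the sign is
    shared by all outgoing connections of a presynaptic neuron.

    ``universe`` optionally lists neuron identifiers to retain in the index
    even if none of their connections survive.
    """
    if threshold < 1:
        raise ConfigError(f"threshold must be >= 1, got {threshold}")
    if threshold_op not in (">=", ">"):
        raise ConfigError(f"threshold_op must be '>=' or '>', got {threshold_op!r}")
    sign_map = dict(DEFAULT_SIGN_MAP if sign_map is None else sign_map)

    if len(table) == 0:
        ids = np.asarray(sorted(universe)) if universe is not None else np.array([], dtype=np.int64)
        return SignedConnectome(
            neuron_index=ids,
            matrix=sp.csr_matrix((len(ids), len(ids))),
            threshold=threshold,
        )

    pre_signs = _presynaptic_signs(table, sign_map, coerce_unknown, unknown_sign)
    agg = (
        table.groupby(["pre_id", "post_id"], sort=False)["count"]
        .sum()
        .reset_index()
    )
    keep = agg["count"] >= threshold if threshold_op == ">=" else agg["count"] > threshold
    agg = agg[keep]

    ids = set(agg["pre_id"]) | set(agg["post_id"])
    if universe is not None:
        ids |= set(universe)
    neuron_index = np.asarray(sorted(ids))
    pos = {nid: i for i, nid in enumerate(neuron_index.tolist())}

    rows = agg["post_id"].map(pos).to_numpy(dtype=int)
    cols = agg["pre_id"].map(pos).to_numpy(dtype=int)
    vals = (agg["count"] * agg["pre_id"].map(pre_signs)).to_numpy(dtype=float)
    d = len(neuron_index)
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(d, d))
    return SignedConnectome(neuron_index=neuron_index, matrix=matrix, threshold=threshold)


def prune_isolated(conn: SignedConnectome) -> SignedConnectome:
    """Drop neurons whose row and column are both entirely zero."""
    m = conn.matrix
    in_deg = np.asarray((m != 0).sum(axis=1)).ravel()
    out_deg = np.asarray((m != 0).sum(axis=0)).ravel()
    keep = np.flatnonzero((in_deg + out_deg) > 0)
    if len(keep) == conn.d:
        return conn
    sub = m[keep][:, keep]
    return SignedConnectome(
        neuron_index=conn.neuron_index[keep],
        matrix=sub,
        scale_factor=conn.scale_factor,
        threshold=conn.threshold,
    )


def spectral_radius(matrix, seed: int = 0, dense_cutoff: int = 400) -> float:
    """Largest eigenvalue magnitude of a (sparse) matrix.

    Uses a dense solve below ``dense_cutoff`` and seeded ARPACK above it,
    with a dense fallback on non-convergence for moderate sizes.
    """
    if sp.issparse(matrix):
        d = matrix.shape[0]
        if matrix.nnz == 0:
            return 0.0
        if d <= dense_cutoff:
            return float(np.abs(np.linalg.eigvals(matrix.toarray())).max())
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(d)
        try:
            vals = eigs(
                matrix.astype(float),
                k=1,
                which="LM",
                v0=v0,
                return_eigenvectors=False,
                maxiter=5000,
            )
            return float(np.abs(vals).max())
        except ArpackNoConvergence as exc:
            if len(exc.eigenvalues):
                return float(np.abs(exc.eigenvalues).max())
            raise
    arr = np.asarray(matrix, dtype=float)
    if arr.size == 0 or not arr.any():
        return 0.0
    return float(np.abs(np.linalg.eigvals(arr)).max())


def scale_spectral(
    conn: SignedConnectome,
    target_radius: float = 1.0,
    seed: int = 0,
) -> SignedConnectome:
    """Rescale the matrix to the requested spectral radius.

    Multiplies every entry by ``target_radius / rho(W)``; eigenvectors are
    unchanged and every eigenvalue is multiplied by the same factor. An
    all-zero matrix is returned unchanged with a warning (its radius is
    undefined).
    """
    if target_radius <= 0:
        raise ConfigError("target_radius must be positive")
    rho = spectral_radius(conn.matrix, seed=seed)
    if rho == 0.0:
        warnings.warn(
            "spectral radius is undefined for an all-zero matrix; returning "
            "the connectome unchanged",
            stacklevel=2,
        )
        return conn
    factor = target_radius / rho
    return conn.with_matrix(
        conn.matrix * factor, scale_factor=conn.scale_factor * factor
    )


def save_matrix(conn: SignedConnectome, path) -> None:
    """Write MatrixMarket coordinate file plus a plain-text sidecar index.

    The sidecar (``<path>.ids``) holds one neuron id per line in matrix
    order, preceded by comment lines recording scale_factor and threshold.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(
        str(path),
        sp.coo_matrix(conn.matrix),
        comment="signed synaptic-count matrix; rows=postsynaptic, cols=presynaptic",
    )
    sidecar = path.with_suffix(path.suffix + ".ids")
    with open(sidecar, "w") as fh:
        fh.write("# neuron index for matrix; one id per line, file order = matrix order\n")
        fh.write(f"# scale_factor = {conn.scale_factor!r}\n")
        fh.write(f"# threshold = {conn.threshold!r}\n")
        for nid in conn.neuron_index:
            fh.write(f"{nid}\n")


def load_matrix(path) -> SignedConnectome:
    """Load a matrix + sidecar pair written by :func:`save_matrix`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".ids")
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar.exists():
        raise FileNotFoundError(sidecar)
    matrix = sp.csr_matrix(mmread(str(path)))
    scale_factor, threshold = 1.0, None
    ids = []
    with open(sidecar) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "scale_factor" in line:
                    scale_factor = float(line.split("=", 1)[1].strip())
                elif "threshold" in line:
                    raw = line.split("=", 1)[1].strip()
                    threshold = None if raw == "None" else int(raw)
                continue
            ids.append(line)
    index = _maybe_numeric(pd.Series(ids)).to_numpy()
    if len(index) != matrix.shape[0]:
        raise IntegrityError(
            f"sidecar {sidecar} lists {len(index)} ids but matrix is "
            f"{matrix.shape[0]}x{matrix.shape[1]}"
        )
    return SignedConnectome(
        neuron_index=index,
        matrix=matrix,
        scale_factor=scale_factor,
        threshold=threshold,
    )
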