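"""Pairwise identity and Kimura two-parameter (K2P) distances.

All comparisons use pairwise deletion: for each pair of rows, only
columns where *both* residues are unambiguous A/C/G/T are compared;
gaps and IUPAC ambiguity codes are excluded per pair rather than per
column across the whole alignment.

The K2P model corrects the observed transition proportion P (A<->G,
C<->T) and transversion proportion Q for multiple substitutions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

When a log argument is non-positive the pair is saturated and the
distance is undefined; callers may supply a cap instead of an error.

Rank thresholds downstream are applied to raw identity; K2P distances
are computed alongside so both views of divergence are available and
the thresholding convention is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .core import (
    Alignment,
    NonOverlappingPairError,
    SaturationError,
    ValidationError,
    encode_residues,
)

Metric = Literal["identity", "k2p"]

# Purine codes 0 (A) and 2 (G); pyrimidines 1 (C) and 3 (T).  A
# substitution within a set is a transition, across is a transversion.
_PURINES = (0, 2)


@dataclass(frozen=True)
class K2PComponents:
    """Observed substitution proportions and the corrected distance."""

    P: float  # transition proportion over compared sites
    Q: float  # transversion proportion over compared sites
    d: float  # corrected distance, substitutions per site
    n_sites: int  # number of compared sites


def _encoded_pair(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValidationError("rows must have equal length")
    return encode_residues(a), encode_residues(b)


def compared_sites(a: str, b: str) -> list[int]:
    """Column indices where both rows hold an unambiguous A/C/G/T."""
    ca, cb = _encoded_pair(a, b)
    return np.nonzero((ca < 4) & (cb < 4))[0].tolist()


def pairwise_identity(a: str, b: str) -> float:
    """Proportion of matching residues over compared sites."""
    ca, cb = _encoded_pair(a, b)
    both = (ca < 4) & (cb < 4)
    n = int(np.count_nonzero(both))
    if n == 0:
        raise NonOverlappingPairError("no compared sites between rows")
    matches = int(np.count_nonzero(both & (ca == cb)))
    return matches / n


def k2p_from_proportions(
    P: float, Q: float, n_sites: int, max_distance: float | None = None
) -> K2PComponents:
    """Evaluate the K2P closed form for given substitution proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        if max_distance is not None:
            return K2PComponents(P=P, Q=Q, d=max_distance, n_sites=n_sites)
        raise SaturationError(
            f"K2P distance undefined for P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PComponents(P=P, Q=Q, d=d, n_sites=n_sites)


def k2p_distance(a: str, b: str, max_distance: float | None = None) -> K2PComponents:
    """K2P components for one pair of aligned rows (pairwise deletion)."""
    ca, cb = _encoded_pair(a, b)
    both = (ca < 4) & (cb < 4)
    n = int(np.count_nonzero(both))
    if n == 0:
        raise NonOverlappingPairError("no compared sites between rows")
    diff = both & (ca != cb)
    ts = int(
        np.count_nonzero(diff & ((ca % 2) == (cb % 2)))
    )  # same parity code = both purine or both pyrimidine
    tv = int(np.count_nonzero(diff)) - ts
    return k2p_from_proportions(ts / n, tv / n, n, max_distance=max_distance)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix over an ordered id list.

    ``metric`` is ``"identity"`` (unit diagonal, values in [0, 1]) or
    ``"k2p"`` (zero diagonal, substitutions per site).
    """

    ids: list[str]
    values: np.ndarray
    metric: Metric

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("matrix must be symmetric")
        if self.metric not in ("identity", "k2p"):
            raise ValidationError(f"unknown metric {self.metric!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, id1: str, id2: str) -> float:
        return float(self.values[self.ids.index(id1), self.ids.index(id2)])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path: str | Path, metric: Metric) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), metric)


def _pair_counts(aln: Alignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair compared-site, match, and transition counts via matmuls.

    One-hot products count, for every pair of rows, the number of
    columns with a given (base, base) combination — O(n^2 * L) work in
    BLAS rather than a Python double loop.
    """
    X = aln.encoded()
    onehot = [(X == b).astype(np.float32) for b in range(4)]
    valid = (X < 4).astype(np.float32)
    # float32 matmuls are exact for these integer counts (< 2^24);
    # promote to float64 before any division downstream
    compared = (valid @ valid.T).astype(np.float64)
    matches = sum(h @ h.T for h in onehot).astype(np.float64)
    ts = onehot[0] @ onehot[2].T + onehot[2] @ onehot[0].T  # A<->G
    ts += onehot[1] @ onehot[3].T + onehot[3] @ onehot[1].T  # C<->T
    return compared, matches, ts.astype(np.float64)


def _check_overlap(aln: Alignment, compared: np.ndarray) -> None:
    n = len(aln)
    bad = np.argwhere((compared == 0) & ~np.eye(n, dtype=bool))
    if bad.size:
        i, j = bad[0]
        raise NonOverlappingPairError(
            f"no compared sites between {aln.ids[i]} and {aln.ids[j]}"
        )


def identity_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs identity with pairwise deletion."""
    if len(aln) < 2:
        raise ValidationError("need at least two rows")
    compared, matches, _ = _pair_counts(aln)
    _check_overlap(aln, compared)
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(compared > 0, matches / compared, 1.0)
    np.fill_diagonal(ident, 1.0)
    ident = (ident + ident.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(list(aln.ids), ident, "identity")


def k2p_matrix(aln: Alignment, max_distance: float | None = None) -> DistanceMatrix:
    """All-pairs K2P distance with pairwise deletion."""
    if len(aln) < 2:
        raise ValidationError("need at least two rows")
    compared, matches, ts = _pair_counts(aln)
    _check_overlap(aln, compared)
    safe = np.where(compared > 0, compared, 1.0)
    P = ts / safe
    Q = (compared - matches - ts) / safe
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    n = len(aln)
    offdiag = ~np.eye(n, dtype=bool)
    saturated = ((w1 <= 0.0) | (w2 <= 0.0)) & offdiag
    if saturated.any():
        if max_distance is None:
            i, j = np.argwhere(saturated)[0]
            raise SaturationError(
                f"K2P saturated between {aln.ids[i]} and {aln.ids[j]}"
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = -0.5 * np.log(np.where((w1 > 0) & (w2 > 0), w1 * np.sqrt(np.abs(w2)), 1.0))
    if max_distance is not None:
        d = np.where(saturated, max_distance, d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(aln.ids), d, "k2p")


def distance_matrix(
    aln: Alignment, metric: Metric, max_distance: float | None = None
) -> DistanceMatrix:
    """Dispatch to :func:`identity_matrix` or :func:`k2p_matrix`."""
    if metric == "identity":
        return identity_matrix(aln)
    if metric == "k2p":
        return k2p_matrix(aln, max_distance=max_distance)
    raise ValidationError(f"unknown metric {metric!r}")


def long_format(
    ident: DistanceMatrix, k2p: DistanceMatrix | None = None
) -> pd.DataFrame:
    """Long-format table (id1, id2, identity[, k2p_d]) over unordered pairs."""
    if k2p is not None and k2p.ids != ident.ids:
        raise ValidationError("identity and k2p matrices must share ids")
    rows = []
    n = len(ident.ids)
    for i in range(n):
        for j in range(i + 1, n):
            row = {
                "id1": ident.ids[i],
                "id2": ident.ids[j],
                "identity": ident.values[i, j],
            }
            if k2p is not None:
                row["k2p_d"] = k2p.values[i, j]
            rows.append(row)
    return pd.DataFrame(rows)
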