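"""Fixed-length moment-based feature vectors for nucleotide sequences.

A variable-length sequence is made comparable across lengths by:

1. integer-encoding it (A=1, C=2, G=3, T=4, N=0) into the smallest square
   matrix that holds it (row-major, zero-padded) — the *sequence matrix*;
2. summarizing that matrix, and two 4x4 position-relative incidence matrices
   (PRIM on the forward strand, RPRIM on the reverse), by raw, central and
   discrete-Hahn moments of total order <= 3 (10 moments each);
3. appending per-nucleotide frequency and accumulated-position vectors
   (FV, AAPIV, RAAPIV).

The result is a 102-dimensional descriptor with a fixed, documented layout:
FV(4) + AAPIV(4) + RAAPIV(4) + 30 sequence-matrix moments + 30 PRIM moments
+ 30 RPRIM moments.  Zero encodes both padding and the ambiguity code N, so
neither contributes to any weighted sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import binom, factorial, poch
from sklearn.base import BaseEstimator, TransformerMixin

from .datagen import GeneSequence
from .errors import ParameterError, SequenceValidationError

#: integer codes for the DNA alphabet; N (and padding) carry no weight
NUC_CODE = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 0}

#: fixed (row-order, column-order) exponent pairs, total order <= 3
MOMENT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (0, 2),
    (2, 0), (1, 2), (2, 1), (0, 3), (3, 0),
)

_MAX_ORDER = 3
_NUCS = "ACGT"


@dataclass(frozen=True)
class HahnParams:
    """Shape parameters (a, b) of the discrete Hahn polynomials.

    Both default to 0, where the weight function is uniform and the
    normalization reduces to a plain Euclidean norm.
    """

    a: int = 0
    b: int = 0

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ParameterError(f"Hahn parameters must be >= 0, got {self}")


@dataclass(frozen=True)
class SequenceMatrix:
    """A sequence integer-encoded into a zero-padded square grid."""

    values: np.ndarray
    side: int
    original_length: int


@dataclass(frozen=True)
class IncidenceMatrix:
    """4x4 position-relative incidence matrix (rows/cols ordered A,C,G,T)."""

    values: np.ndarray
    kind: str  # "PRIM" | "RPRIM"


@dataclass(frozen=True)
class PositionVector:
    """Accumulated 1-based occurrence positions per nucleotide (A,C,G,T)."""

    values: np.ndarray
    kind: str  # "AAPIV" | "RAAPIV"


@dataclass(frozen=True)
class FrequencyVector:
    """Counts of A, C, G, T (N excluded)."""

    values: np.ndarray


@dataclass(frozen=True)
class MomentSet:
    """Raw, central and Hahn moments of one grid, in MOMENT_ORDERS order."""

    raw: np.ndarray
    central: np.ndarray
    hahn: np.ndarray

    def concat(self) -> np.ndarray:
        return np.concatenate([self.raw, self.central, self.hahn])


def _residues(seq: GeneSequence | str) -> str:
    res = seq.residues if isinstance(seq, GeneSequence) else seq
    if not res:
        raise SequenceValidationError("empty sequence")
    return res


# ---------------------------------------------------------------------------
# 2-D encoding


def encode_sequence(seq: GeneSequence | str) -> SequenceMatrix:
    """Encode a sequence into the smallest square grid that holds it.

    A=1, C=2, G=3, T=4, N=0; row-major fill; trailing zero padding up to
    side**2 where side = ceil(sqrt(L)).
    """
    res = _residues(seq)
    length = len(res)
    side = math.isqrt(length)
    if side * side < length:
        side += 1
    flat = np.zeros(side * side, dtype=np.int64)
    flat[:length] = [NUC_CODE[c] for c in res]
    return SequenceMatrix(flat.reshape(side, side), side, length)


def _as_grid(m) -> np.ndarray:
    if isinstance(m, SequenceMatrix) or isinstance(m, IncidenceMatrix):
        grid = np.asarray(m.values, dtype=float)
    else:
        grid = np.asarray(m, dtype=float)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ParameterError(f"expected a square grid, got shape {grid.shape}")
    return grid


# ---------------------------------------------------------------------------
# Raw and central moments


def raw_moments(m) -> np.ndarray:
    """Raw moments R_xy = sum_g sum_h g^x h^y d_gh over 1-based indices.

    g indexes rows, h columns; the ten (x, y) pairs follow MOMENT_ORDERS.
    """
    grid = _as_grid(m)
    n = grid.shape[0]
    idx = np.arange(1, n + 1, dtype=float)
    pows = np.stack([idx**k for k in range(_MAX_ORDER + 1)])  # (4, n)
    out = np.empty(len(MOMENT_ORDERS))
    for i, (x, y) in enumerate(MOMENT_ORDERS):
        out[i] = pows[x] @ grid @ pows[y]
    return out


def central_moments(m) -> np.ndarray:
    """Central moments about the intensity centroid.

    C_ab = sum_g sum_h (g - gbar)^a (h - hbar)^b d_gh with
    gbar = R10/R00, hbar = R01/R00.  A zero-mass grid has no centroid; the
    geometric center is used and a warning emitted.
    """
    grid = _as_grid(m)
    n = grid.shape[0]
    total = grid.sum()
    idx = np.arange(1, n + 1, dtype=float)
    if total > 0:
        gbar = (idx @ grid.sum(axis=1)) / total
        hbar = (idx @ grid.sum(axis=0)) / total
    else:
        warnings.warn(
            "zero-mass grid: centroid undefined, using geometric center",
            stacklevel=2,
        )
        gbar = hbar = (n + 1) / 2.0
    dg = idx - gbar
    dh = idx - hbar
    gp = np.stack([dg**k for k in range(_MAX_ORDER + 1)])
    hp = np.stack([dh**k for k in range(_MAX_ORDER + 1)])
    out = np.empty(len(MOMENT_ORDERS))
    for i, (a, b) in enumerate(MOMENT_ORDERS):
        out[i] = gp[a] @ grid @ hp[b]
    return out


# ---------------------------------------------------------------------------
# Hahn moments


def _hahn_poly_value(m: int, x: int, G: int, a: int, b: int) -> float:
    """Un-normalized Hahn polynomial value by its finite Pochhammer sum.

    h_m^{(a,b)}(x; G) = (G+b-1)_m (G-1)_m *
        sum_z (-1)^z [(-m)_z (-x)_z (2G+a+b-m-1)_z] /
              [(G+b-1)_z (G-1)_z z!]

    The (-m)_z factor truncates the sum at z = m.
    """
    pref = poch(G + b - 1, m) * poch(G - 1, m)
    acc = 0.0
    for z in range(m + 1):
        num = poch(-m, z) * poch(-x, z) * poch(2 * G + a + b - m - 1, z)
        den = poch(G + b - 1, z) * poch(G - 1, z) * factorial(z)
        acc += (-1) ** z * num / den
    return float(pref * acc)


def hahn_polynomial(m: int, x: int, G: int, params: HahnParams = HahnParams()) -> float:
    """Evaluate the order-m Hahn polynomial at integer x on support [0, G-1]."""
    if not 0 <= m <= G - 1:
        raise ParameterError(f"order m={m} outside [0, {G - 1}]")
    if not 0 <= x <= G - 1:
        raise ParameterError(f"x={x} outside [0, {G - 1}]")
    return _hahn_poly_value(m, x, G, params.a, params.b)


def _hahn_weight(G: int, a: int, b: int) -> np.ndarray:
    """Hahn weight function rho(x) on 0..G-1 (uniform when a=b=0)."""
    x = np.arange(G)
    return binom(a + x, x) * binom(b + G - 1 - x, G - 1 - x)


def _normalized_hahn(G: int, params: HahnParams, max_order: int) -> np.ndarray:
    """Matrix of weighted-normalized Hahn polynomial values, (order, x).

    Row m holds h_m(x) * sqrt(rho(x)) / sqrt(sum_x rho(x) h_m(x)^2), the
    standard square-norm weighting; with a=b=0 this is division by the
    Euclidean norm.  Orders above G-1 (needed only for 2x2 and 3x3 grids)
    use the same finite sum, which remains well defined.
    """
    rho = _hahn_weight(G, params.a, params.b)
    H = np.empty((max_order + 1, G))
    for m in range(max_order + 1):
        for x in range(G):
            H[m, x] = _hahn_poly_value(m, x, G, params.a, params.b)
        norm2 = float(rho @ (H[m] ** 2))
        if norm2 > 0:
            H[m] = H[m] * np.sqrt(rho) / math.sqrt(norm2)
        else:  # degenerate high order on a tiny support
            H[m] = 0.0
    return H


def hahn_moments(m, params: HahnParams = HahnParams()) -> np.ndarray:
    """Hahn moments A_pq = sum_i sum_j d_ij h~_p(i) h~_q(j) (0-based i, j).

    i indexes rows (paired with order p), j columns (order q); the ten
    (p, q) pairs follow MOMENT_ORDERS.  Grids of side < 2 are zero-padded to
    2x2 with a warning.
    """
    grid = _as_grid(m)
    if grid.shape[0] < 2:
        warnings.warn("grid side < 2: padding to 2x2 with zeros", stacklevel=2)
        padded = np.zeros((2, 2))
        padded[: grid.shape[0], : grid.shape[1]] = grid
        grid = padded
    G = grid.shape[0]
    H = _normalized_hahn(G, params, _MAX_ORDER)
    proj = H @ grid @ H.T  # (p, q) -> A_pq
    return np.array([proj[p, q] for p, q in MOMENT_ORDERS])


def moment_set(m, params: HahnParams = HahnParams()) -> MomentSet:
    """All 30 moments (raw, central, Hahn) of one square grid."""
    return MomentSet(raw_moments(m), central_moments(m), hahn_moments(m, params))


# ---------------------------------------------------------------------------
# Incidence matrices and position/frequency vectors


def compute_prim(seq: GeneSequence | str) -> IncidenceMatrix:
    """Position-relative incidence matrix on the forward strand.

    Entry (i -> j) accumulates, over every occurrence of nucleotide j at a
    1-based position k strictly after the first occurrence f_i of nucleotide
    i, the positional offset k - f_i.  Rows of nucleotides absent from the
    sequence are zero.  N is ignored entirely.
    """
    res = _residues(seq)
    first: dict[str, int] = {}
    positions: dict[str, list[int]] = {c: [] for c in _NUCS}
    for k, c in enumerate(res, start=1):
        if c == "N":
            continue
        positions[c].append(k)
        first.setdefault(c, k)
    values = np.zeros((4, 4))
    for i, ci in enumerate(_NUCS):
        fi = first.get(ci)
        if fi is None:
            continue
        for j, cj in enumerate(_NUCS):
            values[i, j] = sum(k - fi for k in positions[cj] if k > fi)
    return IncidenceMatrix(values, "PRIM")


def compute_rprim(seq: GeneSequence | str) -> IncidenceMatrix:
    """PRIM of the reversed residue string."""
    return IncidenceMatrix(compute_prim(_residues(seq)[::-1]).values, "RPRIM")


def compute_aapiv(seq: GeneSequence | str) -> PositionVector:
    """Accumulated 1-based occurrence positions of A, C, G, T."""
    res = _residues(seq)
    values = np.zeros(4, dtype=np.int64)
    for k, c in enumerate(res, start=1):
        if c != "N":
            values[_NUCS.index(c)] += k
    return PositionVector(values, "AAPIV")


def compute_raapiv(seq: GeneSequence | str) -> PositionVector:
    """AAPIV of the reversed residue string."""
    return PositionVector(compute_aapiv(_residues(seq)[::-1]).values, "RAAPIV")


def frequency_vector(seq: GeneSequence | str) -> FrequencyVector:
    """Counts of A, C, G, T (N contributes nowhere)."""
    res = _residues(seq)
    values = np.array([res.count(c) for c in _NUCS], dtype=np.int64)
    return FrequencyVector(values)


# ---------------------------------------------------------------------------
# The assembled feature vector


def feature_layout() -> list[str]:
    """Names of the 102 feature positions, in vector order."""
    names = [f"FV_{c}" for c in _NUCS]
    names += [f"AAPIV_{c}" for c in _NUCS]
    names += [f"RAAPIV_{c}" for c in _NUCS]
    for block in ("SEQ", "PRIM", "RPRIM"):
        for kind in ("raw", "central", "hahn"):
            names += [f"{block}_{kind}_{p}{q}" for p, q in MOMENT_ORDERS]
    return names


FEATURE_LENGTH = 102


def extract_features(
    seq: GeneSequence | str, params: HahnParams = HahnParams()
) -> np.ndarray:
    """The 102-dimensional descriptor of one sequence (see feature_layout)."""
    res = _residues(seq)
    parts = [
        frequency_vector(res).values.astype(float),
        compute_aapiv(res).values.astype(float),
        compute_raapiv(res).values.astype(float),
        moment_set(encode_sequence(res), params).concat(),
        moment_set(compute_prim(res), params).concat(),
        moment_set(compute_rprim(res), params).concat(),
    ]
    vec = np.concatenate(parts)
    assert vec.shape == (FEATURE_LENGTH,)
    return vec


class MomentFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn transformer: sequences -> (n_samples, 102) feature matrix.

    Stateless (fit only validates); accepts GeneSequence objects or plain
    residue strings.

    Parameters
    ----------
    hahn_a, hahn_b : int, default 0
        Shape parameters of the Hahn polynomials.
    """

    def __init__(self, hahn_a: int = 0, hahn_b: int = 0):
        self.hahn_a = hahn_a
        self.hahn_b = hahn_b

    def _params(self) -> HahnParams:
        return HahnParams(self.hahn_a, self.hahn_b)

    def fit(self, X: Sequence[GeneSequence | str], y=None):
        self._params()  # validate
        self.n_features_out_ = FEATURE_LENGTH
        return self

    def transform(self, X: Sequence[GeneSequence | str]) -> np.ndarray:
        params = self._params()
        return np.vstack([extract_features(s, params) for s in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(feature_layout(), dtype=object)


def write_features_npz(ids: Iterable[str], matrix: np.ndarray, path) -> None:
    """Compact binary feature-matrix container (npz: ids, matrix, layout)."""
    np.savez_compressed(
        path,
        ids=np.asarray(list(ids), dtype=object),
        matrix=np.asarray(matrix, dtype=float),
        layout=np.asarray(feature_layout(), dtype=object),
    )


def write_features_csv(
    ids: Iterable[str], matrix: np.ndarray, path, layout_path=None
) -> None:
    """Write a feature matrix as CSV (id column first) plus a JSON layout map."""
    import json

    import pandas as pd

    df = pd.DataFrame(np.asarray(matrix), columns=feature_layout())
    df.insert(0, "id", list(ids))
    df.to_csv(path, index=False)
    if layout_path is not None:
        with open(layout_path, "w") as fh:
            json.dump(
                {i: name for i, name in enumerate(feature_layout())}, fh, indent=2
            )
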