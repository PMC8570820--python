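"""Substitution matrices and Karlin-Altschul local-alignment statistics.

A local alignment with raw score :math:`S` searched over a query of length
:math:`m` against a reference of :math:`n` total residues has expectation

.. math:: E = K m n e^{-\\lambda S}

and normalized bit score :math:`S' = (\\lambda S - \\ln K) / \\ln 2`, so that
:math:`E = m n 2^{-S'}` holds identically.  The search space is the raw
product ``m * n`` (no finite-size length adjustment); the statistical
parameters ``lambda`` and ``K`` are the published values for the matrix and
affine gap costs in use.

Gap cost convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(the first gapped residue pays the opening cost).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .errors import AlphabetError, ConfigError

#: Internal residue order for encoded sequences and score arrays.
#: First 24 symbols follow the NCBI matrix layout; U (selenocysteine) is
#: appended and scores as C, the standard NCBI treatment.
MATRIX_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*U"

_BUILTIN = ("BLOSUM62", "BLOSUM50")

# Published Karlin-Altschul parameters (NCBI BLAST statistics tables).
_UNGAPPED_PARAMS = {
    "BLOSUM62": (0.3176, 0.134),
    "BLOSUM50": (0.2318, 0.112),
}
_GAPPED_PARAMS = {
    ("BLOSUM62", 11, 1): (0.267, 0.041),
    ("BLOSUM62", 10, 1): (0.243, 0.0295),
    ("BLOSUM50", 13, 2): (0.212, 0.021),
    ("BLOSUM50", 10, 3): (0.200, 0.023),
}


class SubstitutionMatrix:
    """Symmetric integer residue-pair scoring table over the 25-symbol alphabet."""

    def __init__(self, name: str, alphabet: str, array: np.ndarray):
        self.name = name
        self.alphabet = alphabet
        self.array = np.asarray(array, dtype=np.int32)
        if self.array.shape != (len(alphabet), len(alphabet)):
            raise ConfigError(
                f"matrix {name!r}: array shape {self.array.shape} does not "
                f"match alphabet of size {len(alphabet)}"
            )
        if not np.array_equal(self.array, self.array.T):
            raise ConfigError(f"matrix {name!r} is not symmetric")
        self._index = {c: i for i, c in enumerate(alphabet)}
        # fast char -> ordinal lookup for encode()
        self._lut = np.full(128, -1, dtype=np.int8)
        for c, i in self._index.items():
            self._lut[ord(c)] = i

    def score(self, a: str, b: str) -> int:
        try:
            return int(self.array[self._index[a], self._index[b]])
        except KeyError as exc:
            raise AlphabetError(f"residue {exc.args[0]!r} not in matrix alphabet") from exc

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to int8 ordinals into the score array."""
        codes = self._lut[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
        if (codes < 0).any():
            bad = sorted({residues[i] for i in np.nonzero(codes < 0)[0]})
            raise AlphabetError(f"residue(s) {bad!r} not in matrix alphabet")
        return codes

    def __repr__(self) -> str:
        return f"SubstitutionMatrix({self.name!r}, {len(self.alphabet)} symbols)"


def _wrap_biopython(name: str, bmat) -> SubstitutionMatrix:
    alpha24 = str(bmat.alphabet)
    n = len(MATRIX_ALPHABET)
    arr = np.zeros((n, n), dtype=np.int32)
    # U behaves as C (NCBI convention for selenocysteine)
    proxy = {c: c for c in alpha24}
    proxy["U"] = "C"
    for i, a in enumerate(MATRIX_ALPHABET):
        for j, b in enumerate(MATRIX_ALPHABET):
            arr[i, j] = int(bmat[proxy[a], proxy[b]])
    return SubstitutionMatrix(name, MATRIX_ALPHABET, arr)


def load_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a built-in substitution matrix (BLOSUM62 or BLOSUM50)."""
    key = name.upper()
    if key not in _BUILTIN:
        raise ConfigError(
            f"unknown matrix {name!r}; built-ins are {', '.join(_BUILTIN)}"
        )
    return _wrap_biopython(key, substitution_matrices.load(key))


def read_matrix_file(path, name: str | None = None) -> SubstitutionMatrix:
    """Load a matrix from an NCBI-format text file."""
    bmat = substitution_matrices.read(str(path))
    missing = set("ARNDCQEGHILKMFPSTWYV") - set(str(bmat.alphabet))
    if missing:
        raise ConfigError(
            f"matrix file {path}: missing canonical residues {sorted(missing)!r}"
        )
    return _wrap_biopython(name or str(path), bmat)


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Statistical parameters of the local-alignment score distribution.

    ``lambda_`` is in nats per raw-score unit; ``K`` is dimensionless.
    """

    lambda_: float
    K: float
    gapped: bool = True
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.K <= 0:
            raise ConfigError("Karlin-Altschul parameters require lambda > 0 and K > 0")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigError("gap costs must be >= 0")
        if self.gap_extend > self.gap_open:
            raise ConfigError("gap_extend must not exceed gap_open")


def default_params(
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    gapped: bool = True,
) -> KarlinAltschulParams:
    """Published lambda/K for a built-in matrix and gap-cost pair."""
    key = matrix.upper()
    if gapped:
        try:
            lam, K = _GAPPED_PARAMS[(key, gap_open, gap_extend)]
        except KeyError:
            known = ", ".join(f"{m} {o}/{e}" for m, o, e in _GAPPED_PARAMS)
            raise ConfigError(
                f"no published gapped statistics for {key} with gap costs "
                f"{gap_open}/{gap_extend}; known schemes: {known}. "
                "Construct KarlinAltschulParams explicitly to use custom values."
            ) from None
    else:
        try:
            lam, K = _UNGAPPED_PARAMS[key]
        except KeyError:
            raise ConfigError(f"no ungapped statistics for matrix {key!r}") from None
    return KarlinAltschulParams(lam, K, gapped, gap_open, gap_extend)


def raw_to_bits(raw_score: float, params: KarlinAltschulParams) -> float:
    """Normalized bit score ``(lambda * S - ln K) / ln 2``."""
    return (params.lambda_ * raw_score - math.log(params.K)) / math.log(2.0)


def evalue(raw_score: float, m: int, n: int, params: KarlinAltschulParams) -> float:
    """Expected chance alignments of score >= S in an m-by-n search space."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions m and n must be >= 1")
    return params.K * m * n * math.exp(-params.lambda_ * raw_score)


def min_raw_score(evalue_max: float, m: int, n: int, params: KarlinAltschulParams) -> float:
    """Smallest raw score whose E-value is <= evalue_max (real-valued)."""
    return math.log(params.K * m * n / evalue_max) / params.lambda_
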