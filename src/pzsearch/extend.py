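"""Seed extension and the exhaustive Smith-Waterman oracle.

A seed match is grown in two stages, mirroring the BLAST-family design:

1. :func:`ungapped_extend` — gap-free X-drop extension through the seed,
   stopping on either side once the running score falls ``x_drop`` below the
   best prefix/suffix score seen;
2. :func:`gapped_extend` — banded affine-gap local alignment in a diagonal
   band centred on the ungapped segment, triggered only when the ungapped
   bit score clears a threshold.

:func:`smith_waterman` is the rigorous full-matrix oracle (no band, no
X-drop) used to build ground truth for evaluation; every heuristic HSP score
is bounded above by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .scoring import KarlinAltschulParams, SubstitutionMatrix, evalue, raw_to_bits
from .seedindex import SeedMatch

_PATH_CHARS = np.array(["M", "I", "D"])


@dataclass
class HSP:
    """A scored local alignment segment (high-scoring segment pair).

    Coordinates are 0-based half-open.  ``path`` is a string over
    ``M`` (aligned column), ``I`` (consumes query only) and ``D`` (consumes
    subject only); replaying it against the two sequences with the configured
    matrix and gap costs must reproduce ``raw_score`` exactly.
    """

    query_ordinal: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    raw_score: int
    path: str
    identities: int
    gap_opens: int
    bit_score: float | None = None
    evalue: float | None = None

    @property
    def alignment_length(self) -> int:
        return len(self.path)

    @property
    def mismatches(self) -> int:
        return self.path.count("M") - self.identities

    def sort_key(self) -> tuple:
        # best first: higher score, then smaller q_start/s_start, then shorter
        return (-self.raw_score, self.q_start, self.s_start, len(self.path))


def replay_score(
    path: str,
    q_start: int,
    s_start: int,
    qres: str,
    sres: str,
    matrix: SubstitutionMatrix,
    gap_open: int,
    gap_extend: int,
) -> tuple[int, int, int]:
    """Recompute (raw_score, identities, gap_opens) by replaying an edit path."""
    score = 0
    identities = 0
    gap_opens = 0
    i, j = q_start, s_start
    prev = "M"
    for col in path:
        if col == "M":
            score += matrix.score(qres[i], sres[j])
            if qres[i] == sres[j]:
                identities += 1
            i += 1
            j += 1
        elif col == "I":
            score -= gap_open if prev != "I" else gap_extend
            if prev != "I":
                gap_opens += 1
            i += 1
        elif col == "D":
            score -= gap_open if prev != "D" else gap_extend
            if prev != "D":
                gap_opens += 1
            j += 1
        else:
            raise ValueError(f"invalid path column {col!r}")
        prev = col
    return score, identities, gap_opens


def _path_stats(path: str, qres: str, sres: str, q_start: int, s_start: int) -> tuple[int, int]:
    identities = 0
    gap_opens = 0
    i, j = q_start, s_start
    prev = ""
    for col in path:
        if col == "M":
            if qres[i] == sres[j]:
                identities += 1
            i += 1
            j += 1
        elif col == "I":
            if prev != "I":
                gap_opens += 1
            i += 1
        else:
            if prev != "D":
                gap_opens += 1
            j += 1
        prev = col
    return identities, gap_opens


def decorate_hsp(hsp: HSP, m: int, n: int, params: KarlinAltschulParams) -> HSP:
    """Fill in bit score and E-value for an HSP searched over an m x n space."""
    hsp.bit_score = raw_to_bits(hsp.raw_score, params)
    hsp.evalue = evalue(hsp.raw_score, m, n, params)
    return hsp


def ungapped_extend(
    seed: SeedMatch,
    qenc: np.ndarray,
    senc: np.ndarray,
    matrix_array: np.ndarray,
    k: int,
    x_drop: int,
    qres: str,
    sres: str,
) -> HSP:
    """Maximal gap-free X-drop extension through an exact k-mer seed."""
    qp, sp = seed.q_pos, seed.s_pos
    seed_score = 0
    for t in range(k):
        seed_score += int(matrix_array[qenc[qp + t], senc[sp + t]])

    # extend right of the seed
    best_r, run, ext_r = 0, 0, 0
    i, j = qp + k, sp + k
    step = 0
    while i < len(qenc) and j < len(senc):
        run += int(matrix_array[qenc[i], senc[j]])
        step += 1
        if run > best_r:
            best_r, ext_r = run, step
        elif run < best_r - x_drop:
            break
        i += 1
        j += 1

    # extend left of the seed
    best_l, run, ext_l = 0, 0, 0
    i, j = qp - 1, sp - 1
    step = 0
    while i >= 0 and j >= 0:
        run += int(matrix_array[qenc[i], senc[j]])
        step += 1
        if run > best_l:
            best_l, ext_l = run, step
        elif run < best_l - x_drop:
            break
        i -= 1
        j -= 1

    q_start = qp - ext_l
    q_end = qp + k + ext_r
    s_start = sp - ext_l
    length = q_end - q_start
    path = "M" * length
    identities, _ = _path_stats(path, qres, sres, q_start, s_start)
    return HSP(
        query_ordinal=seed.query_ordinal,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_start + length,
        raw_score=seed_score + best_l + best_r,
        path=path,
        identities=identities,
        gap_opens=0,
    )


def gapped_extend(
    hsp_seed: HSP,
    qenc: np.ndarray,
    senc: np.ndarray,
    matrix_array: np.ndarray,
    gap_open: int,
    gap_extend: int,
    x_drop: int,
    band_width: int,
    qres: str,
    sres: str,
) -> HSP:
    """Banded affine-gap local extension around an ungapped HSP's diagonal.

    The band covers ``band_width`` diagonals centred on the seed HSP's
    diagonal, so the returned score is never below the ungapped score.
    """
    center_diag = hsp_seed.s_start - hsp_seed.q_start
    half_width = max(1, band_width // 2)
    score, qs, qe, ss, se, path_codes = _kernels.banded_sw(
        qenc,
        senc,
        np.int64(center_diag),
        np.int64(half_width),
        matrix_array,
        np.int64(gap_open),
        np.int64(gap_extend),
        np.int64(x_drop),
    )
    if len(path_codes) == 0:  # degenerate: fall back to the ungapped segment
        return hsp_seed
    path = "".join(_PATH_CHARS[path_codes])
    identities, gap_opens = _path_stats(path, qres, sres, qs, ss)
    return HSP(
        query_ordinal=hsp_seed.query_ordinal,
        q_start=int(qs),
        q_end=int(qe),
        s_start=int(ss),
        s_end=int(se),
        raw_score=int(score),
        path=path,
        identities=identities,
        gap_opens=gap_opens,
    )


def smith_waterman(
    qres: str,
    sres: str,
    matrix: SubstitutionMatrix,
    gap_open: int = 11,
    gap_extend: int = 1,
    query_ordinal: int = 0,
) -> HSP:
    """Exact optimal local alignment (full dynamic programming, affine gaps)."""
    if not qres or not sres:
        raise ValueError("smith_waterman requires non-empty sequences")
    qenc = matrix.encode(qres)
    senc = matrix.encode(sres)
    score, qs, qe, ss, se, path_codes = _kernels.sw_full(
        qenc, senc, matrix.array, np.int64(gap_open), np.int64(gap_extend)
    )
    path = "".join(_PATH_CHARS[path_codes]) if len(path_codes) else ""
    identities, gap_opens = (
        _path_stats(path, qres, sres, qs, ss) if path else (0, 0)
    )
    return HSP(
        query_ordinal=query_ordinal,
        q_start=int(qs),
        q_end=int(qe),
        s_start=int(ss),
        s_end=int(se),
        raw_score=int(score),
        path=path,
        identities=identities,
        gap_opens=gap_opens,
    )


def smith_waterman_score(
    qenc: np.ndarray,
    senc: np.ndarray,
    matrix_array: np.ndarray,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Score-only Smith-Waterman (linear memory); used for bulk ground truth."""
    return int(
        _kernels.sw_score(
            qenc, senc, matrix_array, np.int64(gap_open), np.int64(gap_extend)
        )
    )
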