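"""Query-side k-mer seed index with streamed reference scanning.

The index is built over the (small) query set rather than the (huge)
reference: each length-k residue word of every query is posted to a hash
table, and reference sequences are then streamed past the table one at a
time.  This inverts the usual database-indexing layout and keeps memory
proportional to the query set, so arbitrarily large references can be
scanned in chunks.

Words containing ``*`` (and, by default, the ambiguity residue ``X``) are
never indexed.  Homopolymer words are indexed but the number of postings
scanned for them is capped per reference sequence as a worst-case guard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import LimitError
from .seqio import AminoAcidSequence

logger = logging.getLogger(__name__)

DEFAULT_MAX_QUERIES = 10_000
HOMOPOLYMER_POSTING_CAP = 10_000


@dataclass(frozen=True)
class SeedMatch:
    """An exact k-word shared by a query and a reference sequence."""

    query_ordinal: int
    q_pos: int
    s_pos: int

    @property
    def diagonal(self) -> int:
        return self.s_pos - self.q_pos


@dataclass
class SeedIndex:
    """k-mer -> (query_ordinal, query_offset) postings over the query set."""

    k: int
    postings: dict[str, list[tuple[int, int]]]
    n_queries: int
    total_postings: int
    query_ids: list[str] = field(default_factory=list)


def build_index(
    queries: list[AminoAcidSequence],
    k: int = 4,
    max_queries: int = DEFAULT_MAX_QUERIES,
    index_x: bool = False,
) -> SeedIndex:
    """Build the seed table over the query set.

    Queries shorter than *k* are excluded from seeding with a warning (they
    remain addressable by ordinal for oracle-based workflows).
    """
    if k < 2:
        raise ValueError(f"seed length k must be >= 2, got {k}")
    if not queries:
        raise ValueError("at least one query sequence is required")
    if len(queries) > max_queries:
        raise LimitError(
            f"{len(queries)} query sequences exceed the submission limit of "
            f"{max_queries} (maximum sequences per submission)"
        )
    skip = {"*"} if index_x else {"*", "X"}
    postings: dict[str, list[tuple[int, int]]] = {}
    total = 0
    for ordinal, query in enumerate(queries):
        res = query.residues
        if len(res) < k:
            logger.warning(
                "query %r (length %d) is shorter than the seed length %d; "
                "excluded from seeding",
                query.id,
                len(res),
                k,
            )
            continue
        for off in range(len(res) - k + 1):
            word = res[off : off + k]
            if skip & set(word):
                continue
            postings.setdefault(word, []).append((ordinal, off))
            total += 1
    return SeedIndex(
        k=k,
        postings=postings,
        n_queries=len(queries),
        total_postings=total,
        query_ids=[q.id for q in queries],
    )


def _is_homopolymer(word: str) -> bool:
    return len(set(word)) == 1


def scan_reference(index: SeedIndex, ref: AminoAcidSequence) -> list[SeedMatch]:
    """All exact k-word matches between *ref* and the indexed queries.

    Output is ordered by (query_ordinal, diagonal, q_pos).  A reference
    shorter than k yields no matches.
    """
    k = index.k
    res = ref.residues
    matches: list[SeedMatch] = []
    postings = index.postings
    scanned_per_word: dict[str, int] = {}
    for s_pos in range(len(res) - k + 1):
        word = res[s_pos : s_pos + k]
        plist = postings.get(word)
        if plist is None:
            continue
        if _is_homopolymer(word):
            used = scanned_per_word.get(word, 0)
            budget = HOMOPOLYMER_POSTING_CAP - used
            if budget <= 0:
                continue
            if len(plist) > budget:
                logger.warning(
                    "homopolymer word %r: posting scan capped at %d for "
                    "reference %r",
                    word,
                    HOMOPOLYMER_POSTING_CAP,
                    ref.id,
                )
                plist = plist[:budget]
            scanned_per_word[word] = used + len(plist)
        for ordinal, q_pos in plist:
            matches.append(SeedMatch(ordinal, q_pos, s_pos))
    matches.sort(key=lambda sm: (sm.query_ordinal, sm.diagonal, sm.q_pos))
    return matches


def dedupe_seeds(matches: list[SeedMatch], k: int) -> list[SeedMatch]:
    """Collapse seeds on one (query, diagonal) within 2k residues to the leftmost.

    Assumes *matches* are sorted by (query_ordinal, diagonal, q_pos), as
    produced by :func:`scan_reference`.
    """
    kept: list[SeedMatch] = []
    last_key: tuple[int, int] | None = None
    last_qpos = -(10**9)
    for sm in matches:
        key = (sm.query_ordinal, sm.diagonal)
        if key != last_key or sm.q_pos - last_qpos >= 2 * k:
            kept.append(sm)
            last_key = key
            last_qpos = sm.q_pos
    return kept
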