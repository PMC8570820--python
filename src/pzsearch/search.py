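"""Full search pipeline: index queries, stream reference chunks, extend, rank.

The reference may arrive as several chunks (file paths or in-memory sequence
lists).  E-values are always computed against the grand total residue count
of the whole reference, communicated to every chunk before extension, so a
chunked (or multi-worker) run is bit-identical to a single pass over the
concatenated reference and chunks can be merged by a plain sort.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .errors import ConsistencyError, LimitError
from .extend import HSP, decorate_hsp, gapped_extend, ungapped_extend
from .scoring import (
    KarlinAltschulParams,
    SubstitutionMatrix,
    default_params,
    load_matrix,
    raw_to_bits,
)
from .seedindex import build_index, dedupe_seeds, scan_reference
from .seqio import AminoAcidSequence, HitRecord, read_fasta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the seed-and-extend search."""

    k: int = 4
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    x_drop_ungapped: int = 20
    gapped_trigger_bits: float = 22.0
    x_drop_gapped: int = 38
    band_width: int = 64
    evalue_max: float = 1e-8
    max_hits_per_query: int = 10_000
    max_queries: int = 10_000
    workers: int = 1
    total_reference_residues: int | None = None

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.max_hits_per_query < 1:
            raise ValueError("max_hits_per_query must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    def params(self) -> KarlinAltschulParams:
        return default_params(self.matrix_name, self.gap_open, self.gap_extend)

    def matrix(self) -> SubstitutionMatrix:
        return load_matrix(self.matrix_name)


@dataclass
class QueryHits:
    """Ranked hits for one query."""

    hits: list[HitRecord] = field(default_factory=list)
    candidates_examined: int = 0
    truncated: bool = False


@dataclass
class SearchResult:
    query_ids: list[str]
    per_query: dict[str, QueryHits]
    total_reference_residues: int
    config: SearchConfig

    def all_hits(self) -> list[HitRecord]:
        out: list[HitRecord] = []
        for qid in self.query_ids:
            out.extend(self.per_query[qid].hits)
        return out


@dataclass
class ChunkResult:
    """Per-chunk partial result, mergeable across chunks/workers."""

    per_query: dict[str, list[HitRecord]]
    candidates: dict[str, int]
    subject_ids: set[str]
    total_reference_residues: int
    config: SearchConfig


def _load_chunk(chunk) -> list[AminoAcidSequence]:
    if isinstance(chunk, (str, Path)):
        return read_fasta(chunk, mode="lenient")
    return list(chunk)


def extend_pair(
    query: AminoAcidSequence,
    subject: AminoAcidSequence,
    config: SearchConfig,
    matrix: SubstitutionMatrix | None = None,
    query_ordinal: int = 0,
) -> list[HSP]:
    """Run the full heuristic (seed, ungapped, gapped) on one sequence pair.

    Returns all distinct HSPs found, best first.  Used by the search driver
    per candidate pair and directly useful for benchmarking the heuristic
    against the exhaustive oracle.
    """
    matrix = matrix or config.matrix()
    index = build_index([query], k=config.k, max_queries=config.max_queries)
    seeds = dedupe_seeds(scan_reference(index, subject), config.k)
    if not seeds:
        return []
    qenc = matrix.encode(query.residues)
    senc = matrix.encode(subject.residues)
    params = config.params()
    hsps: list[HSP] = []
    for seed in seeds:
        ungapped = ungapped_extend(
            seed,
            qenc,
            senc,
            matrix.array,
            config.k,
            config.x_drop_ungapped,
            query.residues,
            subject.residues,
        )
        ungapped.query_ordinal = query_ordinal
        if raw_to_bits(ungapped.raw_score, params) < config.gapped_trigger_bits:
            hsps.append(ungapped)
            continue
        covered = any(
            h.gap_opens >= 0
            and h.path
            and h.q_start <= ungapped.q_start
            and h.q_end >= ungapped.q_end
            and h.s_start <= ungapped.s_start
            and h.s_end >= ungapped.s_end
            for h in hsps
            if h.raw_score >= ungapped.raw_score
        )
        if covered:
            continue
        gapped = gapped_extend(
            ungapped,
            qenc,
            senc,
            matrix.array,
            config.gap_open,
            config.gap_extend,
            config.x_drop_gapped,
            config.band_width,
            query.residues,
            subject.residues,
        )
        gapped.query_ordinal = query_ordinal
        hsps.append(gapped)
    # distinct spans only, best first
    seen: set[tuple[int, int, int, int]] = set()
    uniq: list[HSP] = []
    for h in sorted(hsps, key=HSP.sort_key):
        span = (h.q_start, h.q_end, h.s_start, h.s_end)
        if span not in seen:
            seen.add(span)
            uniq.append(h)
    return uniq


def _hsp_to_hit(query: AminoAcidSequence, subject: AminoAcidSequence, hsp: HSP) -> HitRecord:
    length = hsp.alignment_length
    pid = 100.0 * hsp.identities / length if length else 0.0
    return HitRecord(
        query_id=query.id,
        subject_id=subject.id,
        percent_identity=round(pid, 2),
        alignment_length=length,
        mismatches=hsp.mismatches,
        gap_opens=hsp.gap_opens,
        q_start=hsp.q_start + 1,
        q_end=hsp.q_end,
        s_start=hsp.s_start + 1,
        s_end=hsp.s_end,
        evalue=hsp.evalue,
        bit_score=round(hsp.bit_score, 4),
    )


def search_chunk(
    queries: list[AminoAcidSequence],
    chunk,
    config: SearchConfig,
    total_reference_residues: int,
) -> ChunkResult:
    """Scan one reference chunk against the query index.

    E-values use *total_reference_residues* (the full reference, all chunks).
    """
    matrix = config.matrix()
    params = config.params()
    index = build_index(queries, k=config.k, max_queries=config.max_queries)
    qenc = [matrix.encode(q.residues) for q in queries]
    per_query: dict[str, list[HitRecord]] = {q.id: [] for q in queries}
    candidates: dict[str, int] = {q.id: 0 for q in queries}
    subject_ids: set[str] = set()

    refs = _load_chunk(chunk)
    for ref in refs:
        if ref.id in subject_ids:
            raise ConsistencyError(f"duplicate subject id {ref.id!r} within chunk")
        subject_ids.add(ref.id)
        seeds = dedupe_seeds(scan_reference(index, ref), config.k)
        if not seeds:
            continue
        senc = matrix.encode(ref.residues)
        best_by_query: dict[int, HSP] = {}
        for seed in seeds:
            qo = seed.query_ordinal
            ungapped = ungapped_extend(
                seed,
                qenc[qo],
                senc,
                matrix.array,
                config.k,
                config.x_drop_ungapped,
                queries[qo].residues,
                ref.residues,
            )
            if raw_to_bits(ungapped.raw_score, params) < config.gapped_trigger_bits:
                hsp = ungapped
            else:
                prev = best_by_query.get(qo)
                if (
                    prev is not None
                    and prev.raw_score >= ungapped.raw_score
                    and prev.q_start <= ungapped.q_start
                    and prev.q_end >= ungapped.q_end
                    and prev.s_start <= ungapped.s_start
                    and prev.s_end >= ungapped.s_end
                ):
                    continue  # seed already inside a better gapped HSP
                hsp = gapped_extend(
                    ungapped,
                    qenc[qo],
                    senc,
                    matrix.array,
                    config.gap_open,
                    config.gap_extend,
                    config.x_drop_gapped,
                    config.band_width,
                    queries[qo].residues,
                    ref.residues,
                )
            prev = best_by_query.get(qo)
            if prev is None or hsp.sort_key() < prev.sort_key():
                best_by_query[qo] = hsp
        for qo, hsp in best_by_query.items():
            candidates[queries[qo].id] += 1
            decorate_hsp(hsp, len(queries[qo]), total_reference_residues, params)
            if hsp.evalue <= config.evalue_max:
                per_query[queries[qo].id].append(_hsp_to_hit(queries[qo], ref, hsp))
    return ChunkResult(
        per_query=per_query,
        candidates=candidates,
        subject_ids=subject_ids,
        total_reference_residues=total_reference_residues,
        config=config,
    )


def merge_chunk_results(
    partials: Sequence[ChunkResult], config: SearchConfig
) -> SearchResult:
    """Merge per-chunk partials into the final ranking.

    The merged ranking is identical (bit-exact on every field) to a
    single-pass search over the concatenated reference.
    """
    if not partials:
        raise ValueError("no partial results to merge")
    base = partials[0]
    if any(p.config != config for p in partials):
        raise ConsistencyError("partial results were computed with different configs")
    for p in partials[1:]:
        if p.total_reference_residues != base.total_reference_residues:
            raise ConsistencyError(
                "partial results disagree on total reference residue count"
            )
        dup = base.subject_ids & p.subject_ids
        if dup:
            raise ConsistencyError(
                f"duplicate subject id(s) across chunks: {sorted(dup)[:5]!r}"
            )
    query_ids = list(base.per_query.keys())
    seen_subjects: set[str] = set()
    for p in partials:
        dup = seen_subjects & p.subject_ids
        if dup:
            raise ConsistencyError(
                f"duplicate subject id(s) across chunks: {sorted(dup)[:5]!r}"
            )
        seen_subjects |= p.subject_ids
    per_query: dict[str, QueryHits] = {}
    for qid in query_ids:
        hits: list[HitRecord] = []
        cand = 0
        for p in partials:
            hits.extend(p.per_query[qid])
            cand += p.candidates[qid]
        hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
        truncated = len(hits) > config.max_hits_per_query
        per_query[qid] = QueryHits(
            hits=hits[: config.max_hits_per_query],
            candidates_examined=cand,
            truncated=truncated,
        )
    return SearchResult(
        query_ids=query_ids,
        per_query=per_query,
        total_reference_residues=base.total_reference_residues,
        config=config,
    )


def count_reference_residues(reference_chunks: Sequence) -> int:
    return sum(len(s) for chunk in reference_chunks for s in _load_chunk(chunk))


def _chunk_worker(args) -> ChunkResult:
    queries, chunk, config, total_n = args
    return search_chunk(queries, chunk, config, total_n)


def search(
    queries: list[AminoAcidSequence],
    reference_chunks: Sequence,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Search queries against a chunked reference collection.

    *reference_chunks* is a sequence of FASTA paths and/or in-memory
    sequence lists.  Results are deterministic for a fixed config regardless
    of chunking and worker count.
    """
    config = config or SearchConfig()
    if len(queries) > config.max_queries:
        raise LimitError(
            f"{len(queries)} query sequences exceed the submission limit of "
            f"{config.max_queries} (maximum sequences per submission)"
        )
    total_n = config.total_reference_residues
    if total_n is None:
        total_n = count_reference_residues(reference_chunks)
    if total_n == 0:
        logger.warning("reference is empty; returning empty results")
        return SearchResult(
            query_ids=[q.id for q in queries],
            per_query={q.id: QueryHits() for q in queries},
            total_reference_residues=0,
            config=config,
        )
    jobs = [(queries, chunk, config, total_n) for chunk in reference_chunks]
    if config.workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            partials = list(pool.map(_chunk_worker, jobs))
    else:
        partials = [_chunk_worker(job) for job in jobs]
    return merge_chunk_results(partials, config)
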