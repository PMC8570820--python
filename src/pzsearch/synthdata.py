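"""Synthetic ontology-annotated metagenome protein references.

Emulates, at desk scale, a reference built from many metagenome samples:
each sample contributes a set of predicted protein sequences, carries an
environment-ontology class (optionally a body-site class) and coordinates,
and homologs of chosen query proteins are planted at controlled identity so
search sensitivity can be measured against a known answer key.

Decoy residues are drawn i.i.d. from the BLOSUM62 background amino-acid
frequencies, which keeps the chance-alignment null model consistent with
the scoring scheme.  The generator is fully deterministic under its seed:
the same configuration writes byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import AminoAcidSequence, write_fasta
from .summarize import SampleMetadata, write_metadata

# BLOSUM62 background (marginal) amino-acid frequencies.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

_BG_RESIDUES = np.array(list(BLOSUM62_BACKGROUND))
_BG_PROBS = np.array(list(BLOSUM62_BACKGROUND.values()))
_BG_PROBS = _BG_PROBS / _BG_PROBS.sum()

#: Default environment-class pool: (class_id, label, sampling weight).
DEFAULT_ENV_POOL = [
    ("ENV:01", "gut", 0.30),
    ("ENV:02", "soil", 0.25),
    ("ENV:03", "marine water", 0.20),
    ("ENV:04", "freshwater", 0.15),
    ("ENV:05", "hot spring", 0.10),
]

#: Body-site classes drawn for host-associated (gut) samples.
DEFAULT_BODY_POOL = [
    ("BODY:01", "colon", 0.6),
    ("BODY:02", "small intestine", 0.4),
]

#: Coordinate pool (decimal degrees); None entries yield samples without
#: location, exercising the no-location aggregation path.
DEFAULT_COORD_POOL = [
    (35.68, 139.69),
    (1.29, 103.85),
    (-33.87, 151.21),
    (51.51, -0.13),
    (37.77, -122.42),
    None,
]


@dataclass(frozen=True)
class PlantSpec:
    """Instructions for planting homologs of one query."""

    query: AminoAcidSequence
    n_copies: int
    target_identity: float
    indel_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.target_identity <= 1.0:
            raise ValueError("target_identity must be in (0, 1]")
        if not 0.0 <= self.indel_rate <= 0.2:
            raise ValueError("indel_rate must be in [0, 0.2]")
        if len(self.query) < 20:
            raise ValueError("planted queries must be at least 20 residues")


@dataclass
class SimConfig:
    """Shape of the synthetic reference."""

    n_samples: int = 20
    seqs_per_sample: int = 250
    length_range: tuple[int, int] = (100, 350)
    planted: list[PlantSpec] = field(default_factory=list)
    env_pool: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_ENV_POOL)
    )
    body_pool: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_BODY_POOL)
    )
    coord_pool: list[tuple[float, float] | None] = field(
        default_factory=lambda: list(DEFAULT_COORD_POOL)
    )
    multi_class: bool = False
    n_chunks: int = 1
    rng_seed: int = 42


@dataclass
class SyntheticReference:
    """In-memory product of :func:`generate_reference`."""

    chunks: list[list[AminoAcidSequence]]
    metadata: dict[str, SampleMetadata]
    planted: pd.DataFrame  # subject_id, query_id, target_identity, realized_identity
    chunk_paths: list[Path] = field(default_factory=list)

    def all_sequences(self) -> list[AminoAcidSequence]:
        return [s for chunk in self.chunks for s in chunk]

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.all_sequences())


def random_protein(length: int, rng: np.random.Generator) -> str:
    """i.i.d. draw from the BLOSUM62 background composition."""
    return "".join(rng.choice(_BG_RESIDUES, size=length, p=_BG_PROBS))


def mutate_homolog(
    query: AminoAcidSequence | str,
    target_identity: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Mutate a query into a homolog at a target identity.

    Each position is substituted with probability ``1 - target_identity`` to
    a uniformly chosen *different* canonical residue.  Indel events occur per
    column with probability *indel_rate*, with geometric lengths (mean 2);
    insertions and deletions are equally likely.

    Returns (residues, realized_identity), where realized identity is the
    fraction of original query columns left unsubstituted and undeleted.
    """
    res = query.residues if isinstance(query, AminoAcidSequence) else query
    if len(res) < 20:
        raise ValueError("query must be at least 20 residues")
    residues20 = list(BLOSUM62_BACKGROUND)
    out: list[str] = []
    preserved = 0
    i = 0
    n = len(res)
    while i < n:
        # deletion event removes a geometric-length run of columns
        if indel_rate and rng.random() < indel_rate / 2.0:
            i += int(rng.geometric(0.5))
            continue
        ch = res[i]
        if rng.random() < 1.0 - target_identity:
            choices = [r for r in residues20 if r != ch]
            out.append(choices[int(rng.integers(len(choices)))])
        else:
            out.append(ch)
            preserved += 1
        # insertion event adds a geometric-length run of background residues
        if indel_rate and rng.random() < indel_rate / 2.0:
            ins_len = int(rng.geometric(0.5))
            out.extend(rng.choice(_BG_RESIDUES, size=ins_len, p=_BG_PROBS))
        i += 1
    if not out:  # pathological all-deleted draw
        out = list(res[:1])
    return "".join(out), preserved / n


def _weighted_choice(pool, rng: np.random.Generator):
    weights = np.array([p[-1] for p in pool], dtype=float)
    weights = weights / weights.sum()
    return pool[int(rng.choice(len(pool), p=weights))]


def generate_reference(
    config: SimConfig, out_dir: str | Path | None = None
) -> SyntheticReference:
    """Generate the synthetic reference, optionally writing it to disk.

    Produces ``n_samples * seqs_per_sample`` decoys plus all planted
    homologs, split into ``n_chunks`` FASTA chunks (samples are distributed
    round-robin).  When *out_dir* is given, writes ``chunk_NN.faa``,
    ``samples.tsv`` and ``planted_truth.tsv``.
    """
    # spawn a child stream so sequences a user draws elsewhere with the same
    # integer seed are statistically independent of the generated reference
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(1,))
    )
    lo, hi = config.length_range
    if not 1 <= lo <= hi:
        raise ValueError("length_range must satisfy 1 <= min <= max")

    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    metadata: dict[str, SampleMetadata] = {}
    for sid in sample_ids:
        cid, label, _w = _weighted_choice(config.env_pool, rng)
        env = [(cid, label)]
        if config.multi_class and rng.random() < 0.3:
            cid2, label2, _w2 = _weighted_choice(config.env_pool, rng)
            if cid2 != cid:
                env.append((cid2, label2))
        body: list[tuple[str, str]] = []
        if label == "gut" and config.body_pool:
            bcid, blabel, _bw = _weighted_choice(config.body_pool, rng)
            body = [(bcid, blabel)]
        coord = config.coord_pool[int(rng.integers(len(config.coord_pool)))]
        lat, lon = coord if coord is not None else (None, None)
        metadata[sid] = SampleMetadata(
            sample_id=sid, env_classes=env, body_classes=body,
            latitude=lat, longitude=lon,
        )

    per_sample: dict[str, list[AminoAcidSequence]] = {sid: [] for sid in sample_ids}
    for sid in sample_ids:
        lengths = rng.integers(lo, hi + 1, size=config.seqs_per_sample)
        for j, length in enumerate(lengths):
            per_sample[sid].append(
                AminoAcidSequence(
                    id=f"{sid}|d{j:05d}",
                    residues=random_protein(int(length), rng),
                    sample_id=sid,
                )
            )

    planted_rows = []
    counter = 0
    for spec in config.planted:
        for _ in range(spec.n_copies):
            sid = sample_ids[int(rng.integers(len(sample_ids)))]
            residues, realized = mutate_homolog(
                spec.query, spec.target_identity, spec.indel_rate, rng
            )
            subject_id = f"{sid}|p{counter:04d}"
            counter += 1
            per_sample[sid].append(
                AminoAcidSequence(id=subject_id, residues=residues, sample_id=sid)
            )
            planted_rows.append(
                (subject_id, spec.query.id, spec.target_identity, realized)
            )
    planted = pd.DataFrame(
        planted_rows,
        columns=["subject_id", "query_id", "target_identity", "realized_identity"],
    )

    chunks: list[list[AminoAcidSequence]] = [[] for _ in range(config.n_chunks)]
    for i, sid in enumerate(sample_ids):
        chunks[i % config.n_chunks].extend(per_sample[sid])

    result = SyntheticReference(chunks=chunks, metadata=metadata, planted=planted)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for c, chunk in enumerate(chunks):
            p = out_dir / f"chunk_{c:02d}.faa"
            write_fasta(chunk, p)
            result.chunk_paths.append(p)
        write_metadata(metadata, out_dir / "samples.tsv")
        planted.to_csv(out_dir / "planted_truth.tsv", sep="\t", index=False)
    return result
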