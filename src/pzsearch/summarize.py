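"""Environment-ontology, body-site and geographic summaries of hit tables.

Each reference sequence belongs to a metagenome sample; samples carry one or
more environment-ontology classes (MEO-style), optional body-site classes
(FMA-style) and optional coordinates.  A hit contributes one count to every
class annotating its sample, so with multi-class metadata the class
fractions may sum to more than 1 (each fraction is relative to the total
number of input hits).  Hits whose sample has no metadata fall into the
reserved ``unclassified`` class; samples without coordinates aggregate under
a ``no-location`` row.

The counting unit is the hit (best HSP per query-subject pair), so sequence
abundance within a sample is reflected in the summary.

Classes are flat labels from the metadata table — no ontology-graph rollup
to ancestor classes is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError, HitTableFormatError
from .seqio import HitRecord, split_sample_id

UNCLASSIFIED = "unclassified"
NO_LOCATION = "no-location"


@dataclass
class SampleMetadata:
    """Per-sample annotations: ontology classes and coordinates."""

    sample_id: str
    env_classes: list[tuple[str, str]] = field(default_factory=list)
    body_classes: list[tuple[str, str]] = field(default_factory=list)
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"sample {self.sample_id}: latitude out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"sample {self.sample_id}: longitude out of range")


def _parse_classes(cell: str) -> list[tuple[str, str]]:
    """``id|label;id|label`` cell -> list of (id, label)."""
    out: list[tuple[str, str]] = []
    for item in cell.split(";"):
        item = item.strip()
        if not item:
            continue
        if "|" in item:
            cid, label = item.split("|", 1)
        else:
            cid, label = item, item
        out.append((cid, label))
    return out


def read_metadata(path) -> dict[str, SampleMetadata]:
    """Read the 5-column sample metadata TSV.

    Columns: sample_id, env_class_ids, body_class_ids, latitude, longitude;
    the last four may be empty.  A header row starting with ``sample_id`` is
    skipped.
    """
    metadata: dict[str, SampleMetadata] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0] == "sample_id":
                continue
            if len(parts) < 2:
                raise HitTableFormatError(
                    f"{path}: line {ln}: expected >= 2 tab-separated columns"
                )
            parts += [""] * (5 - len(parts))
            sid = parts[0]
            lat = float(parts[3]) if parts[3] else None
            lon = float(parts[4]) if parts[4] else None
            metadata[sid] = SampleMetadata(
                sample_id=sid,
                env_classes=_parse_classes(parts[1]),
                body_classes=_parse_classes(parts[2]),
                latitude=lat,
                longitude=lon,
            )
    return metadata


def write_metadata(metadata: Mapping[str, SampleMetadata], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tenv_class_ids\tbody_class_ids\tlatitude\tlongitude\n")
        for sid in metadata:
            md = metadata[sid]
            env = ";".join(f"{c}|{l}" for c, l in md.env_classes)
            body = ";".join(f"{c}|{l}" for c, l in md.body_classes)
            lat = "" if md.latitude is None else f"{md.latitude}"
            lon = "" if md.longitude is None else f"{md.longitude}"
            fh.write(f"{sid}\t{env}\t{body}\t{lat}\t{lon}\n")


def _sample_of(hit: HitRecord) -> str | None:
    return split_sample_id(hit.subject_id)


def summarize_by_class(
    hits: Iterable[HitRecord],
    metadata: Mapping[str, SampleMetadata],
    namespace: str = "env",
) -> pd.DataFrame:
    """Aggregate hits per ontology class.

    Returns a frame with columns class_id, class_label, hit_count,
    hit_fraction (of all input hits) and distinct_samples, sorted by
    hit_count descending then class_id.
    """
    if namespace not in ("env", "body"):
        raise ConfigError(f"unknown namespace {namespace!r}; expected 'env' or 'body'")
    counts: dict[tuple[str, str], int] = {}
    samples: dict[tuple[str, str], set[str]] = {}
    n_hits = 0
    for hit in hits:
        n_hits += 1
        sid = _sample_of(hit)
        md = metadata.get(sid) if sid is not None else None
        classes = None
        if md is not None:
            classes = md.env_classes if namespace == "env" else md.body_classes
        if not classes:
            classes = [(UNCLASSIFIED, UNCLASSIFIED)]
        for key in classes:
            counts[key] = counts.get(key, 0) + 1
            samples.setdefault(key, set()).add(sid if sid is not None else UNCLASSIFIED)
    rows = [
        (cid, label, c, c / n_hits if n_hits else 0.0, len(samples[(cid, label)]))
        for (cid, label), c in counts.items()
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(
        rows,
        columns=["class_id", "class_label", "hit_count", "hit_fraction", "distinct_samples"],
    )


def summarize_geography(
    hits: Iterable[HitRecord], metadata: Mapping[str, SampleMetadata]
) -> pd.DataFrame:
    """Aggregate hits per exact sample coordinate pair.

    Samples without coordinates are pooled under a ``no-location`` row (NaN
    coordinates).  Sorted by hit_count descending, then coordinates.
    """
    counts: dict[tuple[float, float] | str, int] = {}
    for hit in hits:
        sid = _sample_of(hit)
        md = metadata.get(sid) if sid is not None else None
        if md is None or md.latitude is None or md.longitude is None:
            key: tuple[float, float] | str = NO_LOCATION
        else:
            key = (md.latitude, md.longitude)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for key, c in counts.items():
        if key == NO_LOCATION:
            rows.append((math.nan, math.nan, c, NO_LOCATION))
        else:
            rows.append((key[0], key[1], c, ""))
    rows.sort(key=lambda r: (-r[2], math.isnan(r[0]), r[0], r[1]))
    return pd.DataFrame(rows, columns=["latitude", "longitude", "hit_count", "note"])
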