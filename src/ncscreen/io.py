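"""File I/O: BED6/BED9, GFF3, bedGraph and tabular helpers.

BED is native to the internal 0-based half-open convention; GFF3 is
converted from/to its 1-based inclusive coordinates on read/write.
Classified output is written as BED9 where the itemRgb column carries a
fixed per-class colour and the name field the (multi-)label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .intervals import (
    FEATURE_CLASSES,
    AnnotatedFeature,
    AnnotationSet,
    GenomicInterval,
)

#: Fixed colour map for classified BED9 output (itemRgb strings).
CLASS_COLORS: dict[str, str] = {
    "asRNA": "215,48,39",          # red
    "UTR": "118,42,131",           # purple
    "sRNA": "27,120,55",           # green
    "unclear": "128,128,128",      # grey
    "antisense_rRNA": "253,174,97",
    "coding_gene": "33,102,172",
    "candidate": "0,0,0",
}
_DEFAULT_COLOR = "0,0,0"


@dataclass(frozen=True)
class BedRecord:
    """One BED6/BED9 line; thick* and color only serialized when color set."""

    interval: GenomicInterval
    name: str
    score: float = 0.0
    color: str | None = None


class FileFormatError(ValueError):
    """Malformed input line; message names the offending line number."""


def write_bed(path: str | Path, records: list[BedRecord]) -> None:
    """Write BED6, or BED9 when any record carries an itemRgb colour."""
    bed9 = any(r.color is not None for r in records)
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            fields = [iv.seqid, str(iv.start), str(iv.end), r.name,
                      _fmt_score(r.score), iv.strand]
            if bed9:
                fields += [str(iv.start), str(iv.end), r.color or _DEFAULT_COLOR]
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read BED6/BED9; raises :class:`FileFormatError` naming bad lines."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated BED "
                    f"fields, got {len(fields)}"
                )
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[5]
                )
                score = float(fields[4])
            except ValueError as exc:
                raise FileFormatError(f"{path}: line {lineno}: {exc}") from exc
            color = fields[8] if len(fields) >= 9 else None
            records.append(BedRecord(iv, fields[3], score, color))
    return records


# --- GFF3 -----------------------------------------------------------------

_GFF_SOURCE = "ncscreen"


def _encode_attrs(feature: AnnotatedFeature) -> str:
    parts = [f"ID={feature.id}", f"feature_class={feature.feature_class}"]
    for key, values in (
        ("regulons", feature.regulons),
        ("go_terms", feature.go_terms),
        ("pathways", feature.pathways),
    ):
        if values:
            parts.append(f"{key}={','.join(sorted(values))}")
    if feature.metabolic:
        parts.append("metabolic=true")
    if feature.operon_id is not None:
        parts.append(f"operon_id={feature.operon_id}")
    return ";".join(parts)


def write_gff3(path: str | Path, ann: AnnotationSet) -> None:
    """Write an AnnotationSet as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid in sorted(ann.seq_lengths):
            fh.write(f"##sequence-region {seqid} 1 {ann.seq_lengths[seqid]}\n")
        for f in sorted(
            ann.features, key=lambda f: (f.interval.seqid, f.interval.start, f.id)
        ):
            iv = f.interval
            fh.write(
                "\t".join(
                    [
                        iv.seqid,
                        _GFF_SOURCE,
                        f.feature_class,
                        str(iv.start + 1),  # 0-based half-open -> 1-based inclusive
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        _encode_attrs(f),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> AnnotationSet:
    """Read GFF3 written by :func:`write_gff3` (or compatible) into an
    AnnotationSet; coordinates converted to 0-based half-open."""
    features: list[AnnotatedFeature] = []
    seq_lengths: dict[str, int] = {}
    max_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                try:
                    _, seqid, _start, end = line.split()
                    seq_lengths[seqid] = int(end)
                except ValueError as exc:
                    raise FileFormatError(f"{path}: line {lineno}: {exc}") from exc
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected 9 GFF3 columns, "
                    f"got {len(fields)}"
                )
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
            if strand not in ("+", "-"):
                raise FileFormatError(
                    f"{path}: line {lineno}: strandless features are not "
                    f"supported (strand {strand!r})"
                )
            try:
                iv = GenomicInterval(seqid, int(start1) - 1, int(end1), strand)
            except ValueError as exc:
                raise FileFormatError(f"{path}: line {lineno}: {exc}") from exc
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = attr.get("ID")
            if fid is None:
                raise FileFormatError(f"{path}: line {lineno}: missing ID attribute")
            fclass = attr.get("feature_class", ftype)
            if fclass not in FEATURE_CLASSES:
                raise FileFormatError(
                    f"{path}: line {lineno}: unknown feature class {fclass!r}"
                )
            features.append(
                AnnotatedFeature(
                    interval=iv,
                    id=fid,
                    feature_class=fclass,
                    regulons=frozenset(
                        x for x in attr.get("regulons", "").split(",") if x
                    ),
                    go_terms=frozenset(
                        x for x in attr.get("go_terms", "").split(",") if x
                    ),
                    pathways=frozenset(
                        x for x in attr.get("pathways", "").split(",") if x
                    ),
                    metabolic=attr.get("metabolic", "false") == "true",
                    operon_id=attr.get("operon_id"),
                )
            )
            max_end[seqid] = max(max_end.get(seqid, 0), iv.end)
    for seqid, end in max_end.items():
        seq_lengths.setdefault(seqid, end)
    return AnnotationSet(features=features, seq_lengths=seq_lengths)


# --- bedGraph -------------------------------------------------------------


def write_bedgraph(path: str | Path, seqid: str, values) -> None:
    """Write a per-base coverage vector as run-length-encoded bedGraph."""
    import numpy as np

    values = np.asarray(values)
    change = np.nonzero(np.diff(values))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            fh.write(f"{seqid}\t{s}\t{e}\t{_fmt_score(float(v))}\n")


def read_bedgraph(path: str | Path, length: int):
    """Read bedGraph into a dense per-base vector of the given length."""
    import numpy as np

    values = np.zeros(length)
    df = pd.read_csv(
        path, sep="\t", header=None, names=["seqid", "start", "end", "value"]
    )
    for row in df.itertuples(index=False):
        values[row.start : row.end] = row.value
    return values


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"
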