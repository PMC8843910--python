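"""Readers/writers for probe and segment tables, and probe-to-segment summaries.

File formats are plain TSV.  Coordinates are 0-based half-open (BED
convention) both in memory and on disk; every segment file carries a header
comment saying so.  Folded BAF is written with '.' when a segment has no
heterozygous probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeRecord",
    "SegmentRecord",
    "read_segments",
    "write_segments",
    "read_probes",
    "write_probes",
    "summarize_probes",
    "SEGMENT_COLUMNS",
    "PROBE_COLUMNS",
]

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end",
                   "n_probes", "n_het", "log2r", "folded_baf"]
PROBE_COLUMNS = ["chrom", "pos", "log2r", "baf", "is_het"]

_COORD_COMMENT = "# coordinates: 0-based half-open [start, end)"


class SegmentParseError(ValueError):
    """Malformed row in a segment/probe table; message names the line."""


@dataclass(frozen=True)
class ProbeRecord:
    chrom: str
    pos: int
    log2r: float
    baf: float
    is_het: bool

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")
        if not (0.0 <= self.baf <= 1.0):
            raise ValueError(f"baf must lie in [0, 1], got {self.baf}")


@dataclass(frozen=True)
class SegmentRecord:
    """One genomic segment with summary log2R and folded BAF.

    ``folded_baf`` is ``None`` exactly when the segment contains no
    germline-heterozygous probes (``n_het == 0``).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    n_het: int
    log2r: float
    folded_baf: float | None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.n_het > self.n_probes or self.n_het < 0:
            raise ValueError("n_het must lie in [0, n_probes]")
        if (self.folded_baf is None) != (self.n_het == 0):
            raise ValueError("folded_baf must be missing iff n_het == 0")
        if self.folded_baf is not None and not (0.0 <= self.folded_baf <= 0.5):
            raise ValueError(f"folded_baf must lie in [0, 0.5], got {self.folded_baf}")


def write_segments(records: Iterable[SegmentRecord], path: str | Path) -> None:
    """Write segments as TSV: deterministic column order, floats at 6 decimals,
    rows sorted by (sample_id, chrom, start)."""
    recs = sorted(records, key=lambda s: (s.sample_id, s.chrom, s.start))
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in recs:
            baf = "." if s.folded_baf is None else f"{s.folded_baf:.6f}"
            fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t"
                     f"{s.n_probes}\t{s.n_het}\t{s.log2r:.6f}\t{baf}\n")


def read_segments(path: str | Path) -> list[SegmentRecord]:
    """Read a segment TSV, validating every row; errors name the line number."""
    records: list[SegmentRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(SEGMENT_COLUMNS) - set(header)
                if missing:
                    raise SegmentParseError(
                        f"{path}: header missing columns {sorted(missing)}")
                continue
            row = dict(zip(header, fields))
            try:
                baf_raw = row["folded_baf"]
                records.append(SegmentRecord(
                    sample_id=row["sample_id"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    n_probes=int(row["n_probes"]),
                    n_het=int(row["n_het"]),
                    log2r=float(row["log2r"]),
                    folded_baf=None if baf_raw == "." else float(baf_raw),
                ))
            except (KeyError, ValueError) as exc:
                raise SegmentParseError(f"{path}:{lineno}: {exc}") from exc
    if header is None:
        raise SegmentParseError(f"{path}: empty file, no header")
    return records


def write_probes(probes: Iterable[ProbeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        fh.write("\t".join(PROBE_COLUMNS) + "\n")
        for p in probes:
            fh.write(f"{p.chrom}\t{p.pos}\t{p.log2r:.6f}\t{p.baf:.6f}\t"
                     f"{int(p.is_het)}\n")


def read_probes(path: str | Path) -> list[ProbeRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise SegmentParseError(f"{path}: header missing columns {sorted(missing)}")
    return [ProbeRecord(str(r.chrom), int(r.pos), float(r.log2r), float(r.baf),
                        bool(r.is_het))
            for r in df.itertuples(index=False)]


def summarize_probes(probes: Sequence[ProbeRecord],
                     interval: tuple[str, int, int],
                     sample_id: str = "sample") -> SegmentRecord:
    """Summarise probes inside a (chrom, start, end) interval into one segment.

    log2R is the median probe log2R; folded BAF is the median of
    min(baf, 1 - baf) over heterozygous probes (missing when there are
    none).  Medians, not means: robust to outlier probes.
    """
    chrom, start, end = interval
    inside = [p for p in probes if p.chrom == chrom and start <= p.pos < end]
    if not inside:
        raise ValueError(f"no probes in interval {chrom}:{start}-{end}")
    log2r = float(np.median([p.log2r for p in inside]))
    het = [p for p in inside if p.is_het]
    folded = (float(np.median([min(p.baf, 1.0 - p.baf) for p in het]))
              if het else None)
    return SegmentRecord(sample_id=sample_id, chrom=chrom, start=start, end=end,
                         n_probes=len(inside), n_het=len(het),
                         log2r=log2r, folded_baf=folded)
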