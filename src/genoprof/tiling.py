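"""Reduce per-base read-depth data to strand-separated fixed-width tile depths.

The tile is the atomic unit of expression measurement downstream: each strand
of the genome is divided into ``tile_size``-base windows (default 100) and the
depth of a tile is the SUM of per-base depths falling inside it.  Internal
coordinates are 0-based half-open; the samtools-depth dialect (1-based
positions) is converted on ingestion.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"
STRANDS = (FORWARD, REVERSE)

#: index into the strand axis of :attr:`TileDepthMatrix.depths`
STRAND_INDEX = {FORWARD: 0, REVERSE: 1}


@dataclass(frozen=True)
class GenomeAxis:
    """Coordinate frame shared by all tile-level containers.

    The final tile may be shorter than ``tile_size`` when the genome length is
    not a multiple of it; it is kept (and flagged via :attr:`has_short_final_tile`)
    rather than dropped.
    """

    sequence_id: str
    length: int
    tile_size: int = 100

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome length must be positive, got {self.length}")
        if self.tile_size <= 0:
            raise ValueError(f"tile_size must be positive, got {self.tile_size}")

    @property
    def n_tiles(self) -> int:
        return math.ceil(self.length / self.tile_size)

    @property
    def has_short_final_tile(self) -> bool:
        return self.length % self.tile_size != 0

    def tile_starts(self) -> np.ndarray:
        """0-based start coordinate of every tile."""
        return np.arange(self.n_tiles, dtype=np.int64) * self.tile_size

    def tile_of(self, pos0: int) -> int:
        """Tile index containing 0-based position ``pos0``."""
        return pos0 // self.tile_size

    def tile_interval(self, index: int) -> tuple[int, int]:
        """0-based half-open genomic interval of a tile."""
        start = index * self.tile_size
        return start, min(start + self.tile_size, self.length)


@dataclass
class LibraryMeta:
    """Bookkeeping for one sequencing library."""

    label: str
    raw_aligned_size: float = 0.0
    group: str | None = None


@dataclass
class TileDepthMatrix:
    """Per-library, per-strand, per-tile depth values.

    ``depths`` has shape ``(n_libraries, 2, n_tiles)`` with the strand axis
    ordered (forward, reverse).  All values are non-negative; tile order
    follows genome coordinates.
    """

    axis: GenomeAxis
    libraries: list[str]
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        expected = (len(self.libraries), 2, self.axis.n_tiles)
        if self.depths.shape != expected:
            raise ValueError(
                f"depths shape {self.depths.shape} does not match "
                f"(libraries, strands, tiles) = {expected}"
            )
        if len(set(self.libraries)) != len(self.libraries):
            raise ValueError("duplicate library labels")
        if np.any(self.depths < 0):
            raise ValueError("negative tile depth")

    @property
    def n_libraries(self) -> int:
        return len(self.libraries)

    def library_index(self, label: str) -> int:
        try:
            return self.libraries.index(label)
        except ValueError:
            raise KeyError(f"unknown library {label!r}") from None

    def raw_sizes(self) -> np.ndarray:
        """Total depth per library over both strands (the 'raw aligned size')."""
        return self.depths.sum(axis=(1, 2))

    def metas(self) -> list[LibraryMeta]:
        sizes = self.raw_sizes()
        return [LibraryMeta(lab, float(s)) for lab, s in zip(self.libraries, sizes)]

    def copy(self) -> "TileDepthMatrix":
        return TileDepthMatrix(self.axis, list(self.libraries), self.depths.copy())

    def equals(self, other: "TileDepthMatrix") -> bool:
        return (
            self.axis == other.axis
            and self.libraries == other.libraries
            and np.array_equal(self.depths, other.depths)
        )


def compute_tile_depths(
    records: Iterable[tuple[int, str, float]],
    axis: GenomeAxis,
    library: str = "lib",
) -> TileDepthMatrix:
    """Accumulate a stream of ``(position, strand, depth)`` records into tiles.

    Positions use the 1-based input convention (samtools depth).  Out-of-range
    positions are rejected with a logged warning and counted; a negative depth
    is a hard error.  Positions absent from the stream contribute zero.
    """
    depths = np.zeros((1, 2, axis.n_tiles))
    rejected = 0
    for pos, strand, depth in records:
        if depth < 0:
            raise ValueError(f"negative depth {depth} at position {pos}")
        if not 1 <= pos <= axis.length:
            rejected += 1
            continue
        depths[0, STRAND_INDEX[strand], axis.tile_of(pos - 1)] += depth
    if rejected:
        log.warning("rejected %d out-of-range depth records", rejected)
    matrix = TileDepthMatrix(axis, [library], depths)
    matrix.rejected_records = rejected  # type: ignore[attr-defined]
    return matrix


def collate_libraries(matrices: Sequence[TileDepthMatrix]) -> TileDepthMatrix:
    """Stack single-library matrices (sharing one axis) into one matrix."""
    if not matrices:
        raise ValueError("no matrices to collate")
    axis = matrices[0].axis
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for m in matrices:
        if m.axis != axis:
            raise ValueError(f"axis mismatch: {m.axis} != {axis}")
        for lab in m.libraries:
            if lab in labels:
                raise ValueError(f"duplicate library label {lab!r}")
            labels.append(lab)
        blocks.append(m.depths)
    return TileDepthMatrix(axis, labels, np.concatenate(blocks, axis=0))


# ---------------------------------------------------------------------------
# per-base depth readers


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_depth_tsv(path, strand: str) -> Iterator[tuple[int, str, float]]:
    """Yield records from a samtools-depth TSV (chrom, 1-based pos, depth)."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            yield int(parts[1]), strand, float(parts[2])


def iter_bedgraph(path, strand: str) -> Iterator[tuple[int, str, float]]:
    """Yield per-base records from a bedGraph (0-based half-open intervals)."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            for pos0 in range(start, end):
                yield pos0 + 1, strand, value


def iter_records(path, fmt: str, strand: str) -> Iterator[tuple[int, str, float]]:
    """Dispatch on an explicit format flag — the convention is never guessed."""
    if fmt == "depth-tsv":
        return iter_depth_tsv(path, strand)
    if fmt == "bedgraph":
        return iter_bedgraph(path, strand)
    raise ValueError(f"unknown depth format {fmt!r}")


def depths_from_sam(
    path,
    axis: GenomeAxis,
    library: str = "lib",
    protocol: str = "reverse",
) -> TileDepthMatrix:
    """Build tile depths from a SAM/BAM alignment.

    ``protocol='reverse'`` assumes a dUTP-style reverse-stranded library
    (read 1 aligns antisense to the transcript); ``'forward'`` flips that.
    Unmapped and secondary/supplementary reads are skipped.
    """
    import pysam

    if protocol not in ("reverse", "forward"):
        raise ValueError(f"unknown protocol {protocol!r}")
    depths = np.zeros((1, 2, axis.n_tiles))
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            sense_reverse = read.is_reverse
            if read.is_paired and read.is_read2:
                sense_reverse = not sense_reverse
            if protocol == "reverse":
                sense_reverse = not sense_reverse
            strand_idx = 1 if sense_reverse else 0
            for pos0 in read.get_reference_positions():
                if 0 <= pos0 < axis.length:
                    depths[0, strand_idx, axis.tile_of(pos0)] += 1
    return TileDepthMatrix(axis, [library], depths)


# ---------------------------------------------------------------------------
# tile CSV serialization

_CSV_FIXED = ["sequence_id", "strand", "tile_start"]


def write_tile_csv(matrix: TileDepthMatrix, path) -> None:
    """Write the collated tile depths as CSV (gzip if path ends in .gz)."""
    rows = []
    starts = matrix.axis.tile_starts()
    for strand in STRANDS:
        s = STRAND_INDEX[strand]
        for t in range(matrix.axis.n_tiles):
            row = {
                "sequence_id": matrix.axis.sequence_id,
                "strand": strand,
                "tile_start": int(starts[t]),
            }
            for i, lab in enumerate(matrix.libraries):
                row[lab] = matrix.depths[i, s, t]
            rows.append(row)
    df = pd.DataFrame(rows, columns=_CSV_FIXED + list(matrix.libraries))
    with _open_text(path, "wt") as fh:
        # metadata line preserves the axis (length may not be a tile multiple)
        fh.write(
            f"#length={matrix.axis.length},tile_size={matrix.axis.tile_size}\n"
        )
        df.to_csv(fh, index=False)


def read_tile_csv(path, tile_size: int = 100) -> TileDepthMatrix:
    """Read a tile CSV back into a :class:`TileDepthMatrix`.

    Rows are reordered to genome coordinate order; a missing fixed column or a
    non-numeric/negative depth is a hard error.
    """
    length = None
    with _open_text(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].strip().split(","))
            length = int(meta.get("length", 0)) or None
            tile_size = int(meta.get("tile_size", tile_size))
    df = pd.read_csv(path, comment="#")
    for col in _CSV_FIXED:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    libraries = [c for c in df.columns if c not in _CSV_FIXED]
    if not libraries:
        raise ValueError(f"no library columns in {path}")
    seq_ids = df["sequence_id"].unique()
    if len(seq_ids) != 1:
        raise ValueError(f"expected one sequence_id, found {list(seq_ids)}")
    df = df.sort_values(["sequence_id", "strand", "tile_start"], kind="stable")
    for lab in libraries:
        col = pd.to_numeric(df[lab], errors="coerce")
        bad = col.isna()
        if bad.any():
            raise ValueError(
                f"non-numeric depth in column {lab!r} at row {int(bad.idxmax())}"
            )
        if (col < 0).any():
            raise ValueError(f"negative depth in column {lab!r}")
        df[lab] = col
    max_start = int(df["tile_start"].max())
    strands = set(df["strand"])
    if not strands <= set(STRANDS):
        raise ValueError(f"unknown strand labels {strands - set(STRANDS)}")
    n_tiles = max_start // tile_size + 1
    if length is None:
        length = n_tiles * tile_size
    axis = GenomeAxis(str(seq_ids[0]), length, tile_size)
    if axis.n_tiles != n_tiles:
        raise ValueError(
            f"tile rows imply {n_tiles} tiles but length {length} gives {axis.n_tiles}"
        )
    depths = np.zeros((len(libraries), 2, n_tiles))
    for strand in strands:
        sub = df[df["strand"] == strand]
        idx = (sub["tile_start"].to_numpy() // tile_size).astype(int)
        depths[:, STRAND_INDEX[strand], idx] = sub[libraries].to_numpy().T
    return TileDepthMatrix(axis, libraries, depths)
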