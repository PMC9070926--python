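"""Emit expression colours as genome-browser features and overview rasters.

Colours are carried as Artemis-dialect ``/colour=R G B`` qualifiers on EMBL
feature-table records (and as a ``colour=R G B`` attribute in GFF3).  Internal
coordinates are 0-based half-open; flat-file locations are 1-based inclusive,
reverse-strand features written as ``complement(start..end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .encode import EncodingParams, encode, hsl_to_rgb
from .tiling import FORWARD, REVERSE, STRANDS, GenomeAxis, TileDepthMatrix

_EMBL_KEYS = {"tile": "misc_feature", "cds": "CDS", "rna": "misc_RNA"}
_KEYS_EMBL = {v: k for k, v in _EMBL_KEYS.items()}


@dataclass
class ColouredFeature:
    kind: str  # tile | cds | rna
    strand: str  # forward | reverse
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    colour: tuple[int, int, int]
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _EMBL_KEYS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"empty feature interval [{self.start},{self.end})")
        if any(not 0 <= c <= 255 for c in self.colour):
            raise ValueError(f"colour channels out of range: {self.colour}")

    def location_1based(self) -> tuple[int, int]:
        """EMBL/GFF 1-based inclusive coordinates."""
        return self.start + 1, self.end


def render_tiles(
    axis: GenomeAxis,
    colours: Sequence[Sequence[tuple[int, int, int]]],
    merge: bool = False,
) -> list[ColouredFeature]:
    """One feature per (strand, tile); optionally merge identical-colour runs."""
    if len(colours) != 2 or any(len(row) != axis.n_tiles for row in colours):
        raise ValueError("need one colour per (strand, tile)")
    feats: list[ColouredFeature] = []
    for s, strand in enumerate(STRANDS):
        t = 0
        while t < axis.n_tiles:
            start, end = axis.tile_interval(t)
            colour = tuple(colours[s][t])
            t2 = t + 1
            if merge:
                while t2 < axis.n_tiles and tuple(colours[s][t2]) == colour:
                    end = axis.tile_interval(t2)[1]
                    t2 += 1
            feats.append(ColouredFeature("tile", strand, start, end, colour))
            t = t2
    return feats


@dataclass
class AnnotatedFeature:
    """A CDS or RNA feature from the input annotation."""

    id: str
    kind: str  # cds | rna
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive


def feature_profile(
    feature: AnnotatedFeature, matrix: TileDepthMatrix
) -> np.ndarray:
    """Per-sample mean over the same-strand tiles the feature's span covers."""
    if not (0 <= feature.start < feature.end <= matrix.axis.length):
        raise ValueError(
            f"feature {feature.id} outside genome bounds "
            f"[{feature.start},{feature.end}) vs length {matrix.axis.length}"
        )
    t0 = matrix.axis.tile_of(feature.start)
    t1 = matrix.axis.tile_of(feature.end - 1)
    s = STRANDS.index(feature.strand)
    return matrix.depths[:, s, t0 : t1 + 1].mean(axis=1)


def render_genes(
    features: Iterable[AnnotatedFeature],
    matrix: TileDepthMatrix,
    params: EncodingParams,
) -> list[ColouredFeature]:
    """Colour each annotated feature by its averaged expression profile."""
    out = []
    for f in features:
        colour = hsl_to_rgb(encode(feature_profile(f, matrix), params))
        out.append(ColouredFeature(f.kind, f.strand, f.start, f.end, colour, f.id))
    return out


# ---------------------------------------------------------------------------
# flat-file writers / readers


def _sorted(features: Iterable[ColouredFeature]) -> list[ColouredFeature]:
    return sorted(features, key=lambda f: (f.start, f.end, f.strand, f.kind))


def write_embl_colour(
    features: Iterable[ColouredFeature], axis: GenomeAxis, path, sequence: str | None = None
) -> None:
    """EMBL feature-table flat file with Artemis ``/colour=R G B`` qualifiers."""
    with open(path, "w") as fh:
        fh.write(
            f"ID   {axis.sequence_id}; SV 1; linear; genomic DNA; STD; UNC; "
            f"{axis.length} BP.\n"
        )
        fh.write("FH   Key             Location/Qualifiers\n")
        fh.write("FH\n")
        for f in _sorted(features):
            lo, hi = f.location_1based()
            loc = f"{lo}..{hi}"
            if f.strand == REVERSE:
                loc = f"complement({loc})"
            key = _EMBL_KEYS[f.kind]
            fh.write(f"FT   {key:<16}{loc}\n")
            r, g, b = f.colour
            fh.write(f"FT                   /colour={r} {g} {b}\n")
            if f.label:
                fh.write(f'FT                   /label="{f.label}"\n')
        if sequence is not None:
            fh.write(f"SQ   Sequence {len(sequence)} BP;\n")
            for i in range(0, len(sequence), 60):
                fh.write(f"     {sequence[i:i+60].lower()}\n")
        fh.write("//\n")


def read_embl_colour(path) -> list[ColouredFeature]:
    """Strict re-reader for files produced by :func:`write_embl_colour`."""
    feats: list[ColouredFeature] = []
    current: ColouredFeature | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("FT   "):
                continue
            body = line[5:].rstrip("\n")
            if not body.startswith(" "):  # key + location line
                key, loc = body.split(None, 1)
                strand = FORWARD
                if loc.startswith("complement(") and loc.endswith(")"):
                    strand = REVERSE
                    loc = loc[len("complement(") : -1]
                lo, hi = (int(x) for x in loc.split(".."))
                current = ColouredFeature(
                    _KEYS_EMBL[key], strand, lo - 1, hi, (0, 0, 0)
                )
                feats.append(current)
            else:
                qual = body.strip()
                if current is None:
                    raise ValueError(f"{path}:{lineno}: qualifier before feature")
                if qual.startswith("/colour="):
                    current.colour = tuple(int(x) for x in qual[8:].split())
                elif qual.startswith('/label="'):
                    current.label = qual[8:-1]
    return feats


def write_gff_colour(features: Iterable[ColouredFeature], axis: GenomeAxis, path) -> None:
    """GFF3 with a ``colour=R G B`` attribute."""
    type_map = {"tile": "region", "cds": "CDS", "rna": "ncRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {axis.sequence_id} 1 {axis.length}\n")
        for i, f in enumerate(_sorted(features)):
            lo, hi = f.location_1based()
            strand = "+" if f.strand == FORWARD else "-"
            r, g, b = f.colour
            attrs = f"ID={f.label or f'feat{i}'};kind={f.kind};colour={r} {g} {b}"
            fh.write(
                f"{axis.sequence_id}\tgenoprof\t{type_map[f.kind]}\t{lo}\t{hi}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )


def read_gff_colour(path) -> list[ColouredFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            colour = tuple(int(x) for x in attrs.get("colour", "0 0 0").split())
            feats.append(
                ColouredFeature(
                    kind=attrs.get("kind", "tile"),
                    strand=FORWARD if cols[6] == "+" else REVERSE,
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    colour=colour,
                    label=attrs.get("ID"),
                )
            )
    return feats


# ---------------------------------------------------------------------------
# overview raster


@dataclass
class OverviewLayout:
    """Page-layout knobs for the whole-genome overview; aesthetics, not contract."""

    row_bp: int = 50_000
    px_per_bp: float = 0.01
    strip_h: int = 8
    dna_h: int = 2
    box_h: int = 10
    box_gap: int = 3
    row_gap: int = 12
    margin: int = 10
    key_h: int = 40

    @property
    def row_h(self) -> int:
        return (
            2 * (self.strip_h + self.box_gap + self.box_h)
            + self.dna_h
            + self.row_gap
        )


def render_overview(
    matrix: TileDepthMatrix,
    colours: Sequence[Sequence[tuple[int, int, int]]],
    annotation: Sequence[ColouredFeature] = (),
    layout: OverviewLayout | None = None,
):
    """Deterministic whole-genome raster: the genome wrapped over rows, tile
    strips either side of a DNA line, CDS boxes offset from it and RNA boxes
    adjacent, plus a key panel (hue x saturation at full lightness range).

    Returns a PIL image; save with ``img.save(path)`` (PNG output carries no
    timestamps, so identical inputs give identical bytes).
    """
    from PIL import Image

    lay = layout or OverviewLayout()
    axis = matrix.axis
    n_rows = -(-axis.length // lay.row_bp)
    row_px = max(1, int(lay.row_bp * lay.px_per_bp))
    width = row_px + 2 * lay.margin
    height = n_rows * lay.row_h + 2 * lay.margin + lay.key_h
    img = np.full((height, width, 3), 255, dtype=np.uint8)

    def bp_to_px(pos: int) -> tuple[int, int]:
        row, offset = divmod(pos, lay.row_bp)
        return row, lay.margin + int(offset * lay.px_per_bp)

    for row in range(n_rows):
        y0 = lay.margin + row * lay.row_h
        y_fwd_strip = y0 + lay.box_h + lay.box_gap
        y_dna = y_fwd_strip + lay.strip_h
        y_rev_strip = y_dna + lay.dna_h
        row_start = row * lay.row_bp
        row_end = min(row_start + lay.row_bp, axis.length)
        x_end = lay.margin + int((row_end - row_start) * lay.px_per_bp)
        img[y_dna : y_dna + lay.dna_h, lay.margin : max(x_end, lay.margin + 1)] = 0
        t0 = axis.tile_of(row_start)
        t1 = axis.tile_of(row_end - 1)
        for t in range(t0, t1 + 1):
            ts, te = axis.tile_interval(t)
            _, x0 = bp_to_px(max(ts, row_start))
            x1 = lay.margin + int((min(te, row_end) - row_start) * lay.px_per_bp)
            x1 = max(x1, x0 + 1)
            img[y_fwd_strip : y_fwd_strip + lay.strip_h, x0:x1] = colours[0][t]
            img[y_rev_strip : y_rev_strip + lay.strip_h, x0:x1] = colours[1][t]

    for f in annotation:
        r0, _ = bp_to_px(f.start)
        r1, _ = bp_to_px(max(f.start, f.end - 1))
        for row in range(r0, r1 + 1):
            y0 = lay.margin + row * lay.row_h
            y_dna = y0 + lay.box_h + lay.box_gap + lay.strip_h
            row_start = row * lay.row_bp
            row_end = min(row_start + lay.row_bp, axis.length)
            lo = max(f.start, row_start)
            hi = min(f.end, row_end)
            x0 = lay.margin + int((lo - row_start) * lay.px_per_bp)
            x1 = max(lay.margin + int((hi - row_start) * lay.px_per_bp), x0 + 1)
            if f.kind == "rna":  # adjacent to the DNA line, no offset
                if f.strand == FORWARD:
                    ya = y_dna - lay.strip_h
                else:
                    ya = y_dna + lay.dna_h
                yb = ya + lay.strip_h
            elif f.strand == FORWARD:  # offset above
                ya = y0
                yb = y0 + lay.box_h
            else:  # offset below
                ya = y_dna + lay.dna_h + lay.strip_h + lay.box_gap
                yb = ya + lay.box_h
            img[ya:yb, x0:x1] = f.colour
            img[ya, x0:x1] = 0  # border
            img[yb - 1, x0:x1] = 0

    # key panel: hue along x, saturation along y, at mid lightness
    import colorsys

    key_y = height - lay.key_h - lay.margin // 2
    key_w = min(width - 2 * lay.margin, 256)
    for yy in range(lay.key_h - 10):
        sat = 1.0 - yy / max(1, lay.key_h - 11)
        for xx in range(key_w):
            h = (xx / max(1, key_w - 1)) * (240.0 / 360.0)
            r, g, b = colorsys.hls_to_rgb(h, 0.65, sat)
            img[key_y + yy, lay.margin + xx] = (
                round(r * 255),
                round(g * 255),
                round(b * 255),
            )
    return Image.fromarray(img)
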