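"""Encode a per-locus expression vector over ordered sample points as HSL.

Channel semantics:

* lightness — clamped log of the maximum intensity; white at/below background,
  mid-grey (the lightness floor) at/above the upper clamp;
* saturation — squared relative range, ((max - min) / max)^2;
* hue — peak sample point mapped over part of the colour wheel (default 240
  degrees, red through the spectrum to blue), linearly adjusted up to halfway
  towards the larger neighbouring sample point in proportion to its intensity
  relative to the peak.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tiling import STRANDS, TileDepthMatrix


@dataclass
class EncodingParams:
    """Parameters of the three-channel encoding.

    ``hue_mode='spectrum'`` spreads peak time over ``hue_span_degrees`` from
    ``hue_start_degrees``; ``'two-colour'`` is a colour-vision-deficiency
    fallback ramping linearly between two primary hues (same maths, different
    anchors).
    """

    n_samples: int
    background: float
    upper_clamp: float
    hue_span_degrees: float = 240.0
    hue_start_degrees: float = 0.0
    lightness_floor: float = 0.5
    hue_mode: str = "spectrum"
    two_colour_hues: tuple[float, float] = (60.0, 240.0)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 sample points")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.upper_clamp <= self.background:
            raise ValueError("upper_clamp must exceed background")
        if not 0 < self.hue_span_degrees <= 360:
            raise ValueError("hue_span_degrees must be in (0, 360]")
        if not 0 < self.lightness_floor < 1:
            raise ValueError("lightness_floor must be in (0,1)")
        if self.hue_mode not in ("spectrum", "two-colour"):
            raise ValueError(f"unknown hue_mode {self.hue_mode!r}")


@dataclass(frozen=True)
class HslColour:
    hue: float  # degrees in [0, 360)
    saturation: float  # [0, 1]
    lightness: float  # [0, 1]


def estimate_background(matrix: TileDepthMatrix) -> float:
    """Noise floor: double the median per-tile average of the less-expressed strand.

    For every tile position the per-library average intensity is computed for
    each strand; the smaller of the two is that locus's least-expressed-strand
    value, and the background is twice the median of those values.
    """
    if matrix.depths.shape[1] != 2:
        raise ValueError("background estimation needs both strands")
    strand_avg = matrix.depths.mean(axis=0)  # (2, n_tiles)
    least = strand_avg.min(axis=0)
    return 2.0 * float(np.median(least))


def upper_clamp(matrix: TileDepthMatrix, percentile: float = 99.0) -> float:
    """Intensity cap: the given percentile (linear interpolation between order
    statistics) of tile intensities at the most-expressed sample point, i.e.
    the library with the largest total normalized depth."""
    if matrix.depths.size == 0:
        raise ValueError("empty matrix")
    totals = matrix.raw_sizes()
    top = int(np.argmax(totals))
    return float(np.percentile(matrix.depths[top].ravel(), percentile))


def lightness(max_intensity: float, params: EncodingParams) -> float:
    """Log-mapped lightness: 1 (white) at/below background, floor at/above clamp."""
    span = params.upper_clamp - params.background
    i = min(max(max_intensity - params.background, 0.0), span)
    return 1.0 - (1.0 - params.lightness_floor) * math.log1p(i) / math.log1p(span)


def invert_lightness(value: float, params: EncodingParams) -> float:
    """Recover the clamped, background-subtracted intensity from a lightness."""
    span = params.upper_clamp - params.background
    frac = (1.0 - value) / (1.0 - params.lightness_floor)
    return math.expm1(frac * math.log1p(span))


def saturation(profile: np.ndarray) -> float:
    """((max - min) / max)^2, zero for an all-zero profile."""
    profile = np.asarray(profile, dtype=float)
    mx = float(profile.max())
    if mx <= 0:
        return 0.0
    return float(((mx - profile.min()) / mx) ** 2)


def _hue_anchors(params: EncodingParams) -> np.ndarray:
    n = params.n_samples
    if params.hue_mode == "two-colour":
        lo, hi = params.two_colour_hues
        return np.linspace(lo, hi, n)
    return params.hue_start_degrees + np.linspace(0.0, params.hue_span_degrees, n)


def hue(profile: np.ndarray, params: EncodingParams) -> float:
    """Peak-time hue with a linear shift up to halfway towards the larger
    neighbour, proportional to neighbour/peak intensity.

    The peak is the earliest maximum; an equal-valued later sample acts as an
    equal neighbour and pulls exactly halfway.  When both neighbours are equal
    the pulls cancel and no shift is applied.  Endpoints can only shift inward.
    An all-zero profile returns hue 0 (saturation is 0, colour irrelevant).
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) != params.n_samples:
        raise ValueError("profile length does not match n_samples")
    mx = float(profile.max())
    if mx <= 0:
        return 0.0
    anchors = _hue_anchors(params)
    spacing = float(anchors[1] - anchors[0])
    p = int(np.argmax(profile))
    left = float(profile[p - 1]) if p > 0 else None
    right = float(profile[p + 1]) if p < len(profile) - 1 else None
    anchor = float(anchors[p])
    if left is not None and right is not None and left == right:
        return anchor % 360.0
    cand = [(v, sign) for v, sign in ((left, -1.0), (right, 1.0)) if v is not None]
    nb, sign = max(cand, key=lambda t: t[0])
    shift = sign * (nb / mx) * 0.5 * spacing
    return (anchor + shift) % 360.0


def encode(profile: np.ndarray, params: EncodingParams) -> HslColour:
    profile = np.asarray(profile, dtype=float)
    return HslColour(
        hue=hue(profile, params),
        saturation=saturation(profile),
        lightness=lightness(float(profile.max()), params),
    )


def hsl_to_rgb(colour: HslColour) -> tuple[int, int, int]:
    """Standard bi-hexcone HSL -> 8-bit RGB (via colorsys, HLS argument order)."""
    r, g, b = colorsys.hls_to_rgb(
        (colour.hue % 360.0) / 360.0, colour.lightness, colour.saturation
    )
    return (round(r * 255), round(g * 255), round(b * 255))


# ---------------------------------------------------------------------------
# whole-matrix helpers


def auto_params(
    matrix: TileDepthMatrix,
    background: float | None = None,
    clamp: float | None = None,
    **kwargs,
) -> EncodingParams:
    """Build params for a replicate-merged matrix, estimating the background
    and upper clamp from the data unless given explicitly."""
    bg = estimate_background(matrix) if background is None else background
    uc = upper_clamp(matrix) if clamp is None else clamp
    if uc <= bg:  # degenerate fixture; keep the mapping well-defined
        uc = bg + 1.0
    return EncodingParams(
        n_samples=matrix.n_libraries, background=bg, upper_clamp=uc, **kwargs
    )


def encode_matrix(
    matrix: TileDepthMatrix, params: EncodingParams
) -> list[list[tuple[HslColour, tuple[int, int, int]]]]:
    """Encode every (strand, tile) profile; returns [strand][tile] pairs."""
    out: list[list[tuple[HslColour, tuple[int, int, int]]]] = []
    for s in range(2):
        row = []
        for t in range(matrix.axis.n_tiles):
            c = encode(matrix.depths[:, s, t], params)
            row.append((c, hsl_to_rgb(c)))
        out.append(row)
    return out


def colour_table(matrix: TileDepthMatrix, params: EncodingParams) -> pd.DataFrame:
    """Tabulate per-tile colours (id, strand, tile_start, H, S, L, R, G, B)."""
    rows = []
    encoded = encode_matrix(matrix, params)
    starts = matrix.axis.tile_starts()
    for s, strand in enumerate(STRANDS):
        for t in range(matrix.axis.n_tiles):
            c, rgb = encoded[s][t]
            rows.append(
                {
                    "id": f"tile_{strand[0]}_{t}",
                    "strand": strand,
                    "tile_start": int(starts[t]),
                    "H": c.hue,
                    "S": c.saturation,
                    "L": c.lightness,
                    "R": rgb[0],
                    "G": rgb[1],
                    "B": rgb[2],
                }
            )
    return pd.DataFrame(rows)
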