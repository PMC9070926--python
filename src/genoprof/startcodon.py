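"""Score candidate start codons: RBS weight matrix, translational coupling,
codon-type strength; select the best start and report a confidence ratio.

Combined score = (rbs_score + coupling_score) * type_score with type scores
ATG 16, GTG 4, TTG 1.  RBS evidence near a start is aggregated under a 9-base
symmetric triangle whose centre sits 7 bases upstream of the start codon
(schematically tvaGGAGnnnnnnnATG), with each ribosome-binding position's
contribution shared among all candidate starts visible to it so that motifs
serving several potential initiations are down-weighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
START_CODONS = ("ATG", "GTG", "TTG")
TYPE_SCORES = {"ATG": 16.0, "GTG": 4.0, "TTG": 1.0}

#: triangle weights over the 9 positions centred at the ideal spacing,
#: peak 5 falling by 1 per position, normalized to sum 1
TRIANGLE = np.array([1, 2, 3, 4, 5, 4, 3, 2, 1], dtype=float) / 25.0
#: offset of the triangle centre (motif 3' end) upstream of the start codon:
#: 7 intervening bases, so the last motif base sits 8 before the start
CENTRE_OFFSET = 8
HALF_WINDOW = 4

COUPLING_PEAK_OFFSET = -4
COUPLING_SHOULDER = 8.0 / 22.0


@dataclass
class RbsMatrix:
    """Position weight matrix with a scoring threshold and linear ramp.

    Raw scores >= ``threshold`` give full RBS potential (1.0); scores within
    ``ramp`` below it are scored linearly down to zero.
    """

    weights: np.ndarray  # (width, 4), columns A C G T
    threshold: float = 2.54
    ramp: float = 0.4

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("matrix must have shape (width, 4)")
        if self.ramp <= 0:
            raise ValueError("ramp must be positive")

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.weights, axis=1))

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())


def load_matrix(path, threshold: float = 2.54, ramp: float = 0.4) -> RbsMatrix:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            parts = line.split("\t")
            rows.append([float(x) for x in parts[1:5]])
    return RbsMatrix(np.array(rows), threshold, ramp)


def default_matrix(threshold: float = 2.54, ramp: float = 0.4) -> RbsMatrix:
    with resources.as_file(
        resources.files("genoprof.data").joinpath("rbs_matrix.tsv")
    ) as p:
        return load_matrix(p, threshold, ramp)


def ramp_potential(raw: float, matrix: RbsMatrix) -> float:
    """Map a raw matrix score to RBS potential in [0, 1]."""
    if raw >= matrix.threshold:
        return 1.0
    lo = matrix.threshold - matrix.ramp
    if raw <= lo:
        return 0.0
    return (raw - lo) / matrix.ramp


def scan_rbs(sequence: str, matrix: RbsMatrix) -> np.ndarray:
    """RBS potential for every base position of the sequence.

    The value at index ``j`` is the ramped potential of the motif placement
    whose LAST base is at ``j`` (the triangle in :func:`aggregate_rbs` is
    indexed by the same anchor).  Positions with no complete placement are 0.
    Ambiguous bases take the minimum column weight (logged once via warnings).
    """
    sequence = sequence.upper()
    w = matrix.width
    n = len(sequence)
    potentials = np.zeros(n)
    if n < w:
        return potentials
    col_min = matrix.weights.min(axis=1)
    # integer-encode; ambiguity sentinel 4
    enc = np.fromiter(
        (BASE_INDEX.get(b, 4) for b in sequence), dtype=np.int64, count=n
    )
    padded = np.hstack([matrix.weights, col_min[:, np.newaxis]])  # (w, 5)
    raw = np.zeros(n - w + 1)
    for k in range(w):
        raw += padded[k, enc[k : k + n - w + 1]]
    for i, r in enumerate(raw):
        potentials[i + w - 1] = ramp_potential(float(r), matrix)
    return potentials


def find_starts(sequence: str) -> list[tuple[int, str]]:
    """All (position, codon) start-codon occurrences on the given strand."""
    sequence = sequence.upper()
    return [
        (i, sequence[i : i + 3])
        for i in range(len(sequence) - 2)
        if sequence[i : i + 3] in START_CODONS
    ]


def _triangle_weight(start_pos: int, anchor: int) -> float:
    """Triangle weight a start assigns to a ribosome-binding anchor position."""
    k = anchor - (start_pos - CENTRE_OFFSET) + HALF_WINDOW
    if 0 <= k < len(TRIANGLE):
        return float(TRIANGLE[k])
    return 0.0


def aggregate_rbs(
    potentials: np.ndarray,
    start_pos: int,
    start_codon: str,
    visible_starts: Sequence[tuple[int, str]] | None = None,
) -> float:
    """Aggregate per-position RBS potential for one candidate start.

    Weighted sum over the 9-position triangle centred ``CENTRE_OFFSET`` bases
    upstream; each position's contribution is multiplied by this start's share
    (type_score x triangle weight over the sum across all starts visible to
    that position), implementing the ATG-depletion down-weighting.  With a
    single visible start the shares are all 1 and the result is the plain
    triangle-weighted sum (hence in [0, 1]).
    """
    if visible_starts is None:
        visible_starts = [(start_pos, start_codon)]
    total = 0.0
    centre = start_pos - CENTRE_OFFSET
    for anchor in range(centre - HALF_WINDOW, centre + HALF_WINDOW + 1):
        if not 0 <= anchor < len(potentials):
            continue
        p = float(potentials[anchor])
        if p == 0.0:
            continue
        w_self = TYPE_SCORES[start_codon] * _triangle_weight(start_pos, anchor)
        denom = sum(
            TYPE_SCORES[c] * _triangle_weight(s, anchor)
            for s, c in visible_starts
            if _triangle_weight(s, anchor) > 0.0
        )
        if denom <= 0.0:
            continue
        share = w_self / denom
        total += p * _triangle_weight(start_pos, anchor) * share
    return total


def coupling_score(offset: int | None) -> float:
    """Translational-coupling score from the start-vs-upstream-stop offset.

    Offset is the signed position of the start codon relative to the upstream
    gene's stop codon: -4 means the last two bases of the start overlap the
    stop (the maximum).  Piecewise: 0 at/beyond -25, linear to 8/22 at -7,
    linear to 1 at -4, linear back to 8/22 at -1, then exponential decay with
    a halving distance of 100 bases.  No upstream gene in range scores 0.
    """
    if offset is None:
        return 0.0
    if offset <= -25:
        return 0.0
    if offset <= -7:
        return COUPLING_SHOULDER * (offset + 25) / 18.0
    if offset <= -4:
        return COUPLING_SHOULDER + (1.0 - COUPLING_SHOULDER) * (offset + 7) / 3.0
    if offset <= -1:
        return 1.0 - (1.0 - COUPLING_SHOULDER) * (offset + 4) / 3.0
    return COUPLING_SHOULDER * 2.0 ** (-(offset + 1) / 100.0)


def codon_type_score(codon: str) -> float:
    """ATG -> 16, GTG -> 4, TTG -> 1."""
    try:
        return TYPE_SCORES[codon.upper()]
    except KeyError:
        raise ValueError(f"{codon!r} is not a candidate start codon") from None


@dataclass
class StartCandidate:
    orf_id: str
    position: int  # strand-local 0-based position of the start codon
    codon: str
    coupling_offset: int | None = None
    review_only: bool = False  # >10 codons inside the first homology hit


@dataclass
class StartScore:
    candidate: StartCandidate
    rbs_score: float
    coupling_score: float
    type_score: float
    combined: float = field(init=False)

    def __post_init__(self) -> None:
        self.combined = (self.rbs_score + self.coupling_score) * self.type_score


def score_candidates(
    sequence: str,
    candidates: Iterable[StartCandidate],
    matrix: RbsMatrix | None = None,
    potentials: np.ndarray | None = None,
    visible_starts: Sequence[tuple[int, str]] | None = None,
) -> list[StartScore]:
    """Score every candidate of one ORF against a (strand-local) sequence."""
    matrix = matrix or default_matrix()
    if potentials is None:
        potentials = scan_rbs(sequence, matrix)
    if visible_starts is None:
        visible_starts = find_starts(sequence)
    return [
        StartScore(
            candidate=c,
            rbs_score=aggregate_rbs(potentials, c.position, c.codon, visible_starts),
            coupling_score=coupling_score(c.coupling_offset),
            type_score=codon_type_score(c.codon),
        )
        for c in candidates
    ]


@dataclass
class StartSelection:
    chosen: StartScore | None
    confidence_ratio: float  # inf when only one candidate; nan when none
    flagged: bool = False  # no auto-selectable candidate


def select_start(scores: Sequence[StartScore]) -> StartSelection:
    """Pick the best-scoring eligible candidate; ties go to the most upstream.

    Review-only candidates (more than 10 codons inside the first homology hit)
    are never auto-selected.  The confidence ratio is best/second-best over the
    eligible candidates, infinity when only one exists.
    """
    eligible = [s for s in scores if not s.candidate.review_only]
    if not eligible:
        return StartSelection(None, math.nan, flagged=True)
    ranked = sorted(eligible, key=lambda s: (-s.combined, s.candidate.position))
    best = ranked[0]
    if len(ranked) == 1:
        return StartSelection(best, math.inf)
    second = ranked[1].combined
    ratio = math.inf if second == 0 else best.combined / second
    return StartSelection(best, ratio)
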