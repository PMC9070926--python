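"""ORF enumeration, reciprocal-best-hit orthology, RNA-overlap resolution and
iterative suspicion-score filtering.

An ORF is a maximal same-frame segment ending in a stop codon (TAA/TAG/TGA)
that contains at least one in-frame candidate start (ATG/GTG/TTG).  ORFs are
tracked in strand-local coordinates (positions on the reverse complement for
the minus strand) with converters to genomic intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "TTG")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Orf:
    """One open reading frame.  Local coordinates are on the coding strand."""

    id: str
    strand: str  # '+' or '-'
    genome_length: int
    candidate_starts: list[int]  # local 0-based, ascending
    stop_end: int  # local, exclusive end of the stop codon
    current_start_index: int = 0
    evidence: set = field(default_factory=set)

    @property
    def current_start(self) -> int:
        return self.candidate_starts[self.current_start_index]

    @property
    def length(self) -> int:
        """nt from the current start codon through the stop codon."""
        return self.stop_end - self.current_start

    def genomic_interval(self, start_index: int | None = None) -> tuple[int, int]:
        """0-based half-open interval on the forward genome axis."""
        i = self.current_start_index if start_index is None else start_index
        lo, hi = self.candidate_starts[i], self.stop_end
        if self.strand == "+":
            return lo, hi
        return self.genome_length - hi, self.genome_length - lo


def enumerate_orfs(genome: str, min_length: int = 90) -> list[Orf]:
    """Six-frame scan for stop-terminated ORFs with at least one start codon.

    Every maximal stop-to-stop (or sequence-edge-to-stop) frame segment with a
    candidate start and length >= ``min_length`` (first start through stop)
    yields one ORF.  Trailing segments with no stop codon are not ORFs.
    """
    genome = genome.upper()
    n = len(genome)
    orfs: list[Orf] = []
    counter = 0
    for strand, seq in (("+", genome), ("-", revcomp(genome))):
        for frame in range(3):
            starts: list[int] = []
            for pos in range(frame, n - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in STOP_CODONS:
                    if starts and pos + 3 - starts[0] >= min_length:
                        counter += 1
                        orfs.append(
                            Orf(
                                id=f"orf{counter:05d}",
                                strand=strand,
                                genome_length=n,
                                candidate_starts=starts,
                                stop_end=pos + 3,
                            )
                        )
                    starts = []
                elif codon in START_CODONS:
                    starts.append(pos)
    return orfs


# ---------------------------------------------------------------------------
# reciprocal best hits


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float = 0.0
    identity: float = 100.0
    query_start: int = 0
    query_end: int = 0


_OUTFMT6 = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def parse_outfmt6(path) -> pd.DataFrame:
    """Read a BLAST outfmt-6-style TSV into a hit table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(
            f"{path}: expected >=12 outfmt-6 columns, found {df.shape[1]}"
        )
    df = df.iloc[:, :12]
    df.columns = _OUTFMT6
    return df


def hits_frame(hits: Iterable[HitRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        return hits
    return pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "bitscore": h.bitscore,
                "evalue": h.evalue,
            }
            for h in hits
        ]
    )


def best_hits(hits: Iterable[HitRecord] | pd.DataFrame) -> dict[str, str]:
    """Best subject per query: highest bitscore, ties broken by lower e-value
    then lexicographic subject id.  Duplicate rows reduce to their best."""
    df = hits_frame(hits)
    if df.empty:
        return {}
    if "evalue" not in df.columns:
        df = df.assign(evalue=0.0)
    df = df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    top = df.drop_duplicates("qseqid", keep="first")
    return dict(zip(top["qseqid"], top["sseqid"]))


def reciprocal_best_hits(
    hits_q_to_ref: Iterable[HitRecord] | pd.DataFrame,
    hits_ref_to_q: Iterable[HitRecord] | pd.DataFrame,
) -> set[tuple[str, str]]:
    """Pairs (q, r) where r is q's best hit and q is r's best hit."""
    fwd = best_hits(hits_q_to_ref)
    rev = best_hits(hits_ref_to_q)
    return {(q, r) for q, r in fwd.items() if rev.get(r) == q}


# ---------------------------------------------------------------------------
# RNA-feature overlap resolution


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def resolve_rna_overlaps(
    orfs: Sequence[Orf],
    rna_features: Sequence[tuple[int, int]],
    remnant_min: int = 90,
) -> tuple[list[Orf], list[tuple[str, str]]]:
    """Trim or discard no-evidence ORFs overlapping RNA features.

    ORFs carrying RBH evidence are exempt.  A conflicting ORF is advanced to
    the first candidate start whose span clears every feature; if none exists
    or the remnant is shorter than ``remnant_min`` the ORF is discarded.
    Returns (surviving orfs, log of (orf_id, action)).
    """
    kept: list[Orf] = []
    actions: list[tuple[str, str]] = []
    for orf in orfs:
        if orf.evidence & {"rbh_tier1", "rbh_tier2"}:
            kept.append(orf)
            continue
        if not any(_overlap(orf.genomic_interval(), f) for f in rna_features):
            kept.append(orf)
            continue
        chosen = None
        for i in range(orf.current_start_index, len(orf.candidate_starts)):
            iv = orf.genomic_interval(i)
            if not any(_overlap(iv, f) for f in rna_features):
                chosen = i
                break
        if chosen is None or orf.stop_end - orf.candidate_starts[chosen] < remnant_min:
            actions.append((orf.id, "discarded"))
            continue
        if chosen != orf.current_start_index:
            orf.current_start_index = chosen
            actions.append((orf.id, "trimmed"))
        kept.append(orf)
    return kept, actions


# ---------------------------------------------------------------------------
# suspicion scoring and iterative filtering


@dataclass
class SuspicionConfig:
    """Double cut-offs for the four 0/1/2-point components (defaults are
    declared conventions, configurable; none are literature values)."""

    start_ratio_good: float = 2.0  # confidence ratio for 0 points
    start_percentile_bad: float = 10.0  # combined below this pctile -> 2
    length_good: int = 300
    length_bad: int = 150
    strand_ratio_good: float = 2.0  # same:antisense depth ratio
    strand_ratio_bad: float = 0.5
    overlap_minor: int = 30  # nt; below this overlap scores 1, else 2


@dataclass
class SuspicionScore:
    points_start: int
    points_length: int
    points_strand_ratio: int
    points_overlap: int
    flagged: bool = False  # missing RNA-seq data, strand component neutral

    @property
    def total(self) -> int:
        return (
            self.points_start
            + self.points_length
            + self.points_strand_ratio
            + self.points_overlap
        )


@dataclass
class OrfEvidence:
    """Static per-ORF inputs to suspicion scoring."""

    orf: Orf
    confidence_ratio: float
    combined_score: float
    strand_ratio: float | None  # same-strand : antisense depth; None = missing


def suspicion_score(
    ev: OrfEvidence,
    overlap_nt: int,
    combined_median: float,
    combined_p10: float,
    config: SuspicionConfig | None = None,
) -> SuspicionScore:
    cfg = config or SuspicionConfig()
    if ev.combined_score < combined_p10:
        pts_start = 2
    elif ev.confidence_ratio >= cfg.start_ratio_good and ev.combined_score >= combined_median:
        pts_start = 0
    else:
        pts_start = 1
    length = ev.orf.length
    if length >= cfg.length_good:
        pts_len = 0
    elif length < cfg.length_bad:
        pts_len = 2
    else:
        pts_len = 1
    flagged = ev.strand_ratio is None
    if flagged:
        pts_strand = 1
    elif ev.strand_ratio >= cfg.strand_ratio_good:
        pts_strand = 0
    elif ev.strand_ratio <= cfg.strand_ratio_bad:
        pts_strand = 2
    else:
        pts_strand = 1
    if overlap_nt == 0:
        pts_overlap = 0
    elif overlap_nt < cfg.overlap_minor:
        pts_overlap = 1
    else:
        pts_overlap = 2
    return SuspicionScore(pts_start, pts_len, pts_strand, pts_overlap, flagged)


def iterative_filter(
    evidences: Sequence[OrfEvidence],
    fixed_features: Sequence[tuple[int, int]] = (),
    max_score_final: int = 5,
    config: SuspicionConfig | None = None,
) -> tuple[list[OrfEvidence], list[tuple[str, int, int]]]:
    """Iteratively remove the most suspicious ORFs, lowering the permitted
    score from 8 down to ``max_score_final``.

    Removing an ORF can only lower the overlap component of the others, so the
    schedule terminates.  Within a round the highest-scoring ORF (coordinate
    order on ties) is removed first and scores are recomputed.  Returns
    (survivors, removal log of (orf_id, score at removal, cutoff)).
    """
    cfg = config or SuspicionConfig()
    combined = sorted(ev.combined_score for ev in evidences)
    if combined:
        n = len(combined)
        median = combined[n // 2] if n % 2 else 0.5 * (
            combined[n // 2 - 1] + combined[n // 2]
        )
        p10 = combined[max(0, int(cfg.start_percentile_bad / 100.0 * n) - 1)]
    else:
        median = p10 = 0.0

    survivors = list(evidences)
    removal_log: list[tuple[str, int, int]] = []

    def max_overlap(ev: OrfEvidence, pool: Sequence[OrfEvidence]) -> int:
        iv = ev.orf.genomic_interval()
        best = 0
        for other in pool:
            if other is ev:
                continue
            best = max(best, _overlap(iv, other.orf.genomic_interval()))
        for f in fixed_features:
            best = max(best, _overlap(iv, f))
        return best

    for cutoff in range(8, max_score_final - 1, -1):
        while True:
            scored = [
                (ev, suspicion_score(ev, max_overlap(ev, survivors), median, p10, cfg))
                for ev in survivors
            ]
            over = [(ev, s) for ev, s in scored if s.total > cutoff]
            if not over:
                break
            over.sort(key=lambda t: (-t[1].total, t[0].orf.genomic_interval()[0]))
            victim, vscore = over[0]
            survivors.remove(victim)
            removal_log.append((victim.orf.id, vscore.total, cutoff))
    return survivors, removal_log


# ---------------------------------------------------------------------------
# gaps


def gap_report(
    genome_length: int,
    features: Sequence[tuple[int, int]],
    min_gap: int = 300,
) -> list[tuple[int, int]]:
    """Unannotated stretches longer than ``min_gap`` (0-based half-open)."""
    gaps = []
    pos = 0
    for start, end in sorted(features):
        if start - pos > min_gap:
            gaps.append((pos, start))
        pos = max(pos, end)
    if genome_length - pos > min_gap:
        gaps.append((pos, genome_length))
    return gaps


def write_bed(intervals: Sequence[tuple[int, int]], chrom: str, path) -> None:
    with open(path, "w") as fh:
        for start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
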