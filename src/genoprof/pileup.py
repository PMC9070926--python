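"""Parse samtools-mpileup text, call non-ambiguous differences and apply them.

A difference is called only when the top non-reference allele reaches a
support-fraction threshold at sufficient depth; everything else is listed in an
ambiguous-site report, never auto-called.  Only substitutions and single-base
indels are callable; indels inside homopolymer runs are left-normalized to the
run's canonical position (VCF convention: the anchor base before the event).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

log = logging.getLogger(__name__)

SUBSTITUTION = "substitution"
DELETION_1BP = "deletion_1bp"
INSERTION_1BP = "insertion_1bp"

_INDEL_RE = re.compile(r"[+-](\d+)")


@dataclass
class PileupColumn:
    chrom: str
    position: int  # 1-based
    ref_base: str
    depth: int
    counts: Counter = field(default_factory=Counter)
    # allele keys: 'A'/'C'/'G'/'T' (substituted base), '=' (ref match),
    # '+SEQ' (insertion after this base), '-SEQ' (deletion of following bases),
    # '*' (base deleted by an upstream event)


def parse_bases(bases: str, ref_base: str, chrom: str, position: int) -> Counter:
    """Count alleles in one mpileup base string.

    Handles ``.``/``,`` matches, case-folded mismatches, ``^X`` read starts
    (mapping-quality character consumed), ``$`` read ends and ``+n``/``-n``
    indel strings.  A malformed indel length is a hard error.
    """
    counts: Counter = Counter()
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # mapping-quality char consumed
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise ValueError(
                    f"{chrom}:{position}: malformed indel length in {bases!r}"
                )
            length = int(m.group(1))
            seq_start = m.end()
            seq = bases[seq_start : seq_start + length]
            if len(seq) != length:
                raise ValueError(
                    f"{chrom}:{position}: indel sequence shorter than declared"
                )
            counts[c + seq.upper()] += 1
            i = seq_start + length
            continue
        if c in ".,":
            counts["="] += 1
        elif c.upper() in "ACGTN":
            counts[c.upper()] += 1
        elif c == "*":
            counts["*"] += 1
        # other symbols (e.g. '>' '<' reference skips) are ignored
        i += 1
    return counts


def parse_pileup(stream: TextIO | Iterable[str]) -> Iterator[PileupColumn]:
    """Yield columns from samtools mpileup text (chrom pos ref depth bases quals)."""
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ValueError(f"pileup line {lineno}: expected >=5 columns")
        chrom, pos, ref, depth = parts[0], int(parts[1]), parts[2].upper(), int(parts[3])
        counts = parse_bases(parts[4], ref, chrom, int(pos))
        yield PileupColumn(chrom, pos, ref, depth, counts)


@dataclass
class DifferenceCall:
    position: int  # 1-based; indels anchored VCF-style on the base before
    kind: str
    ref_allele: str
    alt_allele: str
    support_fraction: float
    depth: int


@dataclass
class AmbiguousSite:
    position: int
    reason: str
    depth: int
    counts: dict


def _homopolymer_left(genome: str, pos0: int) -> int:
    """Leftmost 0-based index of the homopolymer run containing ``pos0``."""
    base = genome[pos0]
    while pos0 > 0 and genome[pos0 - 1] == base:
        pos0 -= 1
    return pos0


def call_differences(
    columns: Iterable[PileupColumn],
    genome: str,
    min_depth: int = 10,
    min_fraction: float = 0.9,
) -> tuple[list[DifferenceCall], list[AmbiguousSite]]:
    """Emit non-ambiguous substitution / 1-bp indel calls.

    A call requires the top non-reference allele to reach ``min_fraction`` of
    the counted alleles at depth >= ``min_depth``.  Longer indels and columns
    with a prominent but under-threshold allele go to the ambiguous report.
    ``genome`` (the reference being corrected) is needed for homopolymer
    left-normalization of indels.
    """
    calls: list[DifferenceCall] = []
    ambiguous: list[AmbiguousSite] = []
    base_keys = ("=", "A", "C", "G", "T", "N", "*")
    for col in columns:
        # one read contributes one base-level symbol; an indel string rides on
        # the same read, so reads are counted at base level only
        counted = sum(col.counts.get(k, 0) for k in base_keys)
        if counted == 0:  # degenerate column carrying only indel strings
            counted = sum(v for k, v in col.counts.items())
        if counted == 0:
            continue
        non_ref = {k: v for k, v in col.counts.items() if k not in ("=", "*", "N")}
        if not non_ref:
            continue
        allele, support = max(non_ref.items(), key=lambda kv: (kv[1], kv[0]))
        fraction = support / counted
        if counted < min_depth or fraction < min_fraction:
            ambiguous.append(
                AmbiguousSite(
                    col.position, "below_threshold", counted, dict(col.counts)
                )
            )
            continue
        pos0 = col.position - 1
        if allele in "ACGT":
            calls.append(
                DifferenceCall(
                    col.position, SUBSTITUTION, col.ref_base, allele, fraction, counted
                )
            )
        elif allele.startswith(("+", "-")) and len(allele) == 2:
            base = allele[1]
            kind = INSERTION_1BP if allele[0] == "+" else DELETION_1BP
            # normalize into the homopolymer run: anchor before the run start
            event0 = pos0 + 1  # first affected/inserted base
            if event0 < len(genome) and genome[event0] == base:
                anchor0 = _homopolymer_left(genome, event0) - 1
            elif genome[pos0] == base:
                anchor0 = _homopolymer_left(genome, pos0) - 1
            else:
                anchor0 = pos0
            anchor0 = max(anchor0, 0)
            anchor = genome[anchor0]
            if kind == DELETION_1BP:
                ref_allele = anchor + genome[anchor0 + 1]
                alt_allele = anchor
            else:
                ref_allele = anchor
                alt_allele = anchor + base
            calls.append(
                DifferenceCall(
                    anchor0 + 1, kind, ref_allele, alt_allele, fraction, counted
                )
            )
        else:
            ambiguous.append(
                AmbiguousSite(
                    col.position, "multi_base_indel", counted, dict(col.counts)
                )
            )
    return calls, ambiguous


def apply_corrections(
    genome: str, calls: Sequence[DifferenceCall]
) -> tuple[str, list[tuple[int, int, str]]]:
    """Apply calls right-to-left; returns (corrected genome, audit trail).

    The audit trail lists (old 1-based position, new 1-based position, kind)
    for every edit, recorded after all edits are applied so that new
    coordinates are final.  Overlapping calls are a hard error.
    """
    ordered = sorted(calls, key=lambda c: c.position)
    for a, b in zip(ordered, ordered[1:]):
        a_end = a.position + len(a.ref_allele) - 1
        if b.position <= a_end:
            raise ValueError(
                f"overlapping calls at positions {a.position} and {b.position}"
            )
    seq = genome
    shifts: list[tuple[int, int]] = []  # (old position, length delta)
    for call in reversed(ordered):
        pos0 = call.position - 1
        if seq[pos0 : pos0 + len(call.ref_allele)] != call.ref_allele:
            raise ValueError(
                f"reference mismatch at {call.position}: expected "
                f"{call.ref_allele!r}, found {seq[pos0:pos0 + len(call.ref_allele)]!r}"
            )
        seq = seq[:pos0] + call.alt_allele + seq[pos0 + len(call.ref_allele) :]
        shifts.append((call.position, len(call.alt_allele) - len(call.ref_allele)))
    audit = []
    for call in ordered:
        delta = sum(d for p, d in shifts if p < call.position)
        audit.append((call.position, call.position + delta, call.kind))
    return seq, audit


def reverse_corrections(
    corrected: str, calls: Sequence[DifferenceCall], audit: Sequence[tuple[int, int, str]]
) -> str:
    """Undo :func:`apply_corrections` using the audit trail."""
    inverted = []
    for call, (_, new_pos, _) in zip(sorted(calls, key=lambda c: c.position), audit):
        inverted.append(
            DifferenceCall(
                new_pos,
                call.kind,
                call.alt_allele,
                call.ref_allele,
                call.support_fraction,
                call.depth,
            )
        )
    restored, _ = apply_corrections(corrected, inverted)
    return restored


# ---------------------------------------------------------------------------
# serialization


def write_vcf(calls: Sequence[DifferenceCall], chrom: str, path) -> None:
    """Minimal VCF 4.2 output for the difference calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SF,Number=1,Type=Float,Description="Support fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Counted depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: c.position):
            fh.write(
                f"{chrom}\t{c.position}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\tPASS\t"
                f"SF={c.support_fraction:.4f};DP={c.depth}\n"
            )


def write_ambiguous_tsv(sites: Sequence[AmbiguousSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\treason\tdepth\tcounts\n")
        for s in sites:
            counts = ",".join(f"{k}:{v}" for k, v in sorted(s.counts.items()))
            fh.write(f"{s.position}\t{s.reason}\t{s.depth}\t{counts}\n")


def write_audit_tsv(audit: Sequence[tuple[int, int, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("old_position\tnew_position\tkind\n")
        for old, new, kind in audit:
            fh.write(f"{old}\t{new}\t{kind}\n")
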