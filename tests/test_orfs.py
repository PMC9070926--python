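import re

import numpy as np
import pandas as pd
import pytest

from genoprof.fixtures import FixtureSpec, random_genome, synth_genome
from genoprof.orfs import (
    HitRecord,
    Orf,
    OrfEvidence,
    SuspicionConfig,
    best_hits,
    enumerate_orfs,
    gap_report,
    iterative_filter,
    reciprocal_best_hits,
    resolve_rna_overlaps,
    revcomp,
    suspicion_score,
)

# ---------------------------------------------------------------------------
# independent six-frame oracle (regex-based, structured differently from the
# implementation's codon walk)

# lookahead so overlapping occurrences (e.g. ATGTG) are all found
_STOP_RE = re.compile(r"(?=(TAA|TAG|TGA))")
_START_RE = re.compile(r"(?=(ATG|GTG|TTG))")


def six_frame_oracle(genome, min_length):
    found = set()
    for strand, seq in (("+", genome.upper()), ("-", revcomp(genome.upper()))):
        for frame in range(3):
            stops = [
                m.start()
                for m in _STOP_RE.finditer(seq)
                if m.start() % 3 == frame
            ]
            prev_end = frame
            for stop in stops:
                window = seq[prev_end : stop]
                starts = tuple(
                    prev_end + m.start()
                    for m in _START_RE.finditer(window)
                    if (prev_end + m.start()) % 3 == frame
                )
                if starts and stop + 3 - starts[0] >= min_length:
                    found.add((strand, starts, stop + 3))
                prev_end = stop + 3
    return found


def _as_tuples(orfs):
    return {(o.strand, tuple(o.candidate_starts), o.stop_end) for o in orfs}


class TestEnumerate:
    def test_minimal_gene(self):
        orfs = enumerate_orfs("ATGAAATAA", min_length=9)
        fwd = [o for o in orfs if o.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].candidate_starts == [0]
        assert fwd[0].length == 9

    def test_all_a_no_orfs(self):
        assert enumerate_orfs("A" * 300, min_length=9) == []

    def test_needs_terminal_stop(self):
        # start but no stop downstream -> no ORF
        assert [o for o in enumerate_orfs("ATGAAAAAA", min_length=3) if o.strand == "+"] == []

    def test_reverse_strand_coordinates(self):
        genome = revcomp("ATGAAATAA") + "CCC"
        orfs = [o for o in enumerate_orfs(genome, min_length=9) if o.strand == "-"]
        assert len(orfs) == 1
        # the gene sits at the start of the forward axis
        assert orfs[0].genomic_interval() == (0, 9)

    def test_planted_genes_recovered(self):
        genome, genes = synth_genome(FixtureSpec(seed=5, n_genes=3))
        orfs = enumerate_orfs(genome, min_length=90)
        intervals = {o.genomic_interval() for o in orfs if o.strand == "+"}
        for g in genes:
            assert any(lo <= g.start and hi == g.end for lo, hi in intervals)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_six_frame_oracle(self, seed):
        genome = random_genome(2000, 0.5, np.random.default_rng(seed))
        assert _as_tuples(enumerate_orfs(genome, 60)) == six_frame_oracle(genome, 60)


# ---------------------------------------------------------------------------
# reciprocal best hits


def _hits(rows):
    return [HitRecord(q, s, b) for q, s, b in rows]


def rbh_oracle(fwd_rows, rev_rows):
    """Exhaustive double-argmax with the same tie-break convention."""
    def best(rows):
        out = {}
        for q, s, b in rows:
            cur = out.get(q)
            if cur is None or b > cur[1] or (b == cur[1] and s < cur[0]):
                out[q] = (s, b)
        return {q: s for q, (s, b) in out.items()}

    f, r = best(fwd_rows), best(rev_rows)
    return {(q, s) for q, s in f.items() if r.get(s) == q}


class TestRbh:
    def test_mutual_best(self):
        assert reciprocal_best_hits(
            _hits([("q1", "r1", 50)]), _hits([("r1", "q1", 50)])
        ) == {("q1", "r1")}

    def test_asymmetric_excluded(self):
        fwd = _hits([("q1", "r1", 50)])
        rev = _hits([("r1", "q2", 60), ("r1", "q1", 50)])
        assert reciprocal_best_hits(fwd, rev) == set()

    def test_duplicates_reduced_to_best(self):
        fwd = _hits([("q1", "r1", 10), ("q1", "r2", 90), ("q1", "r1", 50)])
        rev = _hits([("r2", "q1", 40)])
        assert reciprocal_best_hits(fwd, rev) == {("q1", "r2")}

    def test_symmetry_under_table_swap(self):
        rng = np.random.default_rng(0)
        fwd = [(f"q{i%5}", f"r{i%4}", int(rng.integers(1, 100))) for i in range(30)]
        rev = [(f"r{i%4}", f"q{i%6}", int(rng.integers(1, 100))) for i in range(30)]
        a = reciprocal_best_hits(_hits(fwd), _hits(rev))
        b = reciprocal_best_hits(_hits(rev), _hits(fwd))
        assert a == {(q, r) for r, q in b}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_double_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_q, n_r = 20, 15
        fwd, rev = [], []
        for i in range(n_q):
            for j in rng.choice(n_r, size=rng.integers(1, 6), replace=False):
                fwd.append((f"q{i}", f"r{j}", float(rng.integers(10, 500))))
        for j in range(n_r):
            for i in rng.choice(n_q, size=rng.integers(1, 6), replace=False):
                rev.append((f"r{j}", f"q{i}", float(rng.integers(10, 500))))
        assert reciprocal_best_hits(_hits(fwd), _hits(rev)) == rbh_oracle(fwd, rev)

    def test_evalue_tiebreak(self):
        fwd = pd.DataFrame(
            {
                "qseqid": ["q", "q"],
                "sseqid": ["r2", "r1"],
                "bitscore": [50.0, 50.0],
                "evalue": [1e-10, 1e-20],
            }
        )
        assert best_hits(fwd) == {"q": "r1"}


# ---------------------------------------------------------------------------
# RNA-overlap resolution


def _orf(starts, stop_end, strand="+", length=1000, evidence=()):
    o = Orf("o1", strand, length, list(starts), stop_end)
    o.evidence = set(evidence)
    return o


class TestRnaOverlap:
    def test_fully_inside_rrna_discarded(self):
        orfs, log = resolve_rna_overlaps([_orf([100], 400)], [(0, 500)])
        assert orfs == []
        assert log == [("o1", "discarded")]

    def test_five_prime_overlap_trimmed(self):
        o = _orf([100, 250], 600)
        orfs, log = resolve_rna_overlaps([o], [(0, 200)])
        assert orfs == [o]
        assert o.current_start == 250
        assert log == [("o1", "trimmed")]

    def test_short_remnant_discarded(self):
        o = _orf([100, 555], 600)  # remnant 45 nt
        orfs, _ = resolve_rna_overlaps([o], [(0, 200)], remnant_min=90)
        assert orfs == []

    def test_rbh_evidence_exempt(self):
        o = _orf([100], 400, evidence={"rbh_tier1"})
        orfs, log = resolve_rna_overlaps([o], [(0, 500)])
        assert orfs == [o] and log == []

    def test_non_overlapping_untouched(self):
        o = _orf([100], 400)
        orfs, log = resolve_rna_overlaps([o], [(500, 600)])
        assert orfs == [o] and log == []


# ---------------------------------------------------------------------------
# suspicion scoring


def _ev(orf, ratio=5.0, combined=10.0, strand_ratio=5.0):
    return OrfEvidence(orf, ratio, combined, strand_ratio)


class TestSuspicion:
    def test_all_pass_zero(self):
        ev = _ev(_orf([0], 600))
        s = suspicion_score(ev, overlap_nt=0, combined_median=5.0, combined_p10=1.0)
        assert s.total == 0

    def test_all_fail_eight(self):
        ev = _ev(_orf([0], 120), ratio=1.0, combined=0.5, strand_ratio=0.1)
        s = suspicion_score(ev, overlap_nt=100, combined_median=5.0, combined_p10=1.0)
        assert s.total == 8

    @pytest.mark.parametrize(
        "length,expected", [(300, 0), (299, 1), (150, 1), (149, 2)]
    )
    def test_length_boundaries(self, length, expected):
        ev = _ev(_orf([0], length))
        s = suspicion_score(ev, 0, 5.0, 1.0)
        assert s.points_length == expected

    @pytest.mark.parametrize(
        "ratio,expected", [(2.0, 0), (1.99, 1), (0.5, 2), (0.51, 1)]
    )
    def test_strand_ratio_boundaries(self, ratio, expected):
        ev = _ev(_orf([0], 600), strand_ratio=ratio)
        assert suspicion_score(ev, 0, 5.0, 1.0).points_strand_ratio == expected

    @pytest.mark.parametrize("overlap,expected", [(0, 0), (29, 1), (30, 2)])
    def test_overlap_boundaries(self, overlap, expected):
        ev = _ev(_orf([0], 600))
        assert suspicion_score(ev, overlap, 5.0, 1.0).points_overlap == expected

    def test_missing_rnaseq_neutral_and_flagged(self):
        ev = _ev(_orf([0], 600), strand_ratio=None)
        s = suspicion_score(ev, 0, 5.0, 1.0)
        assert s.points_strand_ratio == 1 and s.flagged

    def test_start_component_boundaries(self):
        good = _ev(_orf([0], 600), ratio=2.0, combined=6.0)
        assert suspicion_score(good, 0, 5.0, 1.0).points_start == 0
        weak = _ev(_orf([0], 600), ratio=1.5, combined=6.0)
        assert suspicion_score(weak, 0, 5.0, 1.0).points_start == 1
        bad = _ev(_orf([0], 600), combined=0.5)
        assert suspicion_score(bad, 0, 5.0, 1.0).points_start == 2


class TestIterativeFilter:
    def test_fixed_point_when_nothing_above_cutoff(self):
        evs = [_ev(_orf([0], 600))]
        survivors, log = iterative_filter(evs)
        assert survivors == evs and log == []

    def test_two_overlapping_weak_orfs(self):
        # both overlap heavily; the weaker exceeds the cut-off, and its removal
        # drops the stronger's overlap component below the cut-off
        a = Orf("a", "+", 10_000, [0], 400)
        b = Orf("b", "+", 10_000, [0], 290)
        ev_a = OrfEvidence(a, 5.0, 10.0, 5.0)  # 0+0+0+overlap(2) = 2 while b present
        ev_b = OrfEvidence(b, 1.0, 0.5, 0.1)  # 1+1+2+2 = 6 > final cut-off 5
        survivors, log = iterative_filter(
            [ev_a, ev_b], max_score_final=5, config=SuspicionConfig()
        )
        assert [ev.orf.id for ev in survivors] == ["a"]
        assert [entry[0] for entry in log] == ["b"]

    def test_removal_never_raises_scores(self):
        rng = np.random.default_rng(0)
        evs = []
        for i in range(12):
            start = int(rng.integers(0, 2000))
            orf = Orf(f"o{i}", "+", 10_000, [start], start + int(rng.integers(120, 700)))
            evs.append(
                OrfEvidence(
                    orf,
                    float(rng.uniform(1, 4)),
                    float(rng.uniform(0.1, 20)),
                    float(rng.uniform(0.1, 6)),
                )
            )
        survivors, log = iterative_filter(evs)
        removed = {r[0] for r in log}
        assert {ev.orf.id for ev in survivors} | removed == {f"o{i}" for i in range(12)}

    def test_chain_matches_schedule_oracle(self):
        # three mutually overlapping ORFs: simulate the removal schedule
        # independently, removing one top-scorer at a time
        orfs = [
            Orf("a", "+", 10_000, [0], 200),
            Orf("b", "+", 10_000, [150], 380),
            Orf("c", "+", 10_000, [350], 560),
        ]
        evs = [
            OrfEvidence(orfs[0], 1.0, 0.5, 0.3),
            OrfEvidence(orfs[1], 1.5, 3.0, 1.0),
            OrfEvidence(orfs[2], 5.0, 10.0, 5.0),
        ]
        combined = sorted(e.combined_score for e in evs)
        median, p10 = combined[1], combined[0]

        def overlap(x, pool):
            iv = x.orf.genomic_interval()
            return max(
                (
                    max(0, min(iv[1], o.orf.genomic_interval()[1]) - max(iv[0], o.orf.genomic_interval()[0]))
                    for o in pool
                    if o is not x
                ),
                default=0,
            )

        pool = list(evs)
        removed = []
        for cutoff in (8, 7, 6, 5):
            while True:
                totals = {
                    e.orf.id: suspicion_score(e, overlap(e, pool), median, p10).total
                    for e in pool
                }
                worst = [e for e in pool if totals[e.orf.id] > cutoff]
                if not worst:
                    break
                worst.sort(key=lambda e: (-totals[e.orf.id], e.orf.genomic_interval()[0]))
                pool.remove(worst[0])
                removed.append(worst[0].orf.id)

        survivors, log = iterative_filter(evs)
        assert [e.orf.id for e in survivors] == [e.orf.id for e in pool]
        assert [r[0] for r in log] == removed


class TestGaps:
    def test_gap_detection(self):
        gaps = gap_report(5000, [(0, 1000), (1200, 1400), (4500, 5000)], min_gap=300)
        assert gaps == [(1400, 4500)]

    def test_no_gaps(self):
        assert gap_report(1000, [(0, 1000)], min_gap=100) == []
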