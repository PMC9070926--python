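import re
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoprof.fixtures import (
    FixtureSpec,
    find_homopolymer_runs,
    implant_errors,
    random_genome,
    synth_pileup,
)
from genoprof.pileup import (
    DELETION_1BP,
    INSERTION_1BP,
    SUBSTITUTION,
    AmbiguousSite,
    DifferenceCall,
    apply_corrections,
    call_differences,
    parse_bases,
    parse_pileup,
    reverse_corrections,
    write_vcf,
)

import numpy as np

# ---------------------------------------------------------------------------
# independent token-at-a-time parser used as an oracle for fuzzed columns

_TOKEN = re.compile(
    r"\^.|"  # read start + mapping quality char
    r"\$|"  # read end
    r"[+-]\d+|"  # indel prefix (sequence consumed separately)
    r"[.,]|"
    r"[*]|"
    r"[ACGTNacgtn]"
)


def naive_parse(bases: str) -> Counter:
    counts: Counter = Counter()
    pos = 0
    while pos < len(bases):
        m = _TOKEN.match(bases, pos)
        assert m, f"unparseable at {pos} in {bases!r}"
        tok = m.group(0)
        pos = m.end()
        if tok.startswith("^") or tok == "$":
            continue
        if tok[0] in "+-":
            n = int(tok[1:])
            counts[tok[0] + bases[pos : pos + n].upper()] += 1
            pos += n
        elif tok in ".,":
            counts["="] += 1
        elif tok == "*":
            counts["*"] += 1
        else:
            counts[tok.upper()] += 1
    return counts


_base_events = st.sampled_from(
    [".", ",", "A", "c", "G", "t", "N", "*", ".$", "^~.", ".+1A", ".-2gt", ",+3ACG"]
)


class TestParse:
    def test_all_match_column(self):
        counts = parse_bases(".,.,.", "A", "c", 1)
        assert counts == Counter({"=": 5})

    def test_uniform_deletion(self):
        counts = parse_bases("-1g" * 5, "A", "c", 1)
        assert counts == Counter({"-G": 5})

    def test_read_start_consumes_quality_char(self):
        # '^' is followed by a mapping-quality char that must not be counted,
        # even when it looks like a base or symbol
        counts = parse_bases("^A.^].", "A", "c", 1)
        assert counts == Counter({"=": 2})

    def test_insertion_attached_to_match(self):
        counts = parse_bases(".+1A.", "G", "c", 1)
        assert counts == Counter({"=": 2, "+A": 1})

    def test_malformed_indel_raises(self):
        with pytest.raises(ValueError, match="indel"):
            parse_bases(".+", "A", "c", 7)
        with pytest.raises(ValueError, match="shorter"):
            parse_bases(".+5AC", "A", "c", 7)

    def test_parse_pileup_lines(self):
        lines = ["chr\t1\ta\t3\t..,\t~~~", "chr\t2\tC\t2\t.T\t~~"]
        cols = list(parse_pileup(lines))
        assert cols[0].ref_base == "A"
        assert cols[0].counts == Counter({"=": 3})
        assert cols[1].counts == Counter({"=": 1, "T": 1})

    @given(st.lists(_base_events, min_size=0, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_fuzzed_columns_match_naive_oracle(self, events):
        bases = "".join(events)
        assert parse_bases(bases, "A", "c", 1) == naive_parse(bases)


def _col(bases, ref="A", pos=5, genome=None):
    cols = list(parse_pileup([f"chr\t{pos}\t{ref}\t{len(bases)}\t{bases}\t{'~'*len(bases)}"]))
    return cols


class TestCalling:
    GENOME = "ACGTACGGGGGGGTACGT"  # 7-G run at 0-based 6..13

    def test_unanimous_deletion_called(self):
        cols = _col(".-1G" * 20, ref="G", pos=13)
        calls, amb = call_differences(cols, self.GENOME, 10, 0.9)
        assert len(calls) == 1 and not amb
        call = calls[0]
        assert call.kind == DELETION_1BP
        # left-normalized: anchor before the run (0-based 5 -> 1-based 6)
        assert call.position == 6
        assert call.ref_allele == "CG" and call.alt_allele == "C"

    def test_half_support_ambiguous(self):
        cols = _col(".-1G" * 10 + "." * 10, ref="G", pos=13)
        calls, amb = call_differences(cols, self.GENOME, 10, 0.9)
        assert calls == [] and len(amb) == 1
        assert amb[0].reason == "below_threshold"

    def test_below_depth_ambiguous(self):
        cols = _col("T" * 5, ref="A", pos=1)
        calls, amb = call_differences(cols, self.GENOME, 10, 0.9)
        assert calls == [] and len(amb) == 1

    def test_substitution_called(self):
        cols = _col("T" * 15, ref="A", pos=5)
        calls, _ = call_differences(cols, self.GENOME, 10, 0.9)
        assert calls == [
            DifferenceCall(5, SUBSTITUTION, "A", "T", 1.0, 15)
        ]

    def test_multibase_indel_goes_to_ambiguous(self):
        cols = _col(".+2GG" * 20, ref="A", pos=1)
        calls, amb = call_differences(cols, self.GENOME, 10, 0.9)
        assert calls == [] and amb[0].reason == "multi_base_indel"

    def test_all_reference_no_call(self):
        cols = _col("." * 30, ref="A", pos=1)
        calls, amb = call_differences(cols, self.GENOME, 10, 0.9)
        assert calls == [] and amb == []


class TestApply:
    def test_empty_call_list_identity(self):
        assert apply_corrections("ACGT", [])[0] == "ACGT"

    def test_single_deletion_splice(self):
        call = DifferenceCall(2, DELETION_1BP, "CG", "C", 1.0, 20)
        corrected, audit = apply_corrections("ACGT", [call])
        assert corrected == "ACT"
        assert audit == [(2, 2, DELETION_1BP)]

    def test_single_insertion(self):
        call = DifferenceCall(2, INSERTION_1BP, "C", "CX", 1.0, 20)
        corrected, _ = apply_corrections("ACGT", [call])
        assert corrected == "ACXGT"

    def test_overlapping_calls_rejected(self):
        a = DifferenceCall(2, DELETION_1BP, "CG", "C", 1.0, 20)
        b = DifferenceCall(3, SUBSTITUTION, "G", "T", 1.0, 20)
        with pytest.raises(ValueError, match="overlapping"):
            apply_corrections("ACGT", [a, b])

    def test_reference_mismatch_rejected(self):
        call = DifferenceCall(2, SUBSTITUTION, "T", "A", 1.0, 20)
        with pytest.raises(ValueError, match="mismatch"):
            apply_corrections("ACGT", [call])

    def test_reverse_restores_original(self):
        genome = "AACCGGGGTTAACGT"
        calls = [
            DifferenceCall(3, SUBSTITUTION, "C", "T", 1.0, 20),
            DifferenceCall(5, DELETION_1BP, "GG", "G", 1.0, 20),
            DifferenceCall(11, INSERTION_1BP, "A", "AA", 1.0, 20),
        ]
        corrected, audit = apply_corrections(genome, calls)
        assert reverse_corrections(corrected, calls, audit) == genome


class TestEndToEnd:
    def _simulate(self, seed=11, n_errors=50):
        spec = FixtureSpec(seed=seed, genome_length=30_000, n_errors=n_errors)
        genome = random_genome(spec.genome_length, 0.5, spec.rng())
        err, truth = implant_errors(genome, spec)
        lines = synth_pileup(err, truth, depth=30)
        cols = list(parse_pileup(lines))
        return genome, err, truth, cols

    def test_exactly_51_calls_no_false_positives(self):
        genome, err, truth, cols = self._simulate()
        calls, amb = call_differences(cols, err, 10, 0.9)
        assert len(calls) == 51
        assert amb == []
        kinds = Counter(c.kind for c in calls)
        assert kinds[INSERTION_1BP] == 50
        assert kinds[SUBSTITUTION] == 1

    def test_corrected_genome_matches_ground_truth(self):
        genome, err, truth, cols = self._simulate()
        calls, _ = call_differences(cols, err, 10, 0.9)
        corrected, _ = apply_corrections(err, calls)
        assert corrected == genome

    def test_recalling_on_corrected_genome_is_clean(self):
        genome, err, truth, cols = self._simulate()
        calls, _ = call_differences(cols, err, 10, 0.9)
        corrected, _ = apply_corrections(err, calls)
        # error-free reads of the corrected genome: all-match pileup
        clean_lines = [
            f"synth\t{i + 1}\t{b}\t30\t{'.' * 30}\t{'~' * 30}"
            for i, b in enumerate(corrected)
        ]
        calls2, amb2 = call_differences(
            parse_pileup(clean_lines), corrected, 10, 0.9
        )
        assert calls2 == [] and amb2 == []

    def test_homopolymer_normalization_is_canonical(self):
        genome, err, truth, cols = self._simulate(seed=12, n_errors=20)
        calls, _ = call_differences(cols, err, 10, 0.9)
        for c in [c for c in calls if c.kind == INSERTION_1BP]:
            # anchor base differs from the inserted base: leftmost position
            assert c.ref_allele != c.alt_allele[1]

    def test_vcf_output(self, tmp_path):
        call = DifferenceCall(6, DELETION_1BP, "AG", "A", 1.0, 20)
        write_vcf([call], "chr", tmp_path / "c.vcf")
        text = (tmp_path / "c.vcf").read_text()
        assert "##fileformat=VCFv4.2" in text
        assert "chr\t6\t.\tAG\tA\t.\tPASS\t" in text


class TestRunFinding:
    def test_find_runs(self):
        runs = find_homopolymer_runs("AAAACCGGGGGT", 4)
        assert runs == [(0, 4), (6, 11)]

    def test_implant_respects_count(self):
        spec = FixtureSpec(seed=3, genome_length=20_000, n_errors=10)
        genome = random_genome(spec.genome_length, 0.5, spec.rng())
        err, truth = implant_errors(genome, spec)
        assert len(err) == len(genome) - 10
        assert truth.n_events == 11

    def test_insufficient_runs_error(self):
        with pytest.raises(ValueError, match="runs"):
            implant_errors("ACGT" * 100, FixtureSpec(seed=0, n_errors=5))
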