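"""Deterministic synthetic inputs with known ground truth.

Everything the test surface needs is generated here from a seed: genomes with
planted genes (RBS motifs at the ideal spacing, optional translationally
coupled pairs), multi-library stranded tile-depth matrices with known scale
factors and differential-expression tiles, and homopolymer-indel error sets
with matching error-free pileups.  Simulated reads are represented directly as
depth/pileup structures; no FASTQ is emitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .startcodon import default_matrix
from .tiling import GenomeAxis, TileDepthMatrix

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")


@dataclass
class FixtureSpec:
    seed: int = 0
    genome_length: int = 10_000
    gc_fraction: float = 0.5
    n_genes: int = 3
    n_coupled_pairs: int = 0
    scale_factors: tuple[float, ...] = (1.0, 1.5, 2.0, 0.8, 1.2, 1.0)
    de_fraction: float = 0.10
    de_fold: float = 5.0
    noise_sigma: float = 0.10
    n_timepoints: int = 7
    n_tiles: int = 500
    tile_size: int = 100
    n_errors: int = 50
    with_substitution: bool = True

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_genome(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# genome with planted genes


@dataclass
class PlantedGene:
    id: str
    start: int  # 0-based, first base of the start codon (forward strand)
    end: int  # 0-based exclusive, end of the stop codon
    start_codon: str
    coupled_to: str | None = None


def _random_body_codons(n: int, rng: np.random.Generator) -> str:
    """In-frame codons guaranteed stop-free (and start-poor, for cleanliness)."""
    safe = [
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if a + b + c not in STOPS and a + b + c not in ("ATG", "GTG", "TTG")
    ]
    return "".join(rng.choice(safe) for _ in range(n))


def synth_genome(spec: FixtureSpec) -> tuple[str, list[PlantedGene]]:
    """Random genome with ``n_genes`` planted forward-strand genes.

    Each gene carries the default-matrix RBS consensus ending 8 bases before
    its ATG (the ideal triangle spacing).  ``n_coupled_pairs`` extra genes are
    planted so their start sits at offset -4 from the upstream partner's stop.
    """
    rng = spec.rng()
    matrix = default_matrix()
    rbs = matrix.consensus()
    total_genes = spec.n_genes + spec.n_coupled_pairs
    gene_codons = 40
    unit = len(rbs) + 7 + 3 + gene_codons * 3 + 3  # rbs + spacer + start+body+stop
    slot = spec.genome_length // max(1, total_genes)
    if unit + 20 > slot:
        raise ValueError("infeasible packing: genome too short for requested genes")
    seq = list(random_genome(spec.genome_length, spec.gc_fraction, rng))
    genes: list[PlantedGene] = []
    for g in range(total_genes):
        offset = g * slot + 10
        cassette = rbs + "".join(rng.choice(list("ACT"), size=7)) + "ATG"
        body = _random_body_codons(gene_codons, rng)
        if g >= spec.n_genes:
            # a coupled partner will overwrite the cassette tail; pin the last
            # body codon so the overlay cannot create an in-frame stop
            body = body[:-3] + "GGC"
        cassette += body + "TAA"
        start = offset + len(rbs) + 7
        gene = PlantedGene(
            id=f"gene{g + 1:03d}",
            start=start,
            end=offset + len(cassette),
            start_codon="ATG",
        )
        seq[offset : offset + len(cassette)] = cassette
        genes.append(gene)
        if g >= spec.n_genes:
            # coupled partner: its ATG starts at offset -4 from the lead stop,
            # turning the lead's TAA into TGA (still a stop) with the last two
            # start bases overlapping it
            partner_start = gene.end - 4
            # second codon starts with A so the lead stop reads TGA after overlay
            cassette2 = "ATG" + "AAA" + _random_body_codons(19, rng) + "TAA"
            seq[partner_start : partner_start + len(cassette2)] = cassette2
            genes.append(
                PlantedGene(
                    id=f"gene{g + 1:03d}c",
                    start=partner_start,
                    end=partner_start + len(cassette2),
                    start_codon="ATG",
                    coupled_to=gene.id,
                )
            )
    return "".join(seq), genes


def write_genes_gff(genes: list[PlantedGene], seq_id: str, length: int, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seq_id} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{seq_id}\tgenoprof\tCDS\t{g.start + 1}\t{g.end}\t.\t+\t0\t"
                f"ID={g.id}\n"
            )


def write_fasta(seq: str, seq_id: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq_id}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> tuple[str, str]:
    seq_id, chunks = "", []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                seq_id = line[1:].split()[0]
            elif line:
                chunks.append(line)
    return seq_id, "".join(chunks)


# ---------------------------------------------------------------------------
# depth libraries with known scale factors


def synth_norm_matrix(spec: FixtureSpec) -> tuple[TileDepthMatrix, dict]:
    """Tile-depth matrix with known per-library scale factors.

    Forward-strand tiles carry lognormal expression; the reverse strand is a
    low-level noise floor (so the least-expressed half of the pooled tile list
    is the reverse strand).  A ``de_fraction`` of expressed tiles is
    ``de_fold``-fold up-regulated in the first half of the libraries.  Library
    ``i`` sees ``expression / scale_factors[i]`` (times multiplicative
    lognormal noise), so a correct normalizer recovers factors proportional to
    ``scale_factors``.
    """
    rng = spec.rng()
    n_lib = len(spec.scale_factors)
    n_tiles = spec.n_tiles
    axis = GenomeAxis("synth", n_tiles * spec.tile_size, spec.tile_size)
    expr = rng.lognormal(mean=np.log(2000.0), sigma=1.0, size=n_tiles)
    expr = np.clip(expr, 50.0, None)
    n_de = int(round(spec.de_fraction * n_tiles))
    de_tiles = rng.choice(n_tiles, size=n_de, replace=False)
    de_libs = np.arange(n_lib // 2)

    depths = np.zeros((n_lib, 2, n_tiles))
    factors = np.asarray(spec.scale_factors, dtype=float)
    for i in range(n_lib):
        fwd = expr / factors[i]
        if i in de_libs and n_de:
            fwd = fwd.copy()
            fwd[de_tiles] *= spec.de_fold
        if spec.noise_sigma > 0:
            fwd = fwd * rng.lognormal(0.0, spec.noise_sigma, size=n_tiles)
            rev = rng.uniform(0.0, 5.0, size=n_tiles)
        else:
            rev = np.zeros(n_tiles)
        depths[i, 0] = fwd
        depths[i, 1] = rev
    matrix = TileDepthMatrix(axis, [f"lib{i + 1}" for i in range(n_lib)], depths)
    truth = {
        "scale_factors": list(map(float, factors)),
        "de_tiles": sorted(int(t) for t in de_tiles),
        "de_libraries": [f"lib{i + 1}" for i in de_libs],
        "noise_sigma": spec.noise_sigma,
    }
    return matrix, truth


def synth_profile_matrix(spec: FixtureSpec) -> tuple[TileDepthMatrix, dict]:
    """Replicate-merged time-course matrix for the encoding/rendering stages.

    Libraries are ordered time points; each forward tile gets a smooth
    single-peak profile with a random peak time and amplitude, the reverse
    strand a low constant floor.
    """
    rng = spec.rng()
    n_tp = spec.n_timepoints
    n_tiles = spec.n_tiles
    axis = GenomeAxis("synth", n_tiles * spec.tile_size, spec.tile_size)
    t = np.arange(n_tp)
    peaks = rng.integers(0, n_tp, size=n_tiles)
    widths = rng.uniform(0.8, 2.5, size=n_tiles)
    amps = rng.lognormal(np.log(500.0), 1.0, size=n_tiles)
    depths = np.zeros((n_tp, 2, n_tiles))
    for j in range(n_tiles):
        profile = amps[j] * np.exp(-0.5 * ((t - peaks[j]) / widths[j]) ** 2)
        depths[:, 0, j] = profile
        depths[:, 1, j] = 2.0
    labels = [f"t{k}" for k in range(n_tp)]
    truth = {"peaks": peaks.tolist(), "amplitudes": amps.tolist()}
    return TileDepthMatrix(axis, labels, depths), truth


def write_depth_tsvs(matrix: TileDepthMatrix, out_dir) -> list[str]:
    """Per-(library, strand) samtools-depth-style TSVs, tile depth spread
    uniformly over the tile's bases."""
    import os

    paths = []
    for i, lab in enumerate(matrix.libraries):
        for s, strand in enumerate(("forward", "reverse")):
            path = os.path.join(str(out_dir), f"{lab}.{strand}.depth.tsv")
            with open(path, "w") as fh:
                for tile in range(matrix.axis.n_tiles):
                    lo, hi = matrix.axis.tile_interval(tile)
                    per_base = matrix.depths[i, s, tile] / (hi - lo)
                    if per_base == 0:
                        continue
                    for pos0 in range(lo, hi):
                        fh.write(
                            f"{matrix.axis.sequence_id}\t{pos0 + 1}\t{per_base:.6g}\n"
                        )
            paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# homopolymer indel errors and pileup simulation


def find_homopolymer_runs(seq: str, min_len: int = 4) -> list[tuple[int, int]]:
    """0-based half-open intervals of runs of identical bases >= min_len."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


@dataclass
class ImplantedErrors:
    """Ground truth of :func:`implant_errors` (coordinates on the ERROR genome).

    ``insertions`` are (anchor0, base): the true genome has one extra ``base``
    right after 0-based ``anchor0`` of the error genome.  ``substitution`` is
    (pos0, true_base) or None.
    """

    insertions: list[tuple[int, str]] = field(default_factory=list)
    substitution: tuple[int, str] | None = None

    @property
    def n_events(self) -> int:
        return len(self.insertions) + (1 if self.substitution else 0)


def implant_errors(genome: str, spec: FixtureSpec) -> tuple[str, ImplantedErrors]:
    """Delete one base from ``n_errors`` distinct homopolymer runs (the classic
    long-read assembly error) and optionally substitute one base.

    Returns the mutated (error) genome and the truth needed to restore the
    original: insertion events in error-genome coordinates.
    """
    rng = spec.rng()
    runs = find_homopolymer_runs(genome, 4)
    if len(runs) < spec.n_errors:
        raise ValueError(
            f"genome has only {len(runs)} homopolymer runs >= 4 bp, "
            f"need {spec.n_errors}"
        )
    chosen = sorted(
        rng.choice(len(runs), size=spec.n_errors, replace=False).tolist()
    )
    del_pos = sorted(runs[k][0] for k in chosen)  # delete the first base of each run

    sub = None
    if spec.with_substitution:
        run_cover = set()
        for a, b in runs:
            run_cover.update(range(a - 1, b + 1))
        for _ in range(10_000):
            p = int(rng.integers(1, len(genome) - 1))
            if p in run_cover or p in del_pos:
                continue
            if genome[p - 1] == genome[p] or genome[p + 1] == genome[p]:
                continue
            alts = [b for b in BASES if b != genome[p] and b not in (genome[p - 1], genome[p + 1])]
            if alts:
                sub = (p, genome[p], alts[int(rng.integers(0, len(alts)))])
                break
        if sub is None:
            raise ValueError("could not place a substitution")

    err = list(genome)
    if sub:
        err[sub[0]] = sub[2]
    for p in reversed(del_pos):
        del err[p]
    err_genome = "".join(err)

    truth = ImplantedErrors()
    n_before = 0
    for p in del_pos:
        # error-genome coordinate of the run after earlier deletions shifted it
        err_run_start = p - n_before
        truth.insertions.append((err_run_start - 1, genome[p]))
        n_before += 1
    if sub:
        err_pos = sub[0] - sum(1 for p in del_pos if p < sub[0])
        truth.substitution = (err_pos, sub[1])  # reads carry the TRUE base
    return err_genome, truth


def synth_pileup(err_genome: str, truth: ImplantedErrors, depth: int = 30) -> list[str]:
    """mpileup-dialect lines for error-free reads of the true genome aligned to
    the error genome: insertion alleles at each missing-base anchor, a uniform
    mismatch at the substitution site, plain matches elsewhere."""
    ins_at = {anchor0: base for anchor0, base in truth.insertions}
    sub_at = dict([truth.substitution]) if truth.substitution else {}
    lines = []
    for pos0, ref in enumerate(err_genome):
        if pos0 in sub_at:
            bases = sub_at[pos0] * depth
        elif pos0 in ins_at:
            bases = f".+1{ins_at[pos0]}" * depth
        else:
            bases = "." * depth
        lines.append(f"synth\t{pos0 + 1}\t{ref}\t{depth}\t{bases}\t{'~' * depth}")
    return lines


def write_truth_vcf(truth: ImplantedErrors, err_genome: str, chrom: str, path) -> None:
    """Truth corrections as minimal VCF against the error genome, left-normalized."""
    rows = []
    for anchor0, base in truth.insertions:
        rows.append((anchor0 + 1, err_genome[anchor0], err_genome[anchor0] + base))
    if truth.substitution:
        pos0, true_base = truth.substitution
        rows.append((pos0 + 1, err_genome[pos0], true_base))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
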