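# genoprof

Tools for gene-free groupwise RNA-seq normalization over fixed-width genome
tiles, HSL colour encoding of time-course expression profiles rendered as
genome-browser features, multi-evidence bacterial start-codon selection,
suspicion-score ORF filtering with reciprocal-best-hit orthology support, and
pileup-based correction of homopolymer indel errors in long-read assemblies.

## Modules

| module | purpose |
| --- | --- |
| `genoprof.tiling` | per-base depth (samtools-depth TSV, bedGraph, SAM) → strand-separated 100-base tile depths, collated tile CSV |
| `genoprof.normalize` | iterative groupwise trimmed normalization: drop the least-expressed half, floor very low tiles, then iterate 10 %/10 % expression trims and an 80 % NRMSD variability trim until the per-library factors converge |
| `genoprof.encode` | expression profile → HSL: lightness = clamped log of max intensity (white→mid-grey), saturation = ((max−min)/max)², hue = peak time over 240° with up-to-halfway neighbour pull |
| `genoprof.render` | Artemis-dialect EMBL (`/colour=R G B`) and GFF3 colour features, per-tile and per-gene, plus a deterministic whole-genome overview PNG |
| `genoprof.startcodon` | RBS weight-matrix scan with threshold/ramp scoring, 9-base triangle aggregation with visible-start down-weighting, translational-coupling curve, codon-type weights (ATG 16 / GTG 4 / TTG 1), best-start selection with confidence ratio |
| `genoprof.orfs` | six-frame ORF enumeration, reciprocal best hits from BLAST outfmt-6 tables, RNA-overlap trimming, iterative 0–8 point suspicion filtering |
| `genoprof.pileup` | samtools-mpileup parsing, non-ambiguous substitution/1-bp-indel calling (≥ 90 % support at ≥ 10×, configurable), left-normalized application with audit trail |
| `genoprof.fixtures` | seeded synthetic genomes, depth libraries with known scale factors, homopolymer-error sets and matching pileups |
| `genoprof.cli` | `genoprof` command-line entry point |

## CLI

Each stage is a subcommand; `viz` and `annotate` are composites. All runs are
deterministic: identical inputs give byte-identical outputs (run reports carry
parameter values and input digests, never timestamps).

```sh
# synthetic inputs with ground truth
genoprof fixtures --preset norm --seed 1 --out fx/

# stages
genoprof tile --format depth-tsv --length 500000 \
    --library lib1=fwd.tsv,rev.tsv --out tiles.csv
genoprof normalize tiles.csv --floor 10 --expr-trim 0.10 --keep 0.20 \
    --tol 1e-6 --out-factors factors.tsv
genoprof encode merged.csv --hue-span 240 --lightness-floor 0.5 \
    --background auto --clamp auto --out colours.tsv
genoprof render merged.csv --annotation genes.gff3 \
    --out-embl colours.embl --out-gff colours.gff3 --out-png overview.png
genoprof startcall genome.fasta --threshold 2.54 --ramp 0.4 --out starts.tsv
genoprof correct reads.pileup assembly.fasta \
    --min-depth 10 --min-fraction 0.9 --out corrected/

# composites
genoprof viz tiles.csv --annotation genes.gff3 --out viz_out/
genoprof annotate genome.fasta --hits-forward q2r.tsv --hits-reverse r2q.tsv \
    --rna-gff rna.gff3 --tile-csv tiles.csv --out ann_out/
```

## Notes

* Internal coordinates are 0-based half-open; flat files use the usual 1-based
  inclusive convention (reverse strand written as `complement(start..end)`).
* The bundled RBS weight matrix (`genoprof/data/rbs_matrix.tsv`, consensus
  `tvaGGag`) is a default; any matrix of the same shape can be supplied with
  `--matrix`.
* Tile depth is the sum of per-base depths in the tile; normalization factors
  are reported rescaled to geometric mean 1 (only ratios matter downstream).
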