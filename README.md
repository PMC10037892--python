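# karyopaint

Design of Oligopaint-style FISH probe libraries and FISH-guided curation of
draft chromosome-scale genome assemblies.

Scaffold-level genome assemblies routinely contain chimeric scaffolds (pieces
of two chromosomes joined end to end), inverted segments, and scaffolds whose
chromosome of origin is unknown. Fluorescence in-situ hybridisation (FISH)
with oligonucleotide paints gives direct physical evidence: each probe is a
pool of short labelled oligos tiling a window of a scaffold, and observing
where the probes land on metaphase chromosome spreads — which chromosome,
which arm, in what order — reveals whether the scaffold is intact, reversed,
reordered, or chimeric. `karyopaint` implements both halves of that loop:

1. **Probe design** — mine 39-mer homology segments from scaffold sequence
   under melting-temperature, GC, k-mer-uniqueness and hairpin constraints;
   allocate probes to scaffolds in tiers under a per-library oligo budget;
   place probe windows evenly along each scaffold; build the orthogonal
   (non-genomic) 20-mer barcode pool that provides amplification primers,
   colour adapters and detection oligos; and assemble the final 79-mer
   library oligos (`reverse 20-mer | homolog 39-mer | forward 20-mer`).
2. **Assembly curation** — take per-spread hybridisation observations
   (probe, chromosome, rank from the centromere, colour), vote probes onto
   chromosomes, flag anomalous scaffolds, narrow chimera breakpoints with
   whole-genome alignments when available, split and orient scaffold parts,
   and emit chromosome builds (AGP) numbered by the standard cytogenetic
   convention (morphology group, then decreasing physical length).

Supporting modules provide a synthetic-data generator with known ground
truth (toy genomes, fragmented scaffolds with planted chimeras/inversions,
zero-noise hybridisation simulation), assembly contiguity metrics (N50,
L-fraction, relative chromosome lengths normalised to the X), and a
synteny-based rearrangement classifier (inversion / fission / fusion /
translocation, minimal-event scenarios by breadth-first search).

## Worked example

Simulate a small genome, fragment it into scaffolds with one planted
chimera, design probes, simulate zero-noise hybridisation, and curate:

```python
import karyopaint as kp
from karyopaint import pipeline, synthetic as ksyn

genome = kp.generate_toy_genome(4, (60_000, 120_000), repeat_fraction=0.0, seed=7)
scaffolds = kp.fragment_into_scaffolds(genome, 6, chimera_spec=[("chr1", "chr3")], seed=7)

design = pipeline.design_probe_plan(scaffolds.sequences, genome.sequences(),
                                    capacity=200, n_oligo=8)
obs = ksyn.simulate_hybridization(design.plan, scaffolds.truths, genome,
                                  n_spreads=3, seed=5)
aln = ksyn.simulate_reference_alignments(scaffolds.truths, genome, tile=5_000)

lengths = {k: len(v) for k, v in scaffolds.sequences.items()}
result = kp.curate(obs, design.plan, lengths, aln)

print(result.statuses)
bp = result.breakpoints["scaffold_1"]
print(bp.left_bound, bp.right_bound, bp.evidence, bp.reference_chromosomes)
```

Output:

```
{'scaffold_1': 'chimeric', 'scaffold_2': 'clean', 'scaffold_3': 'clean',
 'scaffold_4': 'clean', 'scaffold_5': 'clean', 'scaffold_6': 'clean'}
24225 24225 synteny ('chr1', 'chr3')
```

The planted chimera is flagged, and with alignments available the breakpoint
is narrowed to the exact junction (scaffold coordinate 24,225). Note the
small-scale parameters: at toy-genome scale the genome-homology e-value
cutoff must be scale-appropriate (`design_probe_plan` and `prepare_barcodes`
accept `evalue_cutoff`; the default of 25 is meaningful only against a
full-size genome — see `docs/methods.md`).

The same stages are available from the command line:

```
karyopaint simulate --out-dir work --n-chromosomes 4 --n-scaffolds 6 \
    --chimera chr1:chr3 --length-range 60000 120000 --seed 7
karyopaint design   --scaffolds work/scaffolds.fasta --genome work/genome.fasta \
    --out-dir work --n-oligo 8 --capacity 200 --ortho-pool-size 200 --evalue-cutoff 0.01
karyopaint curate   --observations work/observations.tsv --plan work/probe_plan.tsv \
    --scaffolds work/scaffolds.fasta --reference-paf work/reference.paf --out-dir work
karyopaint metrics  --fasta work/genome.fasta
karyopaint synteny  --paf work/reference.paf --min-block 10000 --out-dir work
```

`curate` consumes an observation table (one row per probe signal per spread:
`spread_id`, `probe_id`, `chromosome_label`, `order_index`, `colour`,
`centromere_side`) and, optionally, scaffold-to-reference alignments in PAF.
In an experiment these come from scored metaphase spreads and a whole-genome
aligner; for a synthetic round trip write them with
`karyopaint.synthetic.simulate_hybridization` /
`simulate_reference_alignments` plus `observations_to_frame`, `write_tsv`
and `write_paf`, as in the Python example above.

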