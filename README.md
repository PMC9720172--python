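# oligotiler

Design Tm-uniform overlapping oligonucleotide sets for PCR/LCR gene
assembly.

Given a DNA sequence (typically 200 bp – 3 kb), `oligotiler`:

1. **Splits** the sequence into overlap segments of near-equal length
   (nominal overlap 20–30 bp, so oligos come out at 40–60 bp).
2. **Refines** the segment boundaries iteratively, shifting each internal
   boundary one base at a time until the standard deviation of segment
   melting temperatures stops improving by more than a threshold
   (default 0.001).
3. Optionally runs a **pruned depth-first search** over per-overlap end
   shrinks (up to a per-overlap budget, default 3 bp) that provably
   minimizes the overlap-Tm standard deviation; shrunk bases become
   single-strand gaps for gapped PCR assembly.
4. **Emits** the alternating sense/antisense oligo set, the two
   amplification primers (the first overlap and the reverse complement of
   the last), and Tm statistics. A short random 3' tail is appended
   automatically when the segment count would leave the alternating
   structure unable to close (it can be removed afterwards by PCR with
   specific primers).

Melting temperatures use the unified nearest-neighbor parameter set
(SantaLucia 1998; shipped as `src/oligotiler/data/nn_params.tsv` with the
provenance and the exact equations in its header), with the
monovalent-salt correction applied to the entropy via the duplex
phosphate count and the strand-concentration term `R ln(Ct/x)`.
Defaults: 50 mM Na+, 1 µM total strand concentration.

## Command line

```bash
# design from a single-record FASTA (or a raw sequence string)
oligotiler design gene.fa --mode gapped --target-len 25 --budget 3 \
    --na 0.05 --ct 1e-6 --seed 1 --out-prefix mygene

# writes mygene.oligos.fasta, mygene.report.tsv, mygene.design.json

# melting temperature of one duplex
oligotiler tm ACGTACGTACGTACGTACGTACGT --na 0.05 --ct 1e-6

# re-check an emitted report's structural invariants (exit 2 on violation)
oligotiler validate mygene.report.tsv

# seeded synthetic test sequences (uniform GC or a 30%→70% GC gradient)
oligotiler synth --length 900 --kind gradient --seed 7 --out fixture.fa
```

`design` exits 0 on success, 2 on input/validation errors, 1 on internal
errors. The emitted `.design.json` embeds the input sequence, the full
configuration and the seed; re-running with them reproduces all three
output files byte-for-byte.

## Library

```python
from oligotiler import DesignConfig, design, check_invariants

oset = design(sequence, DesignConfig(mode="gapped", target_len=25, seed=1))
assert check_invariants(oset) == []
print(oset.mean_overlap_tm, oset.std_overlap_tm)
for oligo in oset.oligos:
    print(oligo.index, oligo.strand, oligo.sequence)
```

Modules map one-to-one onto the pipeline stages: `thermo`
(nearest-neighbor Tm engine), `segmentation` (equal split + iterative
boundary refinement), `dfs_optimizer` (exact branch-and-bound over end
shrinks), `oligo_builder` (oligo/primer/gap geometry and the tail rule),
`io_cli` (FASTA/TSV/JSON/YAML I/O and the CLI), `synthetic` (seeded
sequence generators used by the tests).

All coordinates are 0-based half-open on the sense strand; reported
standard deviations are population (divide by L) throughout; stds within
1e-9 °C are treated as ties by the optimizer and broken toward fewer
shrunk bases, then the lexicographically smaller assignment.

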