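# kresolve

Repeat resolution for unitig de Bruijn graphs. Short interspersed repeats
collapse distinct genomic loci into one graph node with multiple in- and
out-neighbours. `kresolve` re-examines every 3-node junction path through
such nodes with a sliding window of *larger* k-mers (`k_rresolver`, by
default `k_assembly + 60`) taken from the original reads and stored in a
Bloom filter: each window position is a membership query, paths whose hit
count stays below the support threshold are removed, each supported path
gets its own copy of the repeat sequence, and the resulting unambiguous
chains are merged. The number of window tests adapts to local coverage and
repeats that cannot be tested sufficiently are skipped entirely. A
synthetic-data module (repeat-bearing genomes, short-read simulation, a
minimal unitig-DBG builder, truth-based scoring) makes the whole pipeline
testable without external data.

## CLI

Generate a fixture set (genome FASTA, reads FASTQ, truth tables, baseline
unitig GFA):

```sh
kresolve simulate --unique-length 5000 --repeat-length 80 --k-assembly 51 \
    --read-length 151 --coverage 40 --seed 1 --out-prefix scratch/toy
```

Resolve repeats in a GFA1 unitig graph (S lines with `KC:i` multiplicity
sums, L lines with fixed `(k_assembly-1)M` overlaps) using the reads that
built it:

```sh
kresolve resolve --graph scratch/toy.gfa --reads scratch/toy.reads.fq \
    --k-assembly 51 --k-rresolver 111 --seed 1 --out-prefix scratch/toy.resolved
```

Outputs: `<prefix>.gfa` (edited graph), `<prefix>.fa` (contigs),
`<prefix>.report.tsv` (per read-size, per pass counters and Bloom stats).
Key tuning flags mirror the algorithm parameters: `--threshold` (support
threshold and k-mers stored per read, 4), `--min-tests` (18), `--max-tests`
(40), `--correction-factor` (4), `--margin` (2), `--hashes` (7),
`--max-side-paths` (75), `--iterations` (2), `--bloom-mem` (MiB, 64).
Runs are deterministic given `--seed`.

## Layout

- `src/kresolve/seq_io.py` — FASTA/FASTQ reads, GFA1 graphs.
- `src/kresolve/assembly_graph.py` — oriented graph model, path spelling, chain merging.
- `src/kresolve/kmer_bloom.py` — canonical rolling hashing, Bloom filter, read indexing.
- `src/kresolve/repeat_finder.py` — site detection, coverage-adaptive test planning.
- `src/kresolve/path_support.py` — window evaluation, complex-repeat expansion.
- `src/kresolve/resolver.py` — edit planning/application and the run driver.
- `src/kresolve/simulate.py` — synthetic genomes, reads, unitig DBG, scoring.
- `src/kresolve/cli.py` — `kresolve resolve` / `kresolve simulate`.
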