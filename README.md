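# spacerkit

Toolkit for profiling CRISPR spacer repertoires from repeat-anchored amplicon
sequencing, with a ground-truthed synthetic-community generator for
end-to-end validation.

Stages (each usable as a library call or CLI subcommand):

- **simulate** — site spacer pools with an exact overlap design, primer-
  anchored amplicon reads (truncated terminal repeats, internal repeat
  variants at declared frequencies, substitution errors), and target genomes
  with planted protospacers + PAM.
- **extract** — quality trimming (3' Phred trim, no ambiguous bases),
  mismatch-tolerant direct-repeat anchoring on both strands, inter-repeat
  spacer extraction with orientation normalization, internal repeat-variant
  census.
- **cluster** — radius-certified clustering by substitution distance
  (default: every member within 5 substitutions of its cluster consensus),
  per-position majority consensus centers.
- **diversity** — Chao1 (+SE, 95% interval), ACE (+SE), Shannon, Simpson,
  Good's coverage, estimated library coverage percent.
- **compare** — cross-site Venn sharing via tolerant one-to-one consensus
  matching, abundance concentration, self-complementary spacer detection.
- **scan** — exhaustive full-length protospacer search on both strands
  (hits require < 5 mismatches by default), 8-nt flank extraction, PAM
  position-weight matrix / information content / motif call.
- **find-arrays** — CRISPR array detection in genomes, anchored on a known
  repeat or de novo (k-mer seed + consensus extension), honoring repeat
  23-47 bp, spacer 26-50 bp, minimum three spacers.

## CLI

```bash
spacerkit simulate --sites 3 --pool-size 100 --shared 30 --shared-all 10 \
    --reads 10000 --seed 1 --out sim/
spacerkit extract --fastq sim/site1.fastq --repeat $(sed -n 2p sim/repeat.fasta) \
    --site site1 --out site1.spacers.tsv
spacerkit cluster --spacers site1.spacers.tsv --out site1.clusters.tsv
spacerkit diversity --clusters site1.clusters.tsv --out diversity.tsv
spacerkit compare --clusters site1.clusters.tsv --clusters site2.clusters.tsv \
    --out sharing.json
spacerkit scan --queries consensuses.fasta --targets genome.fasta --out hits.tsv \
    --pam-out pam.json
spacerkit find-arrays --genome genome.fasta --out arrays.tsv
```

Or run everything from one config:

```bash
spacerkit run --config config.yaml
```

```yaml
# config.yaml
seed: 7
output_dir: out
synthetic:
  n_sites: 3
  pool_sizes: [100, 100, 100]
  pairwise_shared: 30
  shared_all: 10
  reads_per_site: 10000
  error_rate: 0.0
thresholds:
  min_quality: 20
  cluster_radius: 5
  sharing_mismatch: 5
  protospacer_max_mismatch: 4
targets_fasta: null   # set a FASTA path to enable the scan/PAM stage
```

Re-running an identical config reproduces every output file byte-for-byte.

## Layout

```
src/spacerkit/
  seqs.py         byte-level DNA utilities, window mismatch scans, FASTQ/FASTA I/O
  simulate.py     pools / amplicon / target-genome generators + truth objects
  extract.py      trimming, repeat anchoring, spacer extraction, variant census
  cluster.py      radius-certified bisecting k-means, consensus centers
  diversity.py    Chao1, ACE, Shannon, Simpson, Good's coverage
  compare.py      Venn sharing, abundance concentration, self-complementarity
  protospacer.py  exhaustive scanning, PAM profiles and motif calls
  arrays.py       anchored and de novo CRISPR array detection
  pipeline.py     config-driven orchestration
  cli.py          click CLI (`spacerkit ...`)
```
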