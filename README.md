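# herbauth

Quality control of multi-ingredient herbal preparations by ITS2
metabarcoding, with a companion in-silico qPCR specificity check and
digital-PCR Poisson quantification.

The pipeline mirrors a high-throughput amplicon workflow:

1. **Read QC** (`herbauth.io_qc`) — phred+33 FASTQ in; reads kept when the
   mean quality is ≥ Q20 and the length is within 300–500 bp; PCR primers
   masked off the read ends; run-level gates (≥ 10,000 reads; 99%/97%/95% of
   targeted positions covered at depth 1/20/100).
2. **ITS2 trimming** (`herbauth.its2_hmm`) — small Plan7-like profile HMMs
   of the conserved 5.8S-3' and 28S-5' rRNA flanks locate ITS2 proper by
   glocal Viterbi; everything outside the span between the flanks is
   trimmed. Residual rRNA in reference sequences is what causes
   cross-species false positives, so this step is applied to both the
   reference database and (by default) the reads. Score thresholds are
   calibrated against a dinucleotide-shuffled null.
3. **Reference database** (`herbauth.refdb`) — FASTA + two-rank taxonomy
   TSV in; curation trims flanks, deduplicates, flags identical sequences
   labelled with different species, and builds an 8-mer index.
4. **Classification** (`herbauth.classify`) — overlap alignment (match +1,
   mismatch −1, gap open −2, extend −1) against k-mer-prefiltered
   candidates; a hit qualifies at ≥ 97% identity and ≥ 80% query coverage;
   unique best score wins, ties become AMBIGUOUS (genus-collapsed when
   possible). Abundance tables and prescription screening (detection ≥ 2
   reads) follow.
5. **qPCR / dPCR** (`herbauth.qpcr`) — mismatch-count + 3'-window primer
   binding rule for in-silico specificity; Ct < 32 scores presence; digital
   PCR copies via λ = −ln(1 − p) with a Clopper–Pearson CI.
6. **Simulation** (`herbauth.simulate`) — synthetic reference panels,
   flanked amplicon templates (mode length 488 bp) and reads with
   Ion-Torrent-like errors (substitutions, ±1 homopolymer indels,
   truncations), all deterministic under a seed. Includes the scripted
   conserved-flank false-positive experiment and the mixture-recovery
   experiment.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the DP kernels, false-positive suppression, 10,000-read
mixture recovery over 5 seeds, filter exactness, qPCR/dPCR math); the rest
are per-module unit and property tests.

## CLI

```sh
herbauth simulate --config sim.json --seed 7 --out-dir sim/
herbauth qc --in sim/reads.fastq --out filtered.fastq --primers primers.tsv --stats filter_stats.tsv
herbauth build-db --fasta sim/references.fasta --taxonomy sim/taxonomy.tsv --out db/
herbauth classify --db db/ --in filtered.fastq --out table.tsv
herbauth screen --table table.tsv --prescription rx.txt
herbauth trim --in refs.fasta --out trimmed.fasta            # HMM ITS2 extraction only
herbauth primer-check --primers primers.tsv --templates templates.fasta
herbauth ct-call --in ct.tsv --threshold 32
herbauth dpcr --in chips.tsv
```

File formats: FASTQ (phred+33), FASTA, taxonomy TSV (`id`, `species`,
`genus`), primers TSV (`name`, `forward`, `reverse`), Ct TSV (`sample`,
`assay`, `ct`), chip TSV (`name`, `total_wells`, `positive_wells`).
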