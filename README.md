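# jittertag

Jitter-tolerant cell-barcode profiling, extraction and error correction for
combinatorial (split-pool) single-cell sequencing libraries.

Combinatorial barcoding reads carry several fixed-length barcode elements at
designed positions, but technical artifacts (incomplete synthesis, polymerase
slippage, ligation indels) shift them by a base or two — "jitter" — and clip
them at read edges. Tools that assume fixed positions discard those reads.
`jittertag` first profiles where each whitelist's barcodes actually occur in
a read subsample, then extracts and error-corrects barcodes while searching a
±x window around each expected position with up to m mismatches, preferring
perfect matches, then fewest mismatches, then smallest positional offset;
ties between distinct barcodes yield a null (all-N) element. Window
candidates running off a read edge are N-padded, with each pad counted as a
mismatch, so edge-truncated barcodes are still recoverable.

## Pipeline

```
FASTQ + whitelists ─▶ seed ─▶ profile TSVs ─▶ harvest ─▶ positions CSV
                                                            │
FASTQ + whitelists + positions CSV ─────────▶ reap ─▶ SAM / interleaved FASTQ
                                               ▲               │
                     (optional) weed ──────────┘    (optional) sift
```

* **seed** — scan a read subsample (default 10 000 reads) for *exact*
  whitelist occurrences at every position; one run per whitelist.
* **harvest** — pick the modal start per whitelist, flag anomalies
  (low read fraction, multimodal histograms, absent whitelists) and write
  the expected-positions CSV.
* **reap** — match every element in every read under the jitter/mismatch
  budgets (defaults: `--jitter 1 --max-mismatches 1`), assemble the
  corrected barcode + UMI, and emit unaligned SAM (CR/CB/UR/UY plus
  XM/XJ/XS diagnostic tags) or interleaved FASTQ, with a stats JSON.
* **weed** — recover a barcode the provider already demultiplexed into the
  FASTQ header; feed the resulting TSV back into `reap --weed-table`.
* **sift** — drop reads whose barcode contains null elements.
* **simulate** — generate synthetic libraries with injected jitter,
  substitutions and edge truncations plus a ground-truth ledger.

Two matching backends produce identical output: `--backend set`
(precomputed mismatch-variant index; default, suited to ≤96-barcode rounds)
and `--backend trie` (prefix trie + pigeonhole seed index; suited to large
whitelists, where the variant index would exceed its memory cap).

## Quick start

```sh
# one seed run per whitelist
jittertag seed --fastq R1.fastq.gz --fastq R2.fastq.gz \
    --whitelist bc1:bc1.txt --samples 10000 --out bc1.profile.tsv

jittertag harvest --profile bc1.profile.tsv --profile bc2.profile.tsv \
    --profile bc3.profile.tsv --out positions.csv --report harvest.txt

jittertag reap --fastq R1.fastq.gz --fastq R2.fastq.gz \
    --positions positions.csv \
    --whitelists bc1:bc1.txt --whitelists bc2:bc2.txt --whitelists bc3:bc3.txt \
    --jitter 1 --max-mismatches 1 \
    --umi read1:37-44 --target read2:all \
    --format sam --out tagged.sam

jittertag sift --input tagged.sam --format sam --out sifted.sam
```

Whitelists are plain text, one ACGT barcode per line, all the same length,
in the same orientation as they appear in the read (no reverse
complementing is done). The positions CSV has the columns
`whitelist,read_index,start,read_fraction` (1-based inclusive starts); rows
can also be written by hand. Barcodes at the very start or end of a read
need a larger `--max-mismatches`, since clipped bases are N-padded and each
pad counts as one mismatch.

If harvest reports a *low_read_fraction* flag, that barcode was probably
consumed by provider demultiplexing: recover it from the headers instead
and remove its CSV row:

```sh
jittertag weed --fastq R1.fastq.gz --whitelist sample:sample.txt --out weed.tsv
jittertag reap ... --weed-table weed.tsv --weed-name sample --weed-insert-index 0
```

## Simulating test libraries

```sh
jittertag simulate --config design.yaml --reads 10000 --out-prefix sim/run1
```

`design.yaml` schema:

```yaml
whitelists:
  bc1: {size: 96, length: 8, min_hamming: 3, seed: 5}   # generated...
  bc2: path/to/existing_whitelist.txt                    # ...or loaded
layout:                  # read 1, in order
  - barcode: bc1
  - linker: TCAGGA
  - barcode: bc2
  - umi: 8
read1_length: 48
read2_length: 40         # read 2 is random cDNA
jitter: {0: 0.7, 1: 0.3} # per-read offset distribution (must sum to 1)
one_sub_prob: 0.1        # P(exactly one substitution in a random element)
truncate: {0: 1.0}       # leading-edge truncation distribution
seed: 3
```

Outputs: `R1.fastq`, `R2.fastq`, generated whitelists, and a
`ledger.tsv` recording every read's true barcodes, offset, substitutions,
truncation and UMI.

## Layout

```
src/jittertag/
  barcode_model.py   domain types, whitelist / positions-CSV / profile I/O
  matcher_set.py     mismatch-variant index backend (reference semantics)
  matcher_trie.py    trie + pigeonhole seed-index backend
  seed_profiler.py   FASTQ I/O, sampling, exact position profiling
  harvest.py         peak picking, diagnostics, positions CSV
  reap.py            extraction, SAM / interleaved-FASTQ emission, stats
  weed_sift.py       header-barcode recovery and null-read filtering
  fixtures.py        synthetic library generator + ground-truth ledger
  cli.py             the jittertag command
```
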