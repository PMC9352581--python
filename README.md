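# dnatape

Tools for simulating, parsing and decoding **sequential insertional DNA
recording arrays** ("tapes"): tandem arrays of a short monomer in which each
write deposits a barcode+key insertion at the single active site, shifting
the writable position one unit along the array. Because writing is strictly
sequential, the physical order of insertions is the temporal order of the
recorded events.

The package covers the full computational stack:

| module | what it does |
| --- | --- |
| `dnatape.tape_sim` | canonical tape rendering, epoch-programme simulation, clonal-expansion simulation with true genealogy, read noise, exact state-space math |
| `dnatape.tape_parse` | insertion extraction from amplicon reads, editing-pattern classification, efficiency / sequential-error metrics, barcode whitelisting, edit scores, long-array read grouping |
| `dnatape.event_order` | site unigrams, adjacent-site bigram matrices, and the unigram-initialized adjacent-swap temporal decoder |
| `dnatape.tape64_codec` | 64-barcode text codec (31-character alphabet with 2–4× redundancy, 7:5:3:1 within-epoch weights), encoder, cluster-and-order decoder, alignment-based reconstruction scoring |
| `dnatape.lineage_tree` | target-barcode correction, UMI collapsing, order-aware shared-edit distance, UPGMA/NJ trees, Fitch parsimony, tape-block bootstrap, cohort summaries |
| `dnatape.cli_io` | FASTA/FASTQ/TSV/Newick/JSON/YAML readers and writers plus the `dnatape` CLI |

## CLI

Every stage is exposed as a subcommand; stochastic commands require
`--seed` and are byte-deterministic given one.

```sh
# simulate a 3-epoch programme and recover the event order
cat > prog.yaml <<EOF
epochs: [[["AA", 1.0]], [["CC", 1.0]], [["GG", 1.0]]]
per_epoch_edit_prob: 0.5
EOF
dnatape simulate-programme --programme prog.yaml --n-tapes 5000 --seed 1 --out reads.fasta
dnatape order --reads reads.fasta

# parse reads and compute editing metrics
dnatape parse --reads reads.fasta --out parsed.tsv
dnatape metrics --parsed parsed.tsv

# simulate a clonal expansion, then rebuild its lineage
dnatape simulate-clone --generations 12 --sample-size 100 --seed 1 \
    --out-cells cells.tsv --out-tree truth.nwk
dnatape lineage-tree --cells cells.tsv --method upgma --out upgma.nwk
dnatape lineage-bootstrap --cells cells.tsv --reps 100 --seed 1 --out boot.nwk
dnatape lineage-summary --cells cells.tsv

# text codec
dnatape encode "GOD FIRST?" --out plan.tsv
dnatape decode --reads message_reads.fasta --barcode-len 3
```

## Conventions

* Sites are numbered 1..n from the 5′ end; insertions occupy a strict
  prefix of sites.
* A rendered tape is `target_bc + key + monomer` followed, per edited
  site, by `barcode + key` at the junction 3′ of that site's monomer.
* Reads are assumed pre-oriented and trimmed to the array; monomer
  matching tolerates at most one substitution (`--max-monomer-mismatch`,
  default 0).
* The order-aware distance between two cells is the panel's total site
  count minus the number of shared edits counted along identical edited
  prefixes; self-distance is defined as 0.
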