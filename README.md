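# mafstream

A streaming processor for genome alignments in the Multiple Alignment
Format (MAF).  Synteny blocks are read lazily, passed through a
user-defined chain of filters — data extraction, sliding-window alignment
cleaning, block-wise population-genetic statistics and distance-based
phylogenetics — and exported to MAF, Fasta/Clustal/Phylip (with
coordinate-bearing headers), Newick tree lists, CSV tables or VCF.
Pipelines are declared in a small `key=value` option language and run from
the command line; every stage is a Python generator, so processing is
single-pass and bounded-memory regardless of input size.  Plain, zip, gzip
and bzip2 files are read and written transparently.

## Command-line usage

A pipeline is an option file:

```text
# primates.opt — subset, merge, clean, window, tree
input.file=alignment.maf.gz
input.format=Maf
maf.filter=\
  Subset(species=(Human,Chimp,Gorilla,Orang,Macaque), strict=yes),\
  Merge(species=(Human,Chimp,Gorilla,Orang,Macaque), dist_max=0),\
  XFullGap(species=(Human,Chimp,Gorilla,Orang,Macaque)),\
  WindowSplit(window.size=1000, align=left),\
  DistanceEstimation(method=kimura),\
  DistanceBasedPhylogeny(method=nj),\
  OutputTrees(file=windows.nwk)
```

```sh
mafstream primates.opt                  # run it
mafstream primates.opt input.file=other.maf   # override any key
mafstream --list-filters                # registered filters + signatures
mafstream-fixtures --blocks 10 --out demo.maf # synthetic demo data
```

Option-file grammar: `key=value` lines, `#` comments, backslash
continuation; `maf.filter` holds a comma-separated list of
`Name(arg=value, arg=(list, of, items))` invocations.  Flags are
`yes`/`no`; list items may be nested calls (used by
`SequenceStatistics(statistics=(BlockLength, PairwiseDivergence(...)))`).
Command-line `key=value` arguments override file entries.  Unknown keys
warn; unknown filters or arguments are errors.

Registered filters: Subset, Merge, Concatenate, XFullGap, FeatureFilter,
ExtractFeature, SelectChr, MinBlockLength, MinBlockSize, AlnFilter,
AlnFilter2, EntropyFilter, MaskFilter, QualityFilter, WindowSplit,
SequenceStatistics, DistanceEstimation, DistanceBasedPhylogeny,
NewOutgroup, DropSpecies, Output, OutputAlignments, OutputTrees,
VcfOutput.  `mafstream --list-filters` prints the full signatures.

## Library layout

| module                 | contents                                                            |
| ---------------------- | ------------------------------------------------------------------- |
| `mafstream.model`      | `MafSequence`, `MafBlock`, `Feature(Set)`, coordinate arithmetic    |
| `mafstream.io`         | MAF/Fasta/GFF3/BED/Newick/VCF readers & writers, compression        |
| `mafstream.filters`    | the streaming filter chain (all generators)                         |
| `mafstream.statistics` | per-block statistics and the CSV-streaming statistics stage         |
| `mafstream.phylo`      | K80 & observed distances, NJ/BioNJ/UPGMA/WPGMA, rerooting, tallies  |
| `mafstream.pipeline`   | option-language parser, filter registry, pipeline executor          |
| `mafstream.simulate`   | K80 block simulator and synthetic MAF/GFF3 fixture generators       |

Conventions: all coordinates are 0-based UCSC MAF coordinates internally
(minus-strand starts relative to the reverse complement); exported
alignment headers are `species.chromosome/first-last(strand)` with
1-based inclusive forward-strand positions; quality scores are stored
gap-expanded with a `-1` sentinel at gaps; sub-block slicing drops the
aligner block score.

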