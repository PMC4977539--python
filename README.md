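# seracon

Quantify serum-derived cross-species RNA contamination in cell-culture
extracellular-RNA sequencing data.

Cell cultures are routinely grown in media supplemented with animal serum,
which carries its own RNA into every "cell-derived" RNA preparation. When
reads from such an experiment are aligned competitively against the host
genome and the serum-donor genome, the reads that align to exactly one
genome quantify the contamination: `seracon` computes the ratio of
contaminant-specific to host-specific read counts as a per-sample
contamination index, compares groups by fold change and an exact two-tailed
Mann–Whitney U test, and ships the supporting composition (RPM, biotype
fractions, Pearson clustering) and qPCR (ΔCq, geNorm) analytics.

Everything runs on synthetic data with known ground truth — no downloads
required. The built-in read simulator, the seed-and-extend classifier, and
an exhaustive dynamic-programming alignment oracle let every stage be
verified end to end.

## Modules

| module | what it does |
|---|---|
| `seracon.simulate` | diverged genome pairs, labeled FASTQ read mixtures at a known contamination fraction, grouped biotype count tables, Cq tables |
| `seracon.qc` | per-cycle quality summary, longest >Q30 quality span, min-span discard rule, trimming, seeded subsampling |
| `seracon.classify` | competitive classification against two genomes (specific-A / specific-B / both / neither) via a local ungapped seed-and-extend aligner, or from external SAM pairs |
| `seracon.oracle` | independent brute-force reference implementation of the alignment contract |
| `seracon.contamination` | contamination index, fold change of group means ± SEM, exact Mann–Whitney U, unpaired t-test, mixture-fraction estimate r/(1+r) |
| `seracon.composition` | RPM normalization, biotype composition, top-k features, depletion efficiency, average-linkage Pearson clustering with Newick output |
| `seracon.qpcr` | ΔCq relative quantities, geNorm M-values/ranking, multi-reference normalization factors, detection flags |
| `seracon.pipeline` / `seracon.cli` | qc → classify → quantify orchestration with a provenance manifest; `seracon` CLI |

## CLI

```sh
# synthesize a genome pair and a labeled read mixture
seracon simulate --length 20000 --divergence 0.15 --n-reads 10000 \
    --contamination 0.1 --seed 1 --out-dir sim/

# quality gate + subsample
seracon qc --fastq sim/reads.fastq --threshold-q 30 --min-span 20 \
    --subsample 100000 --seed 1 --out qc/sample1

# competitive classification (built-in aligner, or --sam-a/--sam-b)
seracon classify --fastq qc/sample1.fastq --ref-a ref_a.fasta \
    --ref-b ref_b.fasta --sample-id sample1 --out cls/sample1

# group quantification from per-sample classification JSONs
seracon quantify --classifications cls/ --samples samples.tsv --out report.tsv

# composition and qPCR analytics
seracon compose --counts counts.tsv --sample-anno groups.tsv --out-dir comp/
seracon qpcr --cq cq.tsv --controls U6,U2,miR-103a-3p,miR-24-3p --out qpcr/run1

# or everything at once from a JSON config
seracon run --config config.json
```

Exit codes: 0 ok, 1 input error, 2 internal error.

## Notes

- Coordinates are 0-based half-open on the forward strand; qualities are
  PHRED+33 only (PHRED+64 is rejected, not auto-detected).
- The built-in aligner is ungapped by design (the simulator emits no
  indels), which keeps it exactly checkable against `seracon.oracle`;
  gapped alignments can be ingested via SAM.
- Text formats only: FASTA/FASTQ (gzip detected by magic bytes), SAM, TSV,
  JSON, Newick.
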