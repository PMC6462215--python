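# nexuskit

Analysis toolkit for ChIP-nexus profiling of the dual corticosteroid-receptor
system: the high-affinity mineralocorticoid receptor (MR) and the
lower-affinity glucocorticoid receptor (GR), which co-occupy glucocorticoid
response elements (GREs) and respond differently to a corticosterone (CORT)
pulse and its washout.

ChIP-nexus reads carry a 9-nt random barcode followed by a genomic insert
whose 5′ end marks the position where λ-exonuclease digestion stopped at the
crosslinked receptor.  This geometry enables two things a conventional
ChIP-seq pipeline cannot do: PCR duplicates are identified as reads sharing
*(chromosome, strand, 5′ stop, barcode)* rather than position alone, and
binding sites can be delimited at near-nucleotide resolution by pairing the
plus-strand stop border (left of the protein) with the minus-strand stop
border (right of it).

The package implements the full analysis as a library (`src/nexuskit/`),
a set of numbered analysis drivers (`analysis/`), and a CLI (`nexuskit`):

| stage | module | what it does |
|---|---|---|
| simulate | `nexuskit.simulate` | synthetic genome, planted GRE sites, per-condition occupancy, ChIP-nexus reads with borders/barcodes/duplicates, ground truth |
| preprocess | `nexuskit.preprocess` | sliding-window quality trim (4 bp, Q20), length filter (29–59 bp), barcode split, exact alignment (or SAM ingestion), MAPQ > 20 filter, barcode dedup |
| peaks | `nexuskit.peaks` | Poisson local-λ peak calling against an input control, Benjamini–Hochberg FDR < 0.05, fixed 100-bp peaks, replicate-reproducibility filter |
| borders | `nexuskit.borders` | strand-specific stop-border detection and constrained pairing (10–100 bp protected widths) |
| annotate | `nexuskit.annotate` | within-gene / ±5 kb flank / intergenic categories, gene-level multiplicity |
| cobind | `nexuskit.cobind` | ≥1-bp overlap Venn counts, washout retention ratios, midpoint-referenced co-positioning with Jensen–Shannon similarity |
| motifs | `nexuskit.motifs` | log-odds PWM scanning around summits, enrichment fractions, summit-relative frequency profiles |
| pipeline | `nexuskit.pipeline` | end-to-end orchestration, summary tables, run manifest |

The statistical core of the peak caller: the pooled-strand tag count $k$ in a
100-bp window is tested against $\mathrm{Poisson}(\lambda_{\mathrm{local}})$
with

$$\lambda_{\mathrm{local}} = \max(\lambda_{\mathrm{BG}},\ \lambda_{100},\ \lambda_{1\mathrm{k}},\ \lambda_{10\mathrm{k}})$$

where each $\lambda_W$ is the input-control rate in a $W$-bp window centred
on the candidate, depth-scaled to the treatment; window p-values are
converted to Benjamini–Hochberg q-values and merged significant windows are
reported as fixed-width peaks centred on the summit of the extended-read
pileup.

## Worked example

Run the numbered drivers in order (defaults: seed 1, outputs under
`results/`):

```sh
python analysis/01_simulate.py       # 200 kb genome, 100 sites, 6 IP samples + input
python analysis/02_preprocess.py
python analysis/03_call_peaks.py
python analysis/04_annotate.py
python analysis/05_dynamics.py
python analysis/06_borders.py
python analysis/07_copositioning.py
python analysis/08_motifs.py
```

With seed 1 the dynamics step prints:

```
  vehicle : 0.0% of GR peaks overlap an MR peak
  CORT    : 78.5% of GR peaks overlap an MR peak
  washout : 0.0% of GR peaks overlap an MR peak
  MR: washout retains 34.9% of CORT peaks (29/83)
  GR: washout retains 1.3% of CORT peaks (1/79)
```

Reading this: during the CORT pulse both receptors bind (83 MR / 79 GR
peaks, most shared); after washout the low-affinity GR all but vanishes
(1.3% of its CORT peaks) while the high-affinity MR retains about a third
(34.9%) — the planted occupancy asymmetry recovered through the whole
pipeline.  The border step reports protected regions of 26–34 bp (median
30, the planted width), the co-positioning step reports a Jensen–Shannon
divergence of 0.001 nats between MR and GR coverage around shared-site
midpoints (the two receptors occupy the same DNA), and the motif step finds
the GRE in ~53% of CORT peaks with a frequency profile peaking exactly at
summit offset 0.

The same run is available as one command:

```sh
nexuskit run --outdir results/run --seed 1
```

## Notes

- Packaged motif matrices (`nexuskit/data/*.synthetic.jaspar`) are synthetic
  consensus-derived probability matrices (GRE, GATA3, AP-1), not copies of a
  curated database.
- The peak caller is a transparent re-implementation of the MACS2 design,
  not a wrapper; exact numerical equality with MACS2 is not promised.
- See `docs/methods.md` for the model, parameter defaults, and limitations.
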