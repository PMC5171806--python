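# Methods

## The problem

5'-end-enriched RNA sequencing of bacteria (triphosphate capture followed by
template-switching reverse transcription) yields read libraries whose R1 5'
ends mark transcription start sites (TSS) at single-base resolution.
`cappswitch` turns per-replicate read alignments into a genome-wide TSS map
and analyses promoter architecture and condition-specific promoter usage:
which gene each TSS serves, which TSS is a gene's primary start, how long
the 5' UTRs are, which TSS are specific to a carbon source, which genes
switch primary TSS between substrates, and which expression shapes and
upstream sequence motifs those TSS groups share.

## TSS calling model

Read 5' ends scatter within a few bases of the true initiation site
(polymerase slippage, soft-clipped first bases, small mapping wobble), so
raw per-position read-start counts are clustered per strand within a 5 bp
sliding window: repeatedly take the unassigned position with the most read
starts (ties break to the 5'-most base in transcription direction — the
earliest base at which initiation could have occurred), absorb unassigned
neighbours within ±2 bp, and represent the cluster by its peak. Counts are
normalized to read starts per million counted alignments (RPM).

A TSS is called for a condition only when **every replicate** shows a
matching cluster (peak-to-peak distance ≤ ±2 bp) with RPM **strictly
greater than 10**. The two-replicate rule is the specificity control: a
spurious pileup in one library is almost never mirrored at the same base in
an independent culture. By default the threshold applies to the cluster's
summed count; `count_mode="peak_only"` applies it to the peak base alone —
the two modes bracket the reasonable readings of a window-then-threshold
procedure and are both exposed. The reported coordinate is the peak of the
replicate-pooled profile inside the matched window, so the final position
is symmetric in the replicates.

Per-condition TSS lists are merged into one cross-substrate set with the
same ±2 bp tolerance (one positional tolerance throughout); the
representative position is the strongest member's pooled-profile peak and
per-condition expression is carried over. Conditions in which a merged TSS
was *not* called can be back-filled with sub-threshold RPM from the raw
tracks (`attach_subthreshold_rpm`): fold-change and clustering analyses
need the low values, not zeros.

## Classification and distances

Against a gene annotation (1-based inclusive coordinates throughout, GFF3
convention; the chromosome is circular by default so downstream searches
wrap), each TSS receives exactly one of four classes: intragenic if inside
≥1 gene (IntraS/IntraA by strand match), otherwise intergenic
(InterS/InterA by the strand of the nearest gene in the TSS's transcription
direction). Distances follow the convention of published bacterial TSS
tables: TSS → translation start for InterS/IntraS/IntraA, TSS → gene 3'
end for InterA.

Open choices made here:

* **Overlapping genes.** A same-strand containing gene beats an
  opposite-strand one (IntraS is the biologically specific call); among
  several same-strand hosts, the gene whose own start is nearest upstream
  of the TSS wins.
* **Primary TSS.** Per gene, the InterS TSS with the most reads; `global`
  mode sums mean RPM over all conditions, `per_condition` mode ranks among
  TSS detected in that condition. Ties break toward the TSS nearer the
  start codon (the more parsimonious promoter assignment).
* **Leaderless cutoff.** 5' UTR shorter than 10 bp (too short for a
  Shine–Dalgarno site roughly centred 8–10 bp upstream of the start
  codon); exposed as a parameter since any single cutoff is a convention.

## Condition analysis

"Substrate-specific" defaults to strict exclusivity (detected on exactly
one condition); a `vs_reference` mode instead takes "detected on X but not
on the reference sugar", which matches how specific gene sets are usually
contrasted against glucose. The ≥30-fold expression filter is inclusive at
30 and, with the default zero floor, treats a silent condition as an
infinite fold change (a site that is off on one substrate has trivially
changed ≥30-fold); `floor_rpm` gives a pseudofloor alternative. The
association between substrate-specific promoters and differential
expression uses Pearson's χ² on the 2×2 gene table, df = 1, no continuity
correction (SciPy's `chi2_contingency(correction=False)`).

## Expression clustering

Profiles are log2(x+1)-transformed (the +1 RPM pseudocount makes silent
conditions finite; exposed as a flag), median-centred per TSS and scaled to
unit sum of squares, leaving only profile *shape*. Constant rows are
dropped. K-means uses the city-block (L1) metric with component-wise
**median** centroid updates — the exact L1 minimizer, making the objective
provably non-increasing per iteration. Initialization samples k distinct
rows; 10 restarts keep the best objective; clusters emptied by an update
are re-seeded from the farthest point (repeatedly, since duplicate rows can
cascade). `CityBlockKMeans` follows the scikit-learn estimator contract
(`fit`/`predict`/`transform`, `cluster_centers_`, `labels_`, `inertia_`)
and composes with sklearn tooling; `kmeans_cityblock` wraps it for
row-labelled DataFrames and canonically sorts rows so results are
independent of input order. Default k = 24.

## Motif windows and scanning

Window offsets count in the anchored feature's transcription direction
(negative = upstream; "5–20 bp upstream" = offsets −20..−5, 16 bp;
"−250..+50 around the start codon" = 301 bp with offset 0 the first codon
base). Minus-strand anchors take the mirror genomic interval
reverse-complemented, so sequences always read 5'→3' on the transcript.
Built-in specs cover the −35 (−50..−25) and −10 (−20..−5) promoter-element
searches, the TSS context (−100..+10) and the start-codon context
(−250..+50).

PWMs are built from aligned sites with a +0.25 pseudocount per cell and
scored as log-odds against a mononucleotide background (genome
frequencies by default). A hit is any offset reaching ≥ 80% of the maximal
attainable score. De novo motif discovery (EM over a dinucleotide
background) and E-value statistics are deliberately out of scope: the
module prepares windows *for* discovery tools and replaces the
site-scanning step with a transparent threshold rule.

## Synthetic data generator

`simulate_dataset` emulates the statistics this pipeline actually consumes,
at desk scale:

* a random chromosome with 65% A+T (typical of plant-fermenting
  clostridia), default 100 kb with 60 genes — large enough for spacing
  structure, small enough that every test runs in seconds;
* genes in fixed slots with ≥200 bp promoter headroom; planted TSS 20–150
  bp upstream of their gene (intergenic-sense by construction) plus an
  optional intragenic-sense fraction;
* per-TSS strengths uniform on 20–300 RPM (calling-threshold-relevant
  range); per-condition structure plants substrate-specific sites (on one
  substrate, 0–3% basal leakage elsewhere — sub-threshold and ≥30-fold
  down) and primary-switching gene pairs; expressed sites get lognormal
  (σ = 0.25) condition-to-condition wobble matching the high replicate but
  imperfect cross-substrate reproducibility of real libraries;
* reads per replicate drawn binomially per site (independent replicates),
  jittered by a discrete Gaussian truncated at ±2 bp (inside the 5 bp
  clustering window by design), plus a diffuse uniform — optionally
  AT-biased — background (default 1% of reads), emulating promiscuous
  initiation at AT-rich sequence;
* default library size 500,000 counted reads per replicate, inside the
  0.4–3.4 M range of real single-culture libraries;
* everything derives from one seed via deterministic RNG substreams.

What it does **not** emulate: mapping artefacts and mappability gaps,
operon structure and internal sub-operon promoters, 3'-biased coverage,
library-chemistry strand flips, or correlated (batch) noise between
replicates. Passing recovery tests therefore demonstrate the calling
logic's correctness under the stated noise model, not performance on real
libraries with alignment artefacts.

`evaluate_recovery` matches calls to planted sites one-to-one, greedily by
distance within ±2 bp on the same strand, and reports precision, recall
and the signed position-error histogram.

## Numerical and determinism choices

* Strict `>` at the 10 RPM threshold; ≥ is never used.
* All tie-breaks are total orders (count desc, then 5'-most; RPM desc, then
  distance, then position), so identical inputs give byte-identical output
  tables; the CLI writes resolved parameters and input checksums beside
  every run.
* RPM values are serialized to 6 decimals; table round-trips are exact for
  text/integer fields and to 1e-6 for RPM.
* Degenerate inputs: empty tracks, empty annotations, zero library sizes
  and degenerate χ² margins raise errors rather than propagating NaN;
  constant expression rows are dropped with a report.

## Problem sizes

The bundled test suite and the acceptance script run entirely on generated
data: genomes of 30–200 kb, 20–120 genes, 25–200 planted TSS, 2–7
conditions × 2 replicates. The acceptance study uses 7 substrate-named
conditions, 100 genes, 200 planted TSS (25% intragenic, 25%
substrate-specific, 30% of two-promoter genes switching), chosen as the
smallest configuration in which every analysis layer (classification mix,
specificity, switching, 24-cluster K-means) has non-trivial ground truth.

## Known limitations

* Single-chromosome genomes only; multi-contig BAMs are reduced to the
  first reference with a warning.
* The classifier assigns intergenic TSS to the nearest downstream gene with
  no distance cap by default (the intergenic region bounds it naturally on
  gene-dense bacterial chromosomes); a cap is available for sparse toy
  genomes.
* The PWM scanner has no E-value model; its threshold is a fraction of the
  maximal score.
* Whether R1 maps sense or antisense to the transcript depends on library
  chemistry and cannot be inferred from the data; the `--invert-strand`
  flag makes the assumption explicit and reversible.
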