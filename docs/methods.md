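# Methods

## Signal model and pipeline

A tandem duplication (TD) on a fraction of the sequenced genomes changes
three things in a short-read alignment against the reference:

1. **Read depth (RD)** rises over the duplicated interval, by a factor
   1 + purity when a haploid variant genome carrying one extra copy is mixed
   with the normal genome at the given purity and fixed total depth.
2. **Mapping quality (MQ)** drops over duplicated sequence, because reads
   drawn from repeated sequence map ambiguously.
3. **The copy1→copy2 junction** produces split reads (the read prefix
   matches the end of the duplicated interval, the suffix matches its
   start, so the aligner soft-clips one side) and everted discordant pairs
   whose apparent insert size is close to the duplication length.

The caller uses signal (1)+(2) to find *where* to look and signal (3) to
decide *what* it is (tandem vs interspersed) and *exactly where* the
breakpoints lie. It needs no control sample and no assumption on the RD
distribution: anomaly scoring is distance-based and the detection threshold
is a boxplot fence.

### Stage 1 — binned (RD, MQ) profile

- Bins are contiguous, non-overlapping, `lb` = 1000 bp; a bin whose
  reference window contains `N` is masked and carries no signal. The final
  (truncated) bin is averaged over its true width.
- Per-position depth is the pileup of aligned read bases of primary
  alignments (secondary/supplementary/duplicate/QC-fail excluded, so a
  sequenced base is counted once; supplementary alignments are still
  harvested later as split-read evidence). Uncovered positions contribute
  zero to both RD and MQ; per-position MQ is the mean MAPQ of covering
  reads.
- GC correction multiplies each bin by (global typical RD)/(typical RD of
  bins within ±0.002 GC fraction). The typical value is the **median**:
  duplicated bins are strong outliers, and at desk scale they are a large
  enough share of a GC class to bias a class mean and thereby depress the
  corrected RD of ordinary bins sharing the class. Median and mean coincide
  for homogeneous classes. A class with zero median leaves its bins
  uncorrected (warning).
- Both signals are smoothed by exact 1-D total-variation denoising
  (penalty `tv_lambda` = 0.15, recommended range 0.15–0.30). The solver is
  a direct taut-string style sweep, exact to floating point — no iterative
  optimisation, which makes oracle testing against a generic convex solver
  meaningful.
- The smoothed RD is segmented by recursive **circular binary
  segmentation**: for each segment the best arc (interior window vs the
  rest; arcs touching a segment end reduce to ordinary splits) is found by
  a sliding-window scan over a dense-then-geometric grid of arc lengths,
  and accepted when it beats a permutation null (`cbs_alpha` = 0.01,
  `cbs_permutations` = 1000, sequential early stopping once the p-value
  estimate is clearly on either side of alpha). Because greedy recursion
  freezes boundaries chosen under misspecified intermediate models, a
  post-pass re-fits adjacent breakpoint pairs jointly (exact three-mean
  changepoint fit, ±25 bins) on the **unsmoothed** GC-corrected RD — TV
  smoothing smears a step across a few bins at low SNR and would bias the
  changepoint MLE. Masked gaps split the chromosome into independently
  segmented runs; segments never bridge a gap.
- RD and MQ are standardized to z-scores (population σ over unmasked
  bins; a constant signal standardizes to zeros with a warning).

### Stage 2 — KNN anomaly scoring and candidate regions

Each unmasked bin is an object with features (z_RD, z_MQ). Its outlier
score is the mean Euclidean distance to its `k` nearest neighbours
(KD-tree; `k_fraction` = 0.2 of the scored bins, at least 1; self
excluded). Scoring bins rather than CBS segments matters: within one
sample all duplicated segments share nearly identical standardized
features, so segment-level scoring with a segment-fraction k would make
them each other's neighbours and hide them; with k = 20 % of bins, a
duplication's bins reach far outside their own kind.

The fence is UQ + θ·IQR of the per-bin scores (`theta` = 0.6, linear
interpolation quartiles). A CBS segment qualifies when the **median** of
its member-bin scores strictly exceeds the fence *and* its mean z_RD is
positive — a duplication raises depth, so depth-deficit anomalies, however
well they clear the fence, are not TD candidates. Adjacent qualifying
segments (no masked gap between) merge; boundaries snap to bin edges,
giving the rough candidate [a, b].

### Stage 3 — junction classification and refinement

Split reads with exactly one match run and one clip ≥ `min_clip` = 20 bp
are collected within S = `m`·`lb` = 2000 bp of each rough edge, including
supplementary records; SA tags provide each junction read's partner loci.

*Classification.* Tandem: post-aligned clips near the start and
pre-aligned clips near the end, all partner loci inside the candidate
(tolerance max(2S, half the candidate length), since rough edges are only
bin-accurate). Interspersed: any partner at a locus outside that
tolerance, or a partner locus exhibiting both clip patterns within a read
length — the insertion-site signature. Interspersed candidates are
dropped; candidates with no informative split reads stay `unresolved` but
are retained (see trade-offs).

*SR refinement.* A = majority post-clip POS within 2S of a; B = majority
pre-clip end within 2S of b (ties go to the breakpoint nearest the rough
edge). When one edge lacks a direct observation, the partner loci of the
junction reads seen at the *other* edge supply it; these are alignments of
the same reads, so they may move the edge beyond 2S, but only if at least
half of the implied duplication lies inside the candidate.

*PEM refinement* (only for edges SR left open). Discordant pairs with a
read within S of the (possibly SR-refined) start and
| |insert| − (b − a) | ≤ 2S, excluding reads already used as SR evidence:
A = the leftmost qualifying read position, B = the mate position of the
rightmost one + `r_l` (= 100 bp), both capped at 2S displacement.

Unrefined edges keep the bin-level boundary; overlapping calls merge into
the widest extent. Output is BED6 + VCF 4.2 with per-edge provenance.

## Simulator

The simulator replaces a FASTA → read generator → aligner chain with
direct BAM synthesis, so junction signals are exactly what an ideal
aligner would report. It emulates:

- a random reference whose GC fraction drifts block-wise (10 kb blocks,
  reflected random walk in [0.35, 0.65]) so GC correction has work to do;
  optional `N` gaps exercise bin masking;
- 10–50 kbp tandem (and optionally interspersed) duplications, placed
  uniformly with ≥ 20 kb separation — the desk-scale analogue of ~10
  events on a ~47 Mb chromosome, where sub-bin gaps between events
  essentially never occur (a floor of 2× the mean insert size is enforced
  regardless);
- paired-end 100 bp reads, insert ~ Normal(300, 30), total depth =
  `coverage`, mutant/normal mixing at `purity` (in-duplication multiplier
  1 + purity);
- junction-spanning reads as soft-clipped records with correct POS/CIGAR,
  mutual SA tags and a supplementary record when both sides are ≥ 20 bp;
  junction-straddling pairs as everted discordant pairs with the implied
  insert size;
- MAPQ degradation (probability 0.5, uniform 0–30, both config-exposed)
  for variant-genome reads drawn from duplicated sequence — an explicit
  stand-in for multi-mapping ambiguity, which direct synthesis cannot
  produce organically, so that MQ carries the signal the 2-D profile
  expects.

It does **not** model sequencing errors (a substitution-rate flag exists,
default 0, only affecting emitted sequences), platform quality profiles,
indels, chimeras, real repeat structure, or reference bias. Passing tests
therefore demonstrate the pipeline's behaviour under its own signal
model — clean Poisson-sampled coverage with idealized junction
evidence — not robustness to real-data artefacts such as alignment noise
in low-complexity regions. By default reads are written without SEQ/QUAL
(`*`), which the format permits and which keeps simulation fast; set
`write_sequences` for records with real bases.

Everything is deterministic given (config, seed): the seed feeds three
independent generator streams (reference, event placement, reads), and
BAMs are written pre-sorted without program-header lines so repeated runs
are bit-identical.

## Benchmark harness and problem sizes

`tdscan grid` / `scripts/acceptance.py` run simulate → call → evaluate
over coverage {4, 6, 8}X × purity {0.2, 0.4, 0.6}. The desk-scale study
uses a 5 Mb reference, 10–15 events per sample and 3 samples per cell —
sizes chosen so the whole grid completes in minutes on one CPU while each
cell still averages ~35 events. Matching uses the >50 %-coverage rule with
pooled call coverage per truth (stable under call fragmentation); one call
recalls at most one truth for boundary statistics (largest overlap,
leftmost on ties). Boundary bias averages (|ΔA| + |ΔB|)/2 over recalled
events. With 3 samples per cell the per-cell metrics carry sampling noise
of roughly ±0.1, which dominates comparisons in the hardest cell.

## Known trade-offs and limitations

- **Retention of unresolved candidates.** Candidates with no junction
  evidence keep bin-resolution boundaries. At 4–8X and purity 0.2–0.6 the
  number of junction-informative fragments per event is Poisson with mean
  of order 1, so a noticeable fraction of true events would vanish if such
  candidates were dropped; retaining them preserves sensitivity at low
  purity but mixes ~0.25–3 kb boundary errors into the boundary-bias
  average. The two goals are irreconcilable at these depths; this package
  chooses sensitivity.
- **Detection power.** The permutation-tested arc statistic needs roughly
  Δ/σ·√w ≳ 4.5 (w bins of contrast Δ against per-bin noise σ), i.e. at 4X
  and purity 0.2 events under ~25 bins are at the edge of detectability;
  losses there are detection-, not refinement-limited.
- **Close events.** Events separated by less than the detection
  resolution can merge into one candidate; junction-linked partner
  refinement then recovers the first event's extent, at the cost of the
  second.
- Within-chromosome processing only; standardization, k and the fence are
  per-chromosome. No deletion/inversion/translocation calling, no
  genotyping, no local assembly or clipped-sequence realignment: an
  interspersed duplication is recognised and excluded, not reported.
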