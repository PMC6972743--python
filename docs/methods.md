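# Methods

## The problem

Gene-expression high-throughput screening (GE-HTS) uses a small mRNA
signature as a proxy for a cellular phenotype: a perturbation whose signature
resembles the reference perturbation's signature is inferred to act on the
same pathway. The screen this package processes depletes one gene per well
across 384-well plates with pooled siRNAs, measures an eight-mRNA panel per
well by multiplexed branched-DNA hybridization read on a Luminex instrument
(median fluorescence intensity, MFI), and asks, for every library gene, how
similar its six-gene signature is to the signature of depleting the KSR1
scaffold — the positive control present in quintuplicate on every plate.

The panel: six signature probes (BNIP3L, NDRG1, ALDOC, LOXL2, BNIP3, ACSL5,
all consistently down-regulated upon KSR1 loss) and two housekeeping probes
(PPIB, HPRT) assumed invariant to the perturbations and used for per-well
cell-number correction.

## Plate and batch structure

Each 384-well plate (rows A–P, columns 1–24) carries:

- columns 1 and 24: 32 blank (water) wells, the plate-wise background;
- columns 3 and 22: five wells each of non-targeting siCont, siKSR1
  (positive control), lethal siPLK1 and siPPIB, plus 12 unused (`empty`)
  positions excluded from all computation;
- 320 library wells, one gene each.

The original controls were hand-plated at unrecorded positions within the
control columns; this package's default layout places them deterministically,
interleaving the four roles down the paired control columns, and the
placement is configurable. Plates are grouped into transfection batches
(shaker capacity: 8 plates); the deposited screen's batch→plate map is built
in as `default_batch_map()`.

## Processing chain

For each technical replicate, and for the replicate average:

1. **Background subtraction** — per plate × replicate × probe, subtract the
   blank-well center (arithmetic mean by default; median by configuration).
   Blanks are themselves transformed; negatives are retained at this stage.
2. **Flooring** — every value ≤ 0 is replaced by the minimum strictly
   positive value of that probe among the plate's non-blank, non-empty wells.
   Two choices here were genuinely open: (a) the floor pool excludes blanks,
   because post-subtraction blanks sit at ≈ 0 and would floor everything back
   to ≈ 0; (b) flooring happens *before* the geometric-mean step, because
   the geometric mean is undefined on nonpositive values — any other order
   needs an ad hoc repair. If a plate has no positive value for a probe, a
   configurable epsilon (default 1.0 MFI unit) is used and the wells are
   flagged. The floor is applied to all wells including blanks so the next
   step is defined everywhere.
3. **Housekeeping geometric-mean correction** — each probe value is divided
   by g = √(PPIB·HPRT) of its own well, removing multiplicative cell-number
   effects (viability, seeding, transfection efficiency). The identity
   √(PPIB′·HPRT′) = 1 then holds for every well and is asserted by the test
   suite. Wells with g below 0.25× the plate's siCont median g are flagged
   `low_housekeeping` (a QC annotation separating lethal-like wells; they
   remain in the data).
4. **Control-median normalization and log2** — each signature value is
   divided by the median of the scope's siCont wells for that probe, then
   log2-transformed: x′ = log2(x / median_siCont). The scope is plate
   (default, recommended when the positive control sits on every plate),
   batch, or screen; gene-vs-gene comparisons require screen scope.
   Housekeeping probes are carried through unchanged on the geomean scale.
5. **Control outlier exclusion (iterative Grubbs)** — repeated control wells
   are screened per group: siCont per plate (floor 6), positive control per
   batch (floor 20). The Grubbs test is univariate, so each well is reduced
   to a scalar: the Euclidean distance of its 6-probe signature from the
   group's mean signature. One well at a time, the most extreme scalar is
   tested against the two-sided critical value
   G꜀ = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) Student-t quantile
   with n−2 df (α = 0.05 by default); after each removal the mean and
   distances are recomputed. Removal stops at the group floor; undersized
   groups are skipped with a warning and no removals. Flagged wells stay in
   the dataset marked `outlier`. On per-replicate triplicate data the
   per-plate siCont group is pooled across replicates (15 wells), which is
   the only reading under which the printed floor of 6 is attainable with 5
   control wells per plate; pooling is a switch.
6. **Target signature and scoring** — the target is the per-batch mean
   signature of surviving positive-control wells (screen-wide when scoring
   at screen scope). Every library gene is scored by Euclidean distance
   (rdist-style, √Σ(aⱼ−bⱼ)²) and sample Pearson correlation to its batch's
   target. Both are emitted per replicate and for replicate-averaged data;
   because whether the original analysis averaged signatures before the
   metrics or averaged per-replicate metrics is not determinable, both
   columns are emitted (`*_of_avg` and `*_avg_of_metrics`). The averaged
   signature comes from averaging on the geomean scale before the log2
   transform (the pipeline's replicate-averaging point), not from averaging
   log2 values. Ranks are ascending in distance and descending in
   correlation, ties broken lexicographically by gene symbol; an undefined
   correlation (constant vector) propagates as missing, never as a sentinel,
   and ranks last.

## Synthetic screen model

The simulator exists to give every downstream stage a ground truth. Its
signal model is multiplicative-lognormal above an additive background —
MFI data are positive and right-skewed, and the housekeeping correction
presumes multiplicative cell-number effects:

    E[well, probe j] = v_g · s_plate · s_batch · s_edge(row,col) · 2^(μⱼ + δ_gj)
    MFI = Bⱼ + E·exp(ε),  ε ~ N(0, σ_tech²),  Bⱼ ~ N(bⱼ, (cv·bⱼ)²) clipped at 0

- δ_gj: the true log2 effect of depleting gene g on signature probe j (zero
  for housekeeping probes). Null genes draw δ ~ N(0, 0.15²) i.i.d. per probe;
  planted genes get `planted_scale` × the target effect plus N(0, 0.10²);
  the positive control carries the target effect exactly.
- The default target effect (−2.0, −1.5, −1.2, −0.9, −0.7, −0.4) is
  all-negative, matching the direction of the reference depletion; the exact
  values are arbitrary configuration with enough spread across probes for a
  correlation metric to be meaningful.
- v_g: viability. Controls: siCont 1, positive control 0.6 (intermediate,
  matching its observed growth-inhibitory behaviour), lethal control 0.1;
  siPPIB wells keep v ≈ 1 but multiply the PPIB probe by a knockdown
  fraction 0.1. Library genes scatter mildly (lognormal sd 0.05) except
  `n_lethal` planted lethal genes at v = 0.1.
- Artifacts: per-plate and per-batch lognormal scale factors (sd 0.10 and
  0.15), an optional row/column multiplier map for edge effects, and i.i.d.
  lognormal technical noise σ_tech = 0.10 per well per probe.
- Technical replicates share the gene assignment and plate/batch artifacts
  (replicates were dispensed from one master mix) and redraw well-level
  background and noise.

Baseline expressions μⱼ (≈ 2⁸–2¹⁰ MFI units above a background of 30) and all
noise magnitudes are arbitrary defaults — the real study reports no
quantitative noise levels — chosen once to be realistic for bead-based MFI
data (≈ 10% technical CV) and to reproduce the qualitative control ordering
reported for the real screen: blanks ≈ background, lethal ≈ siPPIB ≪
positive control < siCont in raw PPIB, and replicate PPIB correlations
≈ 0.9. Bead-level sampling (the instrument's per-well median over ≥ 50
beads) is below the pipeline's input granularity and is not simulated.

What the simulator does *not* emulate: transfection-efficiency drift over
time, spatially correlated (smooth gradient) artifacts beyond the multiplier
map, probe cross-hybridization, batch-specific biology (real plates group
functionally related genes, so real batch effects partly reflect biology).
Passing recovery tests therefore demonstrates correctness of the processing
chain under the stated noise model, not performance guarantees on the
deposited data.

## Numerical choices

- Background center: mean (median available); with the mean, blank wells
  average exactly to zero after subtraction — an identity the tests assert.
- Geomean and log2 operate on floored, strictly positive values by
  construction; the stage machine (raw → bgsub → geomean → normalized_log2)
  forbids re-application or reordering of stages.
- Grubbs α = 0.05, two-sided, configurable; the test's decision is verified
  in the suite against an independent p-value-route implementation
  (t = √((n−2)G²/((n−1)²/n − G²)), reject iff 2n·P(T>t) < α).
- Distances/correlations computed in float64; oracle tests pin them to
  direct-formula recomputation at 1e−12.
- Ties in ranks: lexicographic by gene symbol, for full determinism; all
  group iteration orders are sorted, and the same seed reproduces simulated
  datasets byte-for-byte.

## Problem sizes

The test suite and the acceptance script run on the `demo` preset — 10
plates × 3 replicates = 11,520 wells, 3,200 library genes in 2 batches of 5
plates, 20 planted positives and 10 planted lethals — which exercises every
code path (multi-plate, multi-batch, outlier floors active) while keeping a
full run under a few seconds. The `paperlike` preset (45 plates × 3
replicates, 14,400 genes, 8 plates per batch, matching the deposited
screen's ~14,355 depletions to within 0.5%) runs the identical code and is
used for scale checks only.

## Known limitations

- The optional tolerant CSV importer maps common column-name variants; it is
  not a parser for raw Luminex instrument exports and there is no PubChem
  client. The real deposits, once exported to a one-row-per-well CSV, can be
  fed through `read_screen_csv`.
- The deposited screen's printed statistics (probe covariation 0.84 between
  BNIP3 and NDRG1; replicate PPIB correlations 0.901/0.808/0.848) are
  properties of the real data; the QC battery computes exactly those
  statistics, so checking them is one `sigscreen qc` invocation away once
  the data is obtained, but they are not reproducible from simulation.
- Housekeeping-geomean division couples the signature probes through the
  shared housekeeping noise term; the probe-covariation QC therefore reports
  small positive off-diagonals even for truly independent gene effects.
  This is a property of the normalization itself, visible in the simulator
  where ground truth is independent.
- Entrez identifiers are annotations carried verbatim (including the
  rodent-style HPRT identifier present in the screen's metadata); no
  identifier resolution is attempted.
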