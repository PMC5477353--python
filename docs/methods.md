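# Methods

`bxsv` analyzes linked-read sequencing data, in which short reads carry a
droplet barcode (BX tag) identifying the high-molecular-weight (HMW) DNA
molecule they derive from. Each droplet partitions 3–5 molecules of
~50 kb under one barcode, so barcodes are a noisy but powerful proxy for
molecule identity: two distant genomic windows that share many barcodes
are physically joined on HMW molecules. The package turns that signal
into somatic SV evidence, cis/trans phase, haplotype-resolved copy
number, and breakpoint structure, and ships a coordinate-level simulator
that provides ground truth for every stage.

## The phasing model

For an SV `v = (x, y)`:

1. **Window barcodes** `B(x)` — all barcodes with a read mapped inside
   the window `[x − w/2, x + w/2)`, regardless of any junction evidence.
   Default `w` = 100 kb: wide enough to collect most reads of a spanning
   molecule, narrow enough that the two windows of a large SV do not
   overlap.
2. **SV-specific molecules** `S(x, y) = B(x) ∩ B(y)` — valid only when
   the breakpoints are separated by more than ordinary molecules can
   span. The guard is `|y − x| > min_span` with `min_span` = 2× the mean
   molecule length (default 100 kb); interchromosomal pairs always
   qualify. Each surviving shared barcode is read as one
   junction-spanning HMW molecule. `background_rate` quantifies the
   residual barcode-collision floor empirically by intersecting randomly
   sampled distant window pairs and reporting a (1 − α) quantile as the
   significance threshold.
3. **Molecule linking** `C(v_i, v_j) = S_i ∩ S_j` — SVs whose
   junction-spanning molecules coincide lie on one DNA molecule, hence
   in cis. Default `min_shared` = 2 molecules; a single shared molecule
   is logged as weak evidence.
4. **Haplotype assignment** — heterozygous SNVs within the breakpoint
   windows, *phased in the matched normal sample* (tumor phasing is less
   reliable), define which allele sits on haplotype 1/2 per phase block.
   The tumor's per-allele barcode lists route each barcode into supports
   `H1`/`H2`; `R_k = H_k ∩ S` counts SV molecules per haplotype.
   Barcodes appearing in both supports (droplet co-occupancy or a stray
   allele assignment) are excluded as unassignable. The call is
   `hap_k` when `r_k/(r1+r2) ≥ 0.8` with at least 5 assignable
   molecules, `mixed` when the minor haplotype holds ≥ 0.3, else
   `unassigned`. The 0.8/0.3/5 thresholds are package defaults chosen so
   that unanimous, near-unanimous (0.99), and genuinely bimodal
   (0.64/0.36) support patterns classify as hap-call, hap-call, and
   mixed respectively.

The pair verdict cascades: shared molecules ⇒ `cis_molecule`; else two
haplotype calls in the *same* phase block ⇒ `cis_haplotype`/`trans`;
else `unresolved`. Haplotype labels are arbitrary per phase block, so
calls in different blocks are never compared. When one SV's windows fall
in different blocks, support is computed per block and the pair-level
comparison is restricted to a block both SVs share.

Two documented caveats: barcodes and molecules are equated inside
windows (one barcode ≈ one molecule locally; droplet co-occupancy makes
this an upper bound), and S sets are optionally filtered against the
matched normal's S for the same SV (`subtract_normal_s`, default on) to
remove window-level systematic artifacts.

## Somatic filtering

Tumor−normal subtraction requires **both** breakpoints of a tumor call
to lie strictly within `slop` (default 5 kb, half-open) of a normal
call's breakpoints, chromosome pairing order-insensitive. Single-end
matching was rejected because it over-filters translocations sharing one
fragile site. Cross-caller validation greedily matches closest
breakpoint pairs one-to-one under the same slop; class labels are
ignored by default (DEL/DUP naming differs across callers) with a
strict-class flag. Driver annotation intersects ±1 Mb breakpoint windows
with a user-supplied gene BED; copy-ratio segments are labelled
amplification above 1.25 and deletion below 0.95.

## Allele-specific depth and fold estimation

Per phased SNV, the tumor barcode count of the allele on each haplotype
(normal orientation) is a haplotype-resolved copy-number proxy.
`detect_amplified_haplotype` compares in-region vs flank **medians** per
haplotype (robust to per-SNV noise; ratio form cancels uniform coverage
differences), requires a one-sided Mann–Whitney test at α = 0.01 and a
clear separation from the other haplotype, and reports the fold to the
nearest 0.5. Purity correction (invert `pF + (1 − p)`) is available but
off by default: raw counts are the primary observable, and note that the
simulator's `purity` is a *molecule* fraction — with an amplified
haplotype the effective mass purity is lower, so raw folds at purity
p < 1 sit below `pF + (1 − p)` computed from the molecule fraction.

## Breakpoint fine-mapping and junction structure

Same-barcode reads with inter-read gaps ≤ `gap_max` (default 50 kb, the
molecule scale; below it, real per-molecule read gaps are almost never
split, above it distinct same-partition molecules are rarely merged)
form read clusters; clusters with ≥ 2 reads stand as molecules. A
cluster censors both molecule ends by about one read spacing, so the
mean-length estimator adds the measured mean spacing to the mean span.

For fine-mapping, distinct SV-specific barcodes are counted per 1-kb
window across a 500-kb region centred on each called breakpoint. After
3-window median smoothing (absorbs single-window dropouts from the
~1 kb read spacing), the breakpoint is the window boundary with the
sharpest count edge: junction support *terminates abruptly* at the
breakpoint and decays gradually away from it, so a sharp drop is
preferred; when no comparable drop exists the sharpest rise is used
(support on the right of the breakpoint), and profiles whose best edge
is under half the plateau median are flagged unrefined. Inversion
breakpoints whose two junctions both fall inside one window pair can
blur this edge; the bundled scenarios separate them, and molecules can
additionally be split by haplotype call before profiling.

Junction adjacency is voted per molecule: each cluster abutting a
refined breakpoint supports its left side (cluster ends there) or right
side (cluster starts there); opposite sides across a junction mean a
colinear adjacency ('forward': deletion- or duplication-like), same
sides an inverted one ('reverse'). Each side-combination is a candidate
edge — a reciprocal inversion legitimately produces two edges on the
same breakpoint pair — and conflicts for a node are resolved by
majority with ties flagged ambiguous. Orientation comes from cluster
geometry plus clipped-read flags; single-read strand is uninformative at
coordinate level.

Barcode-overlap matrices count shared barcodes between 10-kb bins
(optionally Jaccard-normalized); off-diagonal structure beyond the
molecule length marks non-reference adjacency. Plot color thresholds are
display-only quantiles.

## The simulator

Coordinate-level by design: no nucleotide sequence is generated, because
every downstream operation consumes mapped positions, barcodes, and
per-allele barcode lists. Sequence realism (errors, GC bias, FFPE
artifacts, indels) is out of scope.

* **Scaffold** — heterozygous SNVs from a homogeneous Poisson process
  (default 1/kb, the human heterozygosity scale), alleles assigned to
  haplotypes uniformly, phase-block boundaries from a chromosome-wide
  Poisson process with configurable mean (1.4 Mb for the germline
  profile, matching large linked-read phase blocks).
* **Derived haplotypes** — ordered lists of oriented reference segments
  with optional tandem-repeated sub-lists (`RearrangementSpec`) compile
  to a total, invertible piecewise coordinate map; true junction
  breakpoints, classes, and derived-coordinate positions are extracted
  automatically from segment adjacencies.
* **Droplets** — each partition holds Uniform{3,4,5} molecules under one
  barcode; barcodes are never reused across partitions (the ~10⁶
  partition regime). Molecule lengths follow a truncated exponential on
  [1 kb, 500 kb] whose scale is solved so the truncated mean equals the
  requested mean (51 kb germline, 45 kb tumor). A lognormal alternative
  is available. Each molecule is tumor-derived with probability
  `purity` (default 0.4), and lands on a haplotype in proportion to that
  haplotype's genome length, so amplified haplotypes contribute
  proportionally more molecules.
* **Reads** — one ~150 bp read per ~1 kb of molecule (jittered ±25%),
  reproducing realistic per-molecule read counts (~50 reads / 50 kb);
  paired ends are collapsed to single segments. Reads crossing a
  junction are emitted as split, soft-clipped segments with < 20 bp
  pieces suppressed. SNV allele barcode sets are populated from the
  molecules overlapping each SNV, honoring molecule haplotype, with a
  0.5% per-molecule misassignment rate that plants the occasional stray
  molecule on the wrong allele.
* **Desk scaling** — molecules occupy a chromosome-scale
  `genome_extent`, but reads are emitted only for molecules touching the
  configured `active_regions` (±1 Mb around true breakpoints in the
  presets). This keeps droplet co-occupancy — hence the
  barcode-collision background that the whole method must beat — at
  whole-genome-library levels while simulating only the informative
  neighborhoods. Every stochastic draw flows through one seeded
  generator: identical seeds give byte-identical outputs.

What the simulator does **not** model, and what passing tests therefore
do not establish about real data: alignment and mapping artifacts
(repeats, multi-mapping), coverage waves, chimeric droplet artifacts,
real phase-block switch errors, and sequencing error in barcode reading.
The collision background is real but idealized (purely co-occupancy
driven).

### Bundled scenarios

* `normal` — 5-Mb germline slice, ~51 kb molecules, 1.4-Mb phase
  blocks.
* `right_met` — a derived haplotype 1 on chr10 carrying a motif of a
  30-Mb deletion, an inversion with deletions at both boundaries, and a
  9-fold head-to-tail tandem duplication of the whole motif; purity
  0.4, 45 kb molecules. One phase block spans the locus (the analysis
  requires comparable haplotype labels across the region; bridging
  separate blocks via allele counts is demonstrated by the depth
  module instead).
* `left_met` — five haplotype-1 events (two duplications, two
  deletions, an inversion) with a duplication and deletion close enough
  in derived coordinates to share molecules, plus a *distinct*
  haplotype-2 inversion at nearly the same locus so the haplotype-1
  inversion's windows collect molecules from both haplotypes (a mixed
  call); one duplication is tagged as visible only to an orthogonal
  caller.

`random_scenario` draws 2–4 well-separated events with random
haplotypes and purity ∈ [0.3, 0.5] for parameter-recovery sweeps.

## Problem sizes and numerical choices

The bundled scenarios are sized for a single CPU: the germline profile
uses 65,000 partitions over a 250-Mb extent (~5,000 molecules with reads
in the 5-Mb window, ~270k reads); the rearrangement scenarios use
8,000–150,000 partitions tuned to give ~20–50 junction-spanning
molecules per SV — the regime where the published per-SV molecule counts
live. Windows and regions use half-open integer intervals throughout;
internal coordinates are 0-based half-open with conversion only at file
boundaries (VCF 1-based; BEDPE as-is). Barcode identity is the full tag
string including library suffix. Ties in greedy SV matching break
lexically on SV id; degenerate inputs (empty call sets, empty regions,
windows past contig bounds) return empty results or explicit errors as
documented per function.

## Known limitations

* The `S`-set precondition bounds breakpoint *separation*, but windows
  reduce the effective gap by `w`; events whose separation is within
  ~one molecule length of `min_span + w` accumulate long ordinary
  molecules in `S`. These dilute, never flip, haplotype calls (they are
  haplotype-balanced), and the assignable-fraction thresholds absorb
  them.
* Overlapping breakpoint windows of distinct nearby SVs share molecule
  evidence; `cis_molecule` verdicts between such pairs can reflect
  window overlap rather than molecules containing both junctions — the
  same ambiguity the window construction has on real data.
* Phase blocks are taken as given; switch errors inside a block would
  corrupt haplotype routing undetected.
* Fine-mapping resolution is one window (1 kb) and degrades for
  inversion junction pairs closer than the molecule length.
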