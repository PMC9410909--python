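# Methods

This note documents the models and procedures `chromswitch` implements,
the parameters that matter, what the synthetic data emulate, and the
design choices made where a convention had to be fixed.

## Coordinate and format conventions

All coordinates are 0-based half-open (BED convention). Overlap always
means at least one shared base, so book-ended intervals do not overlap
and are not merged. Peaks are narrowPeak (summit = start + column-10
offset; midpoint when the offset is −1) or plain BED (summit =
midpoint). Peak significance filtering uses narrowPeak column 8
(−log10 p): with the default p-threshold of 1e-5, peaks at or above 5
are kept. Signal is interchange as bedGraph; a `SignalTrack` is a
per-chromosome set of sorted, disjoint, nonnegative runs, and interval
means are length-weighted with uncovered bases counted as zero —
identical semantics to averaging a coverage track. Binary formats
(BAM/bigwig) are out of scope.

## Chromatin states

Each retained histone-mark peak contributes a 1-kb window centered on
its summit (clipped at the chromosome start). Windows from **all three
marks and both conditions** are merged into one universe, so both
conditions are classified over identical regions and transitions are
well defined; merged regions longer than 1 kb are kept as merged rather
than re-split (the simplest reproducible convention — output records
region lengths for audit). States follow mark co-occurrence with the
precedence active → primed → repressed → quiescent; H3K27me3 co-occurring
with an active or primed call raises a `multi_match` flag (bivalent-like
regions) rather than changing the call. H3K27ac without H3K4me1 is not
an enumerated combination; it is labelled OTHER by default, with a
switch to fold it into ACTIVE.

Promoters are strand-aware windows from 5,000 bp upstream to 500 bp
downstream of the TSS (+ strand: `[TSS−5000, TSS+500)`; − strand
mirrored as `[TSS−499, TSS+5001)`; endpoint handling at single-base
resolution is a convention choice with no practical effect at these
window sizes). A region is *promoter* if it overlaps any promoter
window, else *gene body* if it overlaps a gene interval, else *distal*;
promoter takes precedence.

## Differential accessibility

Bins tile each chromosome from coordinate 0 on a fixed 1-kb grid (no
sliding windows — reproducibility over sensitivity). The statistic is
`log2((mean_B + c) / (mean_A + c))` with pseudocount c (default 1.0;
common coverage-comparison practice, avoids infinities; with c = 0 the
ratio is ±∞ for one-sided coverage and 0-with-flag when both means are
0). Calls use a fold threshold (default 2) plus the peak-absence rule:
increased bins must not overlap any condition-A ATAC peak, decreased
bins must not overlap any condition-B peak. Adjacent qualifying bins of
the same direction merge book-ended on the grid. Swapping conditions
maps increased ↔ decreased exactly.

For a truly unchanged bin whose two condition means carry independent
multiplicative noise `exp(N(0, σ²))`, the log-ratio is `N(0, 2σ²)` and
the false-call probability at fold f is `2·Φ(−ln f / (√2·σ))`; the test
suite and acceptance script check the empirical rate against this
closed form (at pseudocount 0, where the closed form is exact).

## Binding modes

The signal matrix holds, per TF peak, the binned mean of each track
over the summit ± 2 kb window; the default 40 bins of 100 bp match
heatmap-style summaries (the exact bin width is a free choice; 100 bp
resolves nucleosome-scale structure). Windows clipped at a chromosome
edge are zero-padded and flagged. Columns are z-scored across regions —
this removes per-track scale and offset, so adding a constant to one
track never changes assignments — and rows are clustered with Euclidean
k-means, best of 10 restarts, deterministic under a fixed seed. Cluster
indices are renumbered by descending size so replicate runs agree.

Semantic labels come from centroid whole-window means relative to the
across-cluster median per track, with a 1.5× margin: high ATAC in both
conditions → C1; not high in A but high in B → C2; else high H3K27me3 →
C3; else not high on all three informative tracks → C4; anything else
is left unlabeled. k = 4 is the default but configurable; sensitivity
to k is the user's concern.

## Motif model

A PWM column built from an IUPAC consensus gives the allowed bases
`match_prob` (default 0.997) shared equally and the disallowed bases the
remainder; N columns are uniform. Scores are log2(p/0.25) summed over
the window (uniform background fixed), scanned on both strands with −
strand hits reported on the forward axis; N bases in the query score 0.
The hit threshold defaults to 6 on this log2 scale. Shipped consensi:
monomer `ACAAWG`, defined dimer `ACAAWGNNNNCWTTGT` (palindromic, so
every + hit has a − hit of equal score at the same locus), degenerate
dimer `NCAAWGNNNNNWTTGN` (outer bases and the second half-site's C
relaxed). External matrices load from a simple text PWM format
(`>name threshold` then L rows of 4 probabilities).

Region classification is by precedence: any defined-dimer hit → defined
dimer; else any degenerate-dimer hit not overlapping a defined-dimer
hit → degenerate dimer; else any monomer hit not overlapping either
dimer's hits → monomer only; else none. Overlap is ≥ 1 shared base on
either strand. Regions are scanned over summit ± 150 bp (a 300-bp
motif-finding window).

Region–gene association is deliberately simple: each region maps to the
gene with the nearest TSS (from the region midpoint) within 100 kb,
ties map to all tied genes with a flag. Direct targets are mapped genes
with |log2 expression ratio| strictly above 0.5, split by sign.

## Fragment foci

Per peak, the per-base count of overlapping fragments is computed; foci
are strict local maxima of this profile, with a maximal plateau
yielding one focus at its midpoint (the left of the two central bases
when the plateau length is even) and boundary plateaus counting as
maxima when their interior neighbour is lower. `min_support` (default
1) drops weak maxima. Each focus's statistic is the unweighted mean
length of the fragments covering the focus base (fragments are not
weighted by overlap extent). Modes: direct < 100 bp, nucleosomal
> 120 bp, the 100–120 bp gap kept explicit as *intermediate*.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not sequencing itself: no read-level errors, no replicate variance, no
realistic genome composition (background sequence is uniform ACGT), no
mappability or blacklist structure. Passing recovery tests therefore
demonstrates correctness of the analysis logic under the stated noise
model, not robustness to every artefact of real libraries.

Conditions planted by default: 200 state regions with uniformly random
state pairs; 10,000 accessibility bins with 100 increased, 100
decreased and 100 confounded bins at fold 4 over a baseline mean of 10
(confounded bins carry a condition-A peak so the exclusion filter is
exercised); 400 TF-bound regions, 100 per cluster, with low/high signal
levels 1 and 8 (ln 8 ≈ 2.08, so the default separation is ≥ 5 noise
s.d. whenever the log-normal noise s.d. is ≤ 0.416); dimer motifs in
C1/C2 and monomers in half of C3/C4; 20 fragment foci (10 direct at
μ = 80 bp, 10 nucleosomal at μ = 150 bp, σ = 10, 1,000 fragments each,
lengths truncated at 20 bp). Regions are spaced 10 kb apart so windows
never overlap.

Noise is multiplicative log-normal on signal means — coverage stays
strictly positive and the relative error is directly controlled by the
log-scale s.d. Each output file draws from its own RNG stream derived
from (seed, file tag), so adding an output never perturbs the others,
and identical configs are byte-identical across runs.

Motif planting uses rejection sampling: a region's scan window is
regenerated until its scanner-derived class equals the planted class,
so chance background occurrences of another class cannot corrupt the
truth table. The scanner used for this check is itself validated
against an independent brute-force enumeration of all windows and
strands, keeping the check non-circular.

## Pipeline & reproducibility

`run_pipeline` executes stages in dependency order from one validated
config; any missing input aborts naming the stage and key. The manifest
records the package version, a hash of the pre-run config and a sha256
per output file — and nothing time-dependent — so determinism is
testable as byte-identity of manifests. Problem sizes in the shipped
examples and the acceptance script are the default study conditions
above; they run end to end in tens of seconds on one CPU.

## Known limitations

- The state scheme is rule-based co-occurrence, not an HMM segmentation;
  only two conditions are supported.
- Accessibility calling is the fold/peak rule, not a count-based test;
  it inherits whatever normalization the supplied tracks carry (raw or
  fold-enrichment), which the caller should record.
- The k-means labeling rule assumes the four planted signatures exist in
  the data; with other structures clusters may legitimately come out
  unlabeled.
- The log2/uniform-background PWM scale is one fixed convention for the
  "threshold 6" operating point; other tools use subtly different
  log-odds scalings.
- Gene association is nearest-TSS-within-100-kb, a deliberate
  simplification of regulatory-domain methods.
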