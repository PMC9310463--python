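# Methods

This note documents the models, parameter choices and numerical conventions
implemented in `zetascreen`, and what the synthetic study conditions do and
do not establish about real data.

## Preprocessing

Rows, then columns, are removed when their count of missing values exceeds
the fence Q3 + 3·(Q3 − Q1) computed over the per-row (per-column) missing
counts. Quartiles use linear interpolation (the default of mainstream numeric
stacks); the row-then-column order is a single pass, not iterated to a fixed
point. Remaining gaps are imputed with the column mean over the k = 10
nearest rows, where distance is Euclidean over mutually observed columns
normalised by the number of shared columns; neighbour ties break by row
order, and k is reduced with a warning when fewer candidates carry the target
column. Screen quality is summarised per readout by the strictly standardized
mean difference SSMD = (μ₊ − μ₋)/√(s₊² + s₋²) with sample (n−1) SDs
throughout; a screen is workable when more than 5% of readouts exceed
SSMD = 2. A 2-D PCA embedding of the control rows is emitted as advisory
output only — pass/fail is decided by SSMD alone.

## Zeta scores

Z-scoring uses negative-control moments per column; columns whose controls
are constant are dropped with a warning. The cutoff range starts at |Z| = 2
(two-sided standard-normal tail ≈ 0.046, i.e. p < 0.05) and ends at the
99.9th-percentile |Z|, taken as the value at rank ⌊N·M·0.999⌋ of the
ascending |Z| with ties in stable order. The range is divided into 100 equal
bins and the survival fraction P is evaluated at all 101 bin edges, the edge
nearer zero first — so the first point counts everything beyond |Z| = 2.

The control-separating boundary is a radial-kernel SVM (cost 1, kernel width
from the median pairwise-distance heuristic, cutoff axis standardized)
trained on (cutoff, P) points of the control curves. The boundary value per
bin edge is the P at which the decision function crosses zero, found by
bisection to 1e-6; columns entirely on one side get 0 or 1 by decision-
function sign. Training accuracy below 0.6 triggers a non-separability
warning — bins beyond the signal range hold both classes at P ≈ 0, so
moderate accuracy is expected even for good boundaries and only near-chance
accuracy indicates genuine overlap.

Areas are trapezoids per bin, clipped at zero against the boundary; the
weighted score multiplies each bin's area by the absolute Z at the bin
midpoint, so both directions yield non-negative weighted scores and hits
surviving stringent cutoffs are up-weighted. The two directional scores are
summed by default; both can be reported separately. Without positive
controls the boundary is omitted and the area is taken from the x-axis,
which upper-bounds the SVM-subtracted score.

## Screen Strength and balance points

SS = 1 − aFDR/bFDR over 100 even zeta cutoffs from the minimum to the
maximum score; controls are excluded from the counts, zero-hit cutoffs are
trimmed from the tail, and cutoffs with fewer than 5 hits are ignored during
balance-point detection because their aFDR denominator is unstable.

"Balance point" is a qualitative notion; the operational definition here is
fully specified so results are reproducible. The SS values are smoothed with
a centered moving average (window 5) and a balance point is the first cutoff
of each maximal run in which the forward slope stays below
0.05 · (SS range)/(cutoff range) for at least 5 consecutive steps, subject
to: the curve rises into the run; each balance point improves on the
previous one; the plateau sits at the running maximum of the smoothed curve;
and the SS there exceeds twice its own null sampling SD,
√((1 − bFDR)/(n·bFDR)) at n hits — under random drawing aFDR is binomial
with mean bFDR, so SS fluctuates around zero with exactly that scale. The
last two conditions are what make signal-free curves (permuted ranks, zero
effect sizes) yield no balance point while plateaus of genuine screens
survive; they matter most at stringent cutoffs, where few hits make SS noisy.

Empirical false-positive levels are defined on non-expressors: the cutoff at
level α is the smallest observed score with at most a fraction α of
non-expressors at or above it (level 1 therefore returns the minimum score).
Fewer than 20 non-expressors triggers a coarseness warning.

## Off-target flagging

A hit pool is flagged when (i) one of its guides shows ≥ 11 nt of contiguous
Watson–Crick complementarity (U ≡ T, no wobble pairs) to another hit gene's
transcript and (ii) the response criterion holds at Pearson r ≥ 0.6 — tested
on that same single siRNA's secondary-screen row when one exists, otherwise
on the pool row with a lower-confidence tag. The complementarity scanner
reports all maximal runs with 1-based inclusive transcript coordinates; the
match may fall anywhere on the guide (no seed-region requirement). Scans are
restricted to correlated pairs since correlation is cheap and both criteria
must hold. Flagging is directional: evidence against pool A never alters the
score of the gene it off-targets.

## Hit networks

Two distances D = 1 − |r| (Pearson and Spearman over Z profiles) are each
embedded by classical MDS (top ≤ 10 positive-eigenvalue components) and
partitioned by k-means across k = 2..min(8, n/2) with 50 seeded restarts per
(distance, k). The consensus of a pair is the fraction of runs co-clustered;
final labels come from average-linkage hierarchical clustering of
1 − consensus cut at the elbow k (maximum second difference of the mean
within-cluster sum of squares). Edges are kept at consensus ≥ 0.5, signed by
the Pearson correlation; disconnected nodes are trimmed at export.

## Droplet QC

Cell zeta is the trapezoid area under the curve (t_b, #genes ≥ t_b) over 10
dataset-global expression thresholds, log-spaced from 1 to the 99.9th
percentile of pooled nonzero counts — log spacing reflects the skew of count
data; the thresholds being global makes zeta comparable across cells. No
boundary subtraction or weighting is applied: only the ranking and the
density cutoff are used. The cutoff is placed on the kernel density of
log1p(zeta) (Gaussian KDE, Silverman bandwidth, 512-point grid): the two
tallest modes are located and the cutoff is the first convex-to-concave
inflection between the inter-mode minimum and the higher mode — the low-side
reflection point of the second (intact-cell) population; damaged-cell mass on
that flank pulls the inflection down, which is desirable since those cells
are the ambiguous ones. Fallbacks: the inter-mode minimum when no inflection
exists, and a lower-fence (Q1 − 1.5·IQR) value with a "no bimodality" warning
for unimodal densities. Metric comparisons report ROC AUC with the
orientation made explicit (%mt scores "low = good").

## Synthetic study conditions

The screen generator draws every row as readout-baseline + N(0, noise_sd)
noise; regulators add ±effect_size to a fixed fraction of readouts (signs
split by direction_bias), so the Z of a perturbed readout is ≈
effect_size/noise_sd. Defaults describe a well-powered genome-scale screen:
300 readouts; 200 regulators at effect 6 over 30% of readouts; 1,580 inert
genes; 200 non-expressors; 10 controls per class, positive controls
replicating the strongest regulator's profile. Off-target plants give one
"single siRNA" of a non-expressor pool a diluted (0.8×) copy of a
regulator's response at pool level, a full copy in the secondary screen, and
a 15-nt complementary island against the regulator's transcript embedded in
an otherwise random 21-nt guide.

The droplet generator produces 10,000 droplets by default: 4,000 intact
cells drawn from a 4-type mixture (shares 0.30/0.25/0.20/0.25, depth factors
1.0/1.4/0.6/1.0, profile log-normal sigmas 2/2/2/3 — the last type is a
low-complexity, high-count program such as an erythroid or plasma cell;
without such heterogeneity a single metric like nFeature would separate
damaged cells unrealistically well, which is precisely the failure mode
integrated QC addresses); 4,000 empty droplets sampling the pooled ambient
profile at depth ≈ 80; 1,000 broken cells built mechanistically by binomial
thinning of an intact cell's non-mitochondrial counts (retention U(0.1, 0.5))
so selective cytoplasmic leakage is the literal generative process; and
1,000 stripped nuclei (0.3× depth, mitochondrial retention 0.05, ribosomal
0.15). Counts are gamma-Poisson with overdispersion 0.5; mitochondrial and
ribosomal blocks carry 8% and 20% of expression in intact cells.

What the generators do *not* emulate: plate/edge effects and batch structure,
realistic splicing biology or transcript architecture, seed-sequence
composition biases of real siRNA libraries, doublets, and ambient-profile
biases beyond simple pooling. Passing tests therefore establish internal
correctness and behaviour under the stated generative assumptions, not
performance on any particular real screen.

## Numerical conventions and limitations

All randomness flows through `numpy.random.default_rng` seeds; identical
seeds give byte-identical score tables (matrices are written at %.17g and
parsed with round-trip precision). Ties in KNN neighbours and hit sorting
break by stable order. Problem sizes in the test-suite and the acceptance
script match the default study conditions above (2,000 × 300 screens, 10,000
droplets); the oracle-equivalence checks run 100 random curves and 1,000
random guide/transcript pairs. Known limitations: the balance-point detector
is one reasonable operationalisation among several and its indices on real
data depend on the smoothing parameters; the Gumbel baseline fits row maxima
that are not exactly Gumbel at finite M; and the density cutoff assumes the
intact-cell population is the highest-zeta mode.
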