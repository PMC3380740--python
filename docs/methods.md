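# Methods

This note documents the statistical model behind hotspot-transreg, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## Regions and matched controls

Intervals are 0-based half-open throughout; BED input is taken as-is, and
any 1-based source must be converted at the reader boundary. "Matched"
coldspots satisfy three constraints: per-hotspot length matching on the same
chromosome (which preserves both the length distribution and the
per-chromosome count distribution of the hotspot set), an end-to-end gap of
at least `min_distance` (default 50 kb) from every hotspot, and pairwise
non-overlap among coldspots. We deliberately measure the 50 kb exclusion
end-to-end rather than midpoint-to-midpoint: it is the conservative reading
that guarantees no control base lies within 50 kb of hotspot sequence.
Coldspots are not required to keep any distance from each other beyond
non-overlap.

Sampling is uniform rejection sampling of start positions, processing
hotspots in descending length order (long intervals are hardest to place),
with a 10,000-attempt budget per interval before a placement error naming
the chromosome. An optional filter rejects candidates whose N fraction
exceeds 0.5 (default), since scan hit counts inside assembly gaps are
meaningless; the filter is off unless chromosome sequences are supplied.

## PWM scanning and exact p-values

A position frequency matrix row (counts or probabilities) is smoothed as
p̂ᵢᵦ = (cᵢᵦ + κ·bᵦ) / (Σᵦcᵢᵦ + κ) with pseudocount κ (default 0.1, a common
scanner default) against background b (uniform by default; a 0-order fit to
the scanned sequences is available — published hit counts depend on the
original tool's smoothing and background and are not reproducible from the
tables anyway, so the reproducible default wins). Scores are
log2(p̂ᵢᵦ / bᵦ) in bits; probabilities are floored at 10⁻⁶ so all scores are
finite even at κ = 0.

P-values use the classic lattice dynamic program: per-column scores are
shifted non-negative and rounded to an integer grid with 1000 bins spanning
the total score range (configurable; minimum 100), and the distribution of
the integer total under the background is built by column-wise convolution.
Scanning computes the same integer window scores, so a window's p-value is
exactly the lattice tail probability of its own discretized score; the
discretization error against real-valued enumeration is bounded by half a
bin per column. Both strands are scanned — the reverse strand scores the
reverse-complement of each window — and hit offsets are forward-strand
window starts on both strands. With equal granularity the reverse-complement
matrix lands on the same integer grid (column spans and minima are
permutation-invariant), so one survival function serves both strands under a
strand-symmetric background; an asymmetric background gets its own reverse
table. Windows containing N never match. Benjamini–Hochberg q-values are
computed over n = 2·Σ(Lᵣ − w + 1) scanned positions.

## Enrichment

O_hc = (HM/HN)/(CM/CN). CM is the arithmetic mean over replicate coldspot
draws and may be fractional; the Yates chi-square

χ² = N·(max(|HM·CN − HN·CM| − N/2, 0))² / (N_H·N_C·(HM+CM)·(HN+CN))

is evaluated on the fractional cells as-is — fidelity to how the published
tables were computed is preferred over statistical purism here; a
per-replicate exact test is out of scope. The p-value is the upper tail of
χ²(1 df) (the conventional two-sided reading). Degenerate tables are
flagged rather than silently numeric: HM = 0 → odds 0 with a zero-numerator
flag; HN = 0 or CM = 0 → an infinite-odds flag; HN = CN = 0 (every region
hit, e.g. a p-threshold of 1) → odds exactly 1 with a "saturated" flag; a
zero marginal → a degenerate chi-square flag. Candidate selection keeps
O_hc > 1.20 and p < 0.05, ranked by ascending p then descending odds ratio.
Reported ratios are rounded to 3 decimals at reporting time only.

## GO semantic similarity and the gap statistic

Term similarity is the Wang graph-based measure: within the ancestor closure
of t, S_t(t) = 1 and S_t(a) = max over children c of a on paths to t of
w_edge·S_t(c), with w = 0.8 for is_a and 0.6 for part_of (configurable);
sim(t₁, t₂) sums S-values of common ancestors and normalizes by the two
total S-masses. Cross-namespace similarity is defined as 0 and the ranking
is restricted to one namespace (default biological_process). S(t, g)
averages sim over T(g); genes without annotations are excluded from
averages rather than scored 0, because S(t, g) divides by |T(g)|.
gap(t) = (S(t,HG) − S(t,G))/S(t,G), with gap defined as 0 (plus a warning)
when S(t,G) = 0 rather than ±∞. The candidate-term universe is every term
annotating at least one background gene plus all ancestors, so regulatory
parents can rank. Ties are broken by term id for determinism. A per-gene
relevance score against reference terms (defaults GO:0006310 DNA
recombination, GO:0007127 meiosis I — term ids taken as authoritative over
labels) is the mean of S(t, g) over the reference list.

## Coverage graph

HS(g) is the set of hotspots with at least one hit of gene g's motif; edge
weights are meet/min coefficients. Threshold clustering keeps edges with
w ≥ w_t (inclusive, default 0.16) and reports connected components in
descending size then lexicographic order. Hierarchical clustering runs
average linkage (configurable: single/complete/average) on distance 1 − w,
cut at k clusters; linkage follows the SciPy implementation, which is
deterministic for a fixed input order, and on well-separated graphs
reproduces the threshold partition. The coverage summary emits per-cluster
hotspot unions, pairwise intersections and all Venn regions; the Venn
regions partition the overall union, and union + uncovered equals the
hotspot count by construction.

## Synthetic data and what the tests show

Chromosomes are i.i.d. uniform ACGT. Hotspots occupy equal slots, one per
slot at a uniform feasible position, guaranteeing pairwise gaps of at least
2·min_distance so valid coldspots always exist. Planted motifs are exact
consensus copies (no degeneracy) so scan sensitivity is decoupled from
enrichment recovery; each hotspot receives a copy with probability p_hot,
and the background — everything a coldspot can touch — is tiled into
hotspot-length windows each receiving a copy with probability p_cold.
Planted copies may in principle overwrite one another when several motifs
are planted densely; rates in the shipped configurations make this rare and
it only attenuates, never inflates, enrichment.

Study configurations:

* **paper_like_config** — 400 hotspots of 1 kb on 4×4 Mb chromosomes,
  5 kb exclusion, three enriched motifs (per-region rates 0.60/0.20,
  0.50/0.25, 0.40/0.10) spanning odds ratios ≈ 2–7, plus an unenriched
  control at 0.20/0.20. The exclusion distance is scaled from the 50 kb
  default in proportion to region size so a full 20-replicate run takes
  seconds.
* **recovery_config** — 5000 hotspots of 500 bp, 1 kb exclusion, 10 kb
  slots, one motif at 0.25/0.20 (planting odds 4/3, the weak-enrichment
  regime). Hotspots are deliberately sparse: background segments are then
  long relative to the region length, so the geometry a coldspot samples is
  well approximated by an unbroken window tiling — the model used by the
  independent Monte-Carlo oracle below.

The oracle (`planting_odds_interval`) simulates the generative description
directly, never touching the scanner or sampler: per-region hit
probabilities combine the planting rate, the geometric probability that a
random region fully contains a tiled background copy (simulated), and the
chance false-hit rate 1 − (1 − p_thr)^(2(L−w+1)); binomial draws of
(HM, CM) then give a 95% interval for the estimated odds ratio. Note the
interval is centred near 1.41, not the naive 4/3: containment losses and
chance hits shift the estimand, and the oracle models both.

The toy GO world is a balanced is_a tree (default depth 3, branching 3,
40 background genes, 3 annotations per gene). Candidate genes are annotated
round-robin to leaves of one marked depth-1 subtree; background genes
round-robin over all leaves. The construction is deterministic, so marked
terms outrank unmarked terms exactly, not just in expectation.

Passing these tests shows the statistics are computed correctly under the
planting model. It does not show robustness to GC heterogeneity, repeats,
assembly gaps, motif degeneracy or correlated hotspot placement — none of
which the generator emulates.

## Reproducibility and problem sizes

Every generator and the pipeline are pure functions of (config, seed);
replicate coldspot seeds are derived as (seed·1000003 + 97r + 1) mod 2³¹−1.
Pipeline outputs carry a SHA-1 hash of the analysis configuration (output
directory excluded) and reruns are byte-identical. Default verification
sizes — 50 random matrices for the p-value DP, 100 sampler seeds on a 10 Mb
genome, 10 recovery seeds at N = 5000 with 2 coldspot replicates, 200 random
graphs for the clustering oracle, one 400-hotspot end-to-end run with 20
replicates — were chosen to exercise each statistic at a scale where its
sampling error is far smaller than the effects being checked, while a full
verification pass stays around a minute.

## Known limitations

* No indel-tolerant or dinucleotide-dependency motif models; matches are
  gapless PWM windows.
* The chi-square on fractional replicate-averaged cells slightly overstates
  the effective coldspot sample size; flagged above as a fidelity choice.
* Hierarchical clustering ties follow SciPy's internal (deterministic)
  ordering rather than an explicit lexicographic merge rule.
* meet/min weights are undefined for genes covering no hotspot; such genes
  are dropped from the coverage graph before clustering.
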