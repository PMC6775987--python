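# Methods

## The RTF framework

For a community *C* with members *i = 1..N_C*, the relative total function is
`RTF_C = Σ_i F_C,i / F_i`, with `F_i` the taxon's monoculture function and
`F_C,i` its in-community function. Functions must be summable across taxa; the
package uses maximum cell density within 110 h, maximum total protein within
110 h, and blank-corrected total CO₂ (the 0–40 h window for RTF, because
community composition is measured at early stationary phase, which the
sampling schedule places near 40 h). Per-taxon functions are attributed by
relative read abundance, `F_C,i = F_C · R_C,i`. This attribution is exact for
cell counts and is exact for other functions only when per-cell function
ratios are equal across taxa; `rtf.adjustment_factors` quantifies the
deviation (the per-taxon per-cell ratio over the community mean), with the
working assumption that factors within [0.5, 2] are tolerable.

Operational definitions follow the field protocol: a dilution-to-extinction
sample counts as a monoculture when its top ASV holds **at least 90 %** of
reads (boundary inclusive); a community is *constitutable* when cataloged taxa
cover **at least 85 %** of its reads, after which abundances are renormalized
over the cataloged taxa; samples under 2000 reads are dropped (strict `<`);
ASVs above 2 % in more than 20 % of blank wells are contaminants (both strict
`>`). A sample that qualifies for the monoculture catalog is excluded from the
community side to avoid self-comparison. Communities below the coverage
threshold are reported with missing RTF, never imputed. Multiple qualifying
monocultures per taxon are aggregated by arithmetic mean (median available).
`N_C` for RMF is the number of cataloged taxa entering the renormalized sum,
consistent with the renormalized abundances; the full observed richness is
reported alongside.

Decomposition: `RTF_C = Σ (a_C,i/a_i)(S_C,i/S_i)`. Because a community has one
total uptake while its CO₂ and biomass conversion efficiencies must move in
opposite directions, `Σ S_C,i/S_i` lies between `RTF_CO₂` and `RTF_biomass`;
dividing by `N_C` bounds the mean per-taxon uptake. Relative CUE is
`rCUE = 1/(Ratio·(1−CUE)+CUE)` with `Ratio = RTF_CO₂/RTF_protein`, evaluated
on the inclusive grid CUE ∈ {0, 0.01, …, 0.6} (thermodynamic bounds) and
summarized by the grid mean.

## Measurement conversions

Cell density = gated FACS events / bead events × 990 000 beads mL⁻¹; protein
per cell = sample fluorescence / fixed-standard fluorescence. The CO₂
indicator calibration is `%CO₂ = 0.1648/(Δ₅₇₂ − 0.2457) − 0.2301`, valid on
the branch Δ₅₇₂ > 0.2457 and clamped below at 0 (the formula's negative range
near the blank is physically meaningless); its algebraic inverse serves the
simulator, and the pair is an exact identity on 0.025–5 % (v/v). Total CO₂
sums rate × interval duration × culture volume (0.58 mL, from 580 µL wells)
over intervals whose midpoint falls in the window; "average time" is read as
the interval duration. Blank correction subtracts the mean blank %CO₂ **per
interval** before summation (the alternative — correcting totals — is
algebraically equal for full windows but not for sub-windows). Maximum
protein per cell is the ratio of maxima, not the maximum of ratios, because
cell clumping corrupts late pointwise ratios. The 160 h time point is
excluded by default (late cultures change physical properties). Stationary
phase is the first < 20 % between-point increase following a > 20 % increase.

## The synthetic community generator

The generator emulates the two-stage design so every analysis step can be
validated against exact ground truth.

**Regional pool.** `n_taxa` (default 60) taxa over `n_substrates` (default
20) substrates of equal carbon content (total 1 carbon unit). Regional
abundances are log-normal (σ = 1.5), matching skewed marine rank-abundance
curves. Each taxon uses `max(1, round(niche_breadth · n_substrates))`
substrates with uniform(0.5, 1.5) weights; the first substrate is assigned
round-robin so every substrate has a consumer whenever `n_taxa ≥
n_substrates`, and a one-substrate breadth yields fully disjoint
(complementary) niches.

**Assembly.** The serial-dilution design enumerates 15 replicates at the
undiluted level and at each 4-fold level 4²–4¹¹, plus 5 and 15 extra vessels
at the two deepest levels — 185 vessels. (The protocol's prose mentions "12
steps" of dilution while its enumeration lists levels 4²–4¹¹; the enumeration
is what reproduces 185 and is what the generator follows.) Founders are drawn
multinomially: `round(10⁶ / dilution_factor)` cells from the regional
abundances (10⁶ from ~3×10⁵ cells mL⁻¹ × 30 mL, rounded as stated in the
protocol; the small discrepancy in that product is noted, not resolved).
Controlled-richness studies bypass the design via `sample_community`.

**Growth.** Each substrate's carbon is split among capable members
proportionally to use-profile weights (equal weights → equal split — the
simplest rule consistent with the equal-split picture of the two-taxon
examples), giving `S_C,i`; alone, a taxon takes its whole fundamental niche
(`S_i`). Interference multiplies conversion efficiency by
`1 − γ · ō_C`, where `ō_C` is the community-mean carbon-weighted niche
overlap and γ the interference strength. The penalty acts on efficiency only,
never uptake, keeping the two decomposition channels independently tunable;
it is applied uniformly across members (rather than per-taxon) so that
abundance-based attribution stays exact and adjustment factors are identically
1 — per-taxon penalties would make the CO₂ attribution approximate even in
the noiseless homogeneous regime. Outputs: cells = cue·S·cells_per_carbon,
protein = cells·protein_per_cell, CO₂ = (1−cue)·S. Default taxa share
cue = 0.3, cells_per_carbon = 10⁶, protein_per_cell = 1 (heterogeneity
spreads default to 0; turning them on is how adjustment-factor robustness is
probed).

**Scenarios.** `null`: full overlap, γ = 0 (RTF ≡ 1). `interference`: full
overlap, γ = 0.5. `complementation`: disjoint niches (RTF = N, RMF = 1).
`mixed`: breadth 0.35, γ = 0.4 — both channels active, the regime that
qualitatively reproduces rising uptake with falling rCUE.

**Measurement layer.** Time points 0, 16, 24, 32, 40, 64, 110 h. Cell
trajectories are exponential-to-plateau with the plateau at the true carrying
capacity (so the within-110 h maximum recovers it exactly without noise);
growth rate increases with richness (base 0.1 h⁻¹, +5 % per additional
taxon), reproducing the earlier time-to-peak of diverse communities.
Cumulative CO₂ follows one shared saturating schedule (τ = 24 h) for all
samples, so any windowed total is a fixed fraction of the full total and
window choice cancels from RTF ratios. Noise is a single multiplicative
log-normal factor (mean 1, CV 0.1 by default) per sample × channel — the
plate-calibration error of the bead/protein/indicator standards, which
dominates once counts are normalized per plate; per-time-point noise was
deliberately not used because taking a maximum over different numbers of
plateau points would bias fast growers upward relative to slow-growing
monocultures, an artifact rather than a property of the design. A small
atmospheric baseline (0.002 %CO₂ h⁻¹) is added to every well and removed by
blank correction. Reads are multinomial (depth log-normal around 20 000;
blanks 5 000) over stationary-phase cell fractions, with a kit contaminant at
0.2 % in real samples and 40 % in the four blank wells, plus ≤1 % per-taxon
cross-talk and a second blank-only contaminant. Monoculture impurity is
modeled at the read level (dominant fraction uniform on 0.86–0.995): a single
founder grows a pure culture, so impurity reflects sequencing cross-over, not
growth. Noiseless runs (`exact_composition`) emit counts as
`round(fraction·10¹²)` so integer tables still carry abundances to ≈10⁻¹²;
ordinary multinomial sampling would inject ~depth^(−1/2) noise and mask
exactness checks. All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawning.

What the generator does **not** emulate: sequence-level reads, taxonomy,
tree inference, media chemistry, grazing, strain-level variation below the
16S level, or density-dependent growth interactions beyond the interference
term. Passing tests therefore demonstrate correctness of the analysis
machinery under the model's assumptions (linear function–uptake coupling,
plate-level noise, abundance-proportional attribution), not robustness to
every failure mode of real amplicon data.

## Statistics

Curve fits: `y = a + bx`, `y = a + b·ln x` (natural log), `y = Vx/(K+x)`
(no-intercept Michaelis–Menten; an intercept variant is a flag) by least
squares; AIC from the Gaussian likelihood with the error variance counted as
a parameter. "Comparable to the least AIC" is formalized as ΔAIC ≤ 2 with
ties resolved toward the simpler family (linear ≺ log-linear ≺ hyperbolic).
Exact zero-residual fits are floored at numerical noise so degenerate data
tie rather than rank on rounding error. Confidence bands are Monte-Carlo
draws (default 5000) from the asymptotic parameter covariance — a single
documented method in place of mixed Taylor/Monte-Carlo propagation. A
non-converging family is dropped with a warning.

Richness bins split at 12 and 26 taxa; one-sample two-tailed t against 1 per
bin (bins under 3 communities are skipped with notice). Paired comparisons
report a two-tailed paired t and a one-tailed Wilcoxon **signed-rank** test —
the paired analogue of the rank-sum test (the protocol's phrase "paired
Wilcoxon rank sum" names an unpaired test; signed-rank is what pairing
implies). Scaled curve comparisons divide each fitted curve by its grid
maximum before a paired t, making the test scale-invariant by construction.

The key-taxa screen slides windows of width 2–10 (step 1 richness unit) over
stationary-phase richness, requiring ≥ 5 communities per window and taxon
presence in ≥ 3; Kendall tau-b per (taxon, window, function) with
Benjamini–Hochberg adjustment pooled within each (function, width) stratum
(pooling everything is a flag); hits at q < 0.05. Tau-b and its tie-corrected
asymptotic p-value are computed by direct pair enumeration — the screen makes
thousands of calls on 5–40-point windows where library call overhead
dominates — and are verified against both scipy and a brute-force oracle in
the tests.

Loreau–Hector: ΔRY_i = F_C,i/M_i − RY_exp,i; complementarity =
N·mean(ΔRY)·mean(M); selection = N·cov(ΔRY, M) (population covariance); the
identity net = complementarity + selection holds algebraically, and with
equal monocultures complementarity reduces to (RTF − 1)·M̄ — the linear link
between the partition and the RTF index. Density-adjusted regression uses
OLS on richness + log₁₀(initial density) with type-II sums of squares.

## Problem sizes and determinism

The bundled studies use 20–200 communities over richness 2–30 from pools of
25–60 taxa, 100-seed replications for calibration-style checks, 50 trials per
family for fit recovery, and 100 permutations for screen calibration — sizes
at which every Monte-Carlo check is stable across seeds while a full test
run stays in the minutes range. Identical configuration and seed give
byte-identical pipeline output bundles (fixed float formatting, sorted
orders, hierarchical seeding).

## Known limitations

- Attribution by read abundance inherits the equal-per-cell-ratio assumption;
  with strong taxon heterogeneity the CO₂ and protein RTFs are biased in ways
  the adjustment-factor report flags but does not correct.
- The interference penalty is community-uniform; per-taxon antagonism
  hierarchies (and hence selection-effect-dominated partitions) are outside
  the default model.
- Rarefaction uses the exact hypergeometric expectation; richness estimators
  that extrapolate unseen taxa are out of scope, and observed ASV counts are
  the richness used downstream.
- The MPD/MNTD metrics use the full post-QC table without re-filtering by
  constitutability; MNTD weights each taxon's nearest-neighbour distance by
  its own abundance (the picante ``abundance.weighted`` convention).
- Window screens use stationary-phase richness and function values; the
  inoculum-based variant is not implemented.
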