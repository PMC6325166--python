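# Methods

## Mass arithmetic and ion conventions

All m/z prediction reduces to integer element counts over a five-element
monoisotopic table (C 12.0, H 1.00782503, N 14.00307400, O 15.99491462,
P 30.97376163 Da). Neutral glycerophospholipid formulas come from
closed-form subclass templates in `(c, D)` — total acyl carbons and total
double bonds — algebraically identical to assembling glycerol + phosphate +
headgroup alcohol + fatty acids with one water lost per condensation
(PE: C(c+5)H(2c+10−2D)NO8P, PC: C(c+8)H(2c+16−2D)NO8P, PG:
C(c+6)H(2c+11−2D)O10P, PI: C(c+9)H(2c+15−2D)O13P, PA: C(c+3)H(2c+5−2D)O8P,
PS: C(c+6)H(2c+10−2D)NO10P, FA: CcH(2c−2D)O2; each ether chain −O +2H).
Singly charged ions use the proton mass 1.007276 Da as the charge carrier,
which absorbs the electron mass and reproduces reference neutral masses
(PE 39:4 = 781.5622 Da) and ion m/z to 1e-4 Da. The acetate adduct delta
(+59.0133) follows the configured constant rather than adding the electron
mass back; the 0.55 mDa difference is far below the 0.3 Da matching
tolerance. PA and PS templates exist for completeness but are not profiled
by default (no headgroup scan is defined for them here).

Nominal (unit-resolution) m/z is round-half-up. Exact values are kept
internally everywhere; printed unit-resolution values (m/z 718.6, 776.3)
are treated as display forms and matched with tolerance, never reproduced
as stored constants.

## Diagnostic-ion model

A PB product carries one acetone (+58.0419 Da; conversion to the
double-addition product is treated as background, not signal). CID cleavage
at a bond Δn of a chain with `C` carbons discards the methyl-side fragment
`C_m H_{2m−2k}` (m = C − n; k = methyl-side double bonds of the candidate
position set) and retains one acetone-derived oxygen, giving

    F_A = basis − m(C_m H_{2m−2k}) + m(O) − NL,   F_O = F_A + 26.0157.

The basis and neutral loss depend on subclass and polarity: intact
[M+H]+ with NL = 141.0191 Da (phosphoethanolamine) for PE; intact [M+H]+
with no loss for PC (the phosphocholine headgroup survives); the
fatty-acyl carboxylate anion with no loss for PG/PI (the MS3-style
second-precursor route) and free fatty acids. The neutral-loss table is
configuration, not code, so other subclasses can be added.

Candidate positions for de novo assignment: every n in [2, C−2] for
monounsaturated chains; for polyunsaturated chains, methylene-interrupted
sets (n, n+3, …) by default — essentially all biological PUFA — with an
unconstrained d-subset mode as the escape hatch for unusual structures.

## Acceptance rules for a C=C call

A candidate survives only if, for **every** bond of the set, both F_A and
F_O are matched (default tolerance 0.3 Da, the unit-resolution QTRAP
regime; ppm mode available), both exceed the S/N floor (default 3) and
their intensities agree within a factor r (default 5) — diagnostic pairs
are expected at similar intensities, and a wildly asymmetric "pair" is more
plausibly an interference. Surviving single-bond candidates are coexisting
location isomers; for polyunsaturated chains the highest-evidence set is
the primary call and other surviving sets are coexisting isomers (ω-3/ω-6
mixtures). Weak extra isomers below 5% of the strongest are reported with
a low-confidence flag rather than suppressed. Chains of minor (non-dominant)
acyl compositions are localized only when their theoretical ions avoid all
of the dominant composition's ions by more than the tolerance; otherwise
the chain is marked not-reported. A composition is "dominant" when its
acyl-anion evidence exceeds the runner-up by ≥ 3:1 (configurable; the
original analysis states the one-dominant rule without a number). Ether
chains are never localized, only flagged, since ether diagnostics were not
validated. sn positions are never assigned.

S/N is the peak intensity over the median intensity of the other peaks in
a ±50 Da window, floored at 1. The median is only a noise estimate when a
noise population exists, so it is applied only when the window holds at
least 10 other peaks; sparser spectra fall back to the floor. This keeps
the S/N gate meaningful on dense real scans without rejecting sparse
simulated or clean spectra whose "median peak" is another analyte ion.

## Isomer relative quantitation

For two coexisting isomers A (lower Δ) and B,
R = Σ(F_A + F_O intensities of A) / Σ(F_A + F_O of B), computed per
technical replicate and summarized as mean ± s.d. and RSD%. Only
collision-free evidence contributes; a zero denominator yields an
explicitly flagged undefined ratio, never an infinity. R is a
diagnostic-ion abundance ratio — proportional to, but not identical with,
the concentration ratio; no isomer-standard calibration is modeled.

## Profiling and chain assignment

NLS/PIS profiling scans are pseudo-spectra whose peaks are (precursor m/z,
summed intensity) over the subclass retention-time window; the monitored
NLS mass / PIS fragment m/z rides along (`scan_value`) so that e.g. a
PIS-153 PG profile is never consumed as a PIS-241 PI profile. Profile
peaks above a relative floor (default 0.1% of base peak) are converted to
neutral mass by undoing the profiling adduct and matched on a species grid
(total carbons 24–48 including odd values, 0–8 double bonds, 0.3 Da).
Isobars such as PE 39:4 / PC 36:4 (both m/z 782.6) are separated by scan
mode and RT window (defaults PE 5.1–6.5 min, PC 13.8–15.1 min, PG/PI
0–5 min; fully configurable). Chain compositions are enumerated over
carbons 2–26 (odd included), scored by summed intensity of both matched
fatty-acyl anions — both required — and ranked. Unsaturated resolved
species produce exactly one PB target (+58.0419 Da) within the configured
instrument m/z range (PE 350–1000, PC 500–1000).

## Synthetic data: what it emulates and what it does not

The simulator emits the three scan layers for a ground-truth lipidome with
seeded determinism (byte-identical MGF per seed). Defaults encode the
study conditions: PB conversion 0.25 (20–30% envelope), single-addition
fraction 0.92 (≥0.9; the remainder appears at +116.08 Da), multiplicative
lognormal intensity noise (CV 5%), m/z jitter σ 0.02 Da, Gaussian RT
jitter σ 0.1 min, sparse uniform background peaks standing in for Norrish
type I side products. Diagnostic-pair intensities are proportional to
abundance × PB yield × isomer weight, split evenly between F_A and F_O.
The "bovine-liver-like" template seeds the reference structures (the
C18:1 Δ9/Δ11 duplex at 3:1, C16:1 Δ9/Δ7 at 4:1, ω-6/ω-9 and ω-3/ω-6 PUFA
mixtures, the odd-chain PE 17:0_22:4, and the PE 39:4 / PC 36:4 isobaric
pair) before sampling the rest of the panel.

Not emulated: isotope envelopes, detector saturation, chromatographic peak
shapes, ion suppression beyond per-subclass scaling, and real co-isolation
chimeras. Passing tests therefore demonstrate the correctness of the
annotation logic and the statistical machinery under controlled noise —
not instrument-level robustness on real raw data.

The cohort simulator draws per-individual lognormal measurements around
group means with nested technical repeats (defaults: 6 vs 6 individuals,
3 repeats at 8% technical CV, isomer-ratio biological CV 10%,
subclass-level I/I_IS CV 40%, a 5.0 → 3.7 ratio contrast), reproducing the
precision contrast that makes isomer ratios better group discriminators
than subclass abundances at small sample size.

## Statistics

Group comparisons use the two-tailed Student's t-test (equal variance, as
stated for the original analysis) with Welch switchable; degenerate
variances yield a flagged undefined p, and exactly identical groups give
p = 1. FDR control is Benjamini–Hochberg (method pluggable). Hierarchical
clustering standardizes each measurement (log2 then z-score), uses
Euclidean distance with average linkage by default (Ward/complete
available), and reports the Rand index of a flat k-cut against the known
groups plus a Newick export of the dendrogram. RSD decomposition:
technical RSD = mean within-individual RSD over repeats; inter-individual
RSD = RSD of individual means (the latter includes a small
technical-noise contribution, CV_tech/√n_repeats in quadrature).

## Numerical/design choices and problem sizes

Tolerances: 1e-4 Da on exact-mass identities, 0.3 Da matching. Peak lists
are kept sorted; ties in `match_peak` resolve to the most intense peak.
MGF text is written with fixed formats (4 decimals m/z, 1 decimal
intensity) for reproducible byte-identical output. Simulation-based tests
run at desk scale — panels of 8–20 species, 20 seeds for ratio recovery,
10,000 null comparisons for t-test calibration, 6-vs-6 cohorts for
clustering — sizes chosen to make the checked properties statistically
stable while keeping the suite fast.

Known limitations: no sn-position or C=C geometry assignment; no SM or
glycerolipid support (the PB chemistry model here covers GP subclasses and
free fatty acids); no absolute quantitation; single-charge ions only; the
dominance threshold and the F_A:F_O similarity window are heuristics
surfaced in configuration rather than values fixed by the underlying
chemistry.
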