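# Methods

This note documents the models, conventions and numerical choices behind
`cuspec`, and what the synthetic-data conditions do and do not demonstrate
about real data.

## Mass conventions

All printed m/z values in unit-resolution triple-quadrupole work are
integers, so the package's default mass mode is **nominal**: each element
contributes the integer mass of its most abundant isotope (H 1, C 12, N 14,
O 16, S 32, Cu 63).  The **monoisotopic** mode (lightest-isotope exact
masses, electron mass neglected — an error < 6 × 10⁻⁴ Da at charge 1) is
available throughout for high-resolution data.  The copper element entry
carries the rounded 69/31 abundance pair for ⁶³Cu/⁶⁵Cu; this is the single
source of the doublet ratio 31/69 = 0.449 used by the screen.

## Cu(II) binding convention

Complex ions are assembled as Σ free amino acids − n_bonds·H₂O +
n_waters·H₂O + Cu − 2H, then ±H for the electrospray charge.  The −2H term
is the standard divalent-metal convention: Cu²⁺ displaces two acidic
protons, leaving a neutral complex that ionises by ordinary
(de)protonation.  Chelate ("X=Cu") and bridging ("X-Cu-Y") structural
notations are treated identically — at nominal resolution they are
isobaric.  This convention reproduces the 302/300, 332/330 and 360/358
positive/negative ion pairs exactly.  One reported 3-amino-acid ion (m/z
429, negative, Val/Phe/Ala) does not mass-balance under any bond/adduct
combination; the enumerator finds it only at a widened tolerance (best
candidates at ±2 Da) and reports the error rather than special-casing it.

## Isotope patterns

Theoretical isotopologue distributions are computed by per-atom convolution
on an integer nominal-mass grid, merging isotopologues that land in the
same unit bin (probability-weighted mean exact mass), normalising to base
peak = 100 and truncating below a relative-intensity threshold (default
1 %).  Unit-mass aggregation matches the screen, which operates on
unit-spaced doublets.  The test suite checks the convolution against an
independent multinomial enumeration oracle.  For any one-copper organic the
A+2/A ratio is 0.449 plus the organic A+2 contribution — e.g. ≈ 0.49 for a
C₂₀ species — which is why the screen's ratio window is centred on 0.449
with a generous ±25 % tolerance.

## Doublet screening

Anchors are tried greedily by descending intensity (ties: ascending m/z).
A hit requires a partner peak at A + 2 ± 0.5 Da (nominal mode; Δ = 1.9982
for exact-mass data), an A+2/A ratio inside 0.449 × (1 ± 0.25), and a
cosine score ≥ 0.95 between the local peak cluster (unit-mass binned) and
the theoretical copper doublet.  The 0.95 default passes proportional
patterns with ≤ 10 % relative intensity error while rejecting
partner-less peaks (a lone A peak scores 0.912 against the doublet).

One subtlety: the A+1 isotopologue of a one-copper cluster pairs with A+3
at almost exactly the copper ratio, so a naive scan reports every copper
species twice.  Accepted hits therefore consume the peaks in
(mz_A, mz_A+2] as future anchors.  This is deliberately minimal
deisotoping: the screen remains a pre-filter that reports chance doublets
in noise rather than suppressing them; composition and fragmentation
evidence downstream arbitrate.

## Composition enumeration

The search space is every multiset of ≤ 4 amino acids (20 proteinogenic
codes), 0..n−1 peptide bonds, 0..2 whole-H₂O adducts — ~10⁵ candidates,
enumerated in well under a second with precomputed masses.  Candidates
within tolerance (0.5 Da nominal / 0.01 Da monoisotopic by default) are
ranked by |mass error|, then modification count (bonds + adducts), then
lexicographic ligand order — a total order, so output is deterministic.
All tolerant candidates are returned; a rank-1 candidate is *not* an
identification.  `verify_assignment` recomputes each candidate's m/z from
first principles through the formula layer as a self-check.

## Fragment annotation

Product ions are explained as multisets of ≤ 3 library losses whose masses
(plus a signed ±H₂ adjustment, |n| ≤ 3) sum exactly to the nominal
precursor–product difference.  Preference: fewest steps, then fewest |H₂|,
then lexicographic labels.  H₂ transfer is common in metal-mediated CID but
an unbounded ±nH₂ term would explain any even difference, hence the penalty
and cap.  H₂ itself is never a counted step — it lives exclusively in the
adjustment channel so step counts stay meaningful.

Interpreting a *specific* precursor uses a library restricted to its
proposed ligands plus the generic small losses
(`LossLibrary.for_ligands`).  This mirrors how a spectroscopist reads a
spectrum — losses of amino acids the complex does not contain are not
candidate explanations — and it removes spurious isobaric ties (with all
20 amino acids available, a Val loss (117) would displace the correct
−Thr+H₂ reading on a Tyr/Ser/Thr complex).  Small printed fragment
formulas are matched at neutral nominal mass ± 1 H, since such labels
often name the neutral of a protonated ion (C₄H₇NO, 85, for an ion at
m/z 86).

## SEC calibration and peak detection

Calibration is an ordinary least-squares line of log₁₀(MW/kDa) on retention
time — the standard working model inside a size-exclusion column's
fractionation window.  Fits with a non-negative slope are rejected (they
violate SEC physics), as are duplicate retention times.  Assignments
outside the standards' time span are flagged extrapolated (void volume
above the largest standard; below the smallest calibrant at long times),
and every assignment also reports the MW interval bracketed by the
neighbouring standards, which is often the honest resolution of SEC.

Peak detection requires a local maximum above baseline + SNR·noise, with a
prominence of at least SNR·noise (default SNR 5).  Baseline is the median
intensity; noise is the median absolute deviation of the first-differenced
trace (robust to the peaks themselves).  The prominence gate exists because
under any nonzero noise a pure height threshold converts every noise wiggle
on a tall peak's flank into a "peak".  Detection is invariant to uniform
intensity scaling since baseline and noise both scale.

## Bioaccessibility

%bioaccessibility = fraction/total × 100, with first-order ratio
propagation sd% = pct·√((sd_f/f)² + (sd_t/t)²), treating the two
concentrations as independent.  Values above 100 % are legal, flagged, and
never clipped — with measurement error a fully bioaccessible element's
digest can exceed its measured total, and ≈100 % reads as complete
bioaccessibility.  Reported ± values on input concentrations are treated
as standard deviations (the propagation method for expanded uncertainties
would differ only by the coverage factor).

## Synthetic-data conditions

The generators define the study conditions used by all tests:

* **Spectra**: the five reported complexes planted in negative mode at
  their computed m/z (358, 300, 330, 483, 431 — the last is the
  non-balancing Val/Phe/Ala ion at its nearest balancing composition),
  base intensities 600–1000, full isotope patterns at ≥ 1 % relative
  intensity, plus (optionally) 10× uniform-random noise peaks on
  50–1000 m/z with log-uniform intensities 1–50 — a chemical-noise floor
  well below the analyte peaks.
* **Chromatograms**: Gaussian peaks at 11, 16, 26.5, 34 min (heights
  3000/1500/10000/6000, σ 0.35–0.5 min) on a 0.1-min grid, baseline 100,
  white noise σ = 10 (≈ 0.1 % of the main peak, typical of smooth ICP-MS
  traces).
* **SEC standards**: the five-standard MW set placed exactly on a
  log-linear law anchored at (17 kDa, 26.5 min) and (1.35 kDa, 34 min).
  The source figure's stated time↔MW correspondences are not mutually
  consistent with a single line, so the two most direct anchors define the
  synthetic law; real calibrations drift from log-linearity near the
  exclusion limits.
* **Digestion tables**: n = 3 normal draws per fraction, truncated at 0,
  with fraction means of 48.0/47.1/88.2/81.2/103.7 % of a 23.9 µg g⁻¹
  total and the corresponding reported SDs.

What passing these conditions shows: the arithmetic chain (composition ↔
m/z, losses ↔ mass differences, line fit ↔ MW, ratio ↔ percent) is
internally consistent and invertible at the study's printed precision, and
the screen/detector logic recovers planted truth under controlled noise.
What it does not show: performance on profile-mode data, overlapping
isotope clusters of co-eluting species, multiply charged or multi-metal
ions, electrospray response, tailing peak shapes or drifting baselines —
all outside the generators' vocabulary and the package's scope.

## Problem sizes and determinism

Default problem sizes (4-ligand search space ≈ 10⁵ compositions, ≤ 3-step
loss search over ≤ ~30 library entries, 1000-repetition recovery studies,
351-sample chromatograms) run in seconds on a laptop.  Every stochastic
component takes an explicit integer seed through numpy's `default_rng`;
identical seeds give byte-identical outputs, and the pipeline writes its
effective configuration next to its outputs.
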