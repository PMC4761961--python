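# Methods

This note documents the models behind `aptascreen`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices that matter for reproducing its output.

## Inverted-repeat detection and selection

A length-*L* sequence is decomposed into terminal arms plus a central loop:
register *(arm, loop)* with 2·arm + loop = L pairs position *i* with
*L*+1−*i* for *i* = 1..arm. Pairing is evaluated on a T→U unified alphabet
(A·U/T and G·C Watson–Crick; G·U/T wobble, counted separately and excluded
from the match score by default because the input elements are DNA, where
wobble pairing is not standard). Because the registers are nested, the best
register is always the longest arm the length admits; outer non-pairing
positions are recorded as mismatches. The detector returns "no repeat" only
when the sequence cannot host `min_arm`-long arms around a `min_loop` (3 nt,
the physical hairpin minimum) loop, or pairs nothing at all.

Selection then keeps elements whose decomposition has `arm ≥ min_arm`
(default 5) and `n_mismatches ≤ max_mismatch` (default 3). The arm-coverage
requirement doubles as the guard against extended half-sites: an element
whose half-sites are separated by a long spacer cannot place complementary
arms at its termini. Ties between equal-scoring registers go to the longer
arm, then the smaller loop; all 18 packaged elements pass the defaults, with
0–3 mismatches at arm 7.

## Single-stem hairpin free energy

The folding model restricts structures to one contiguous stack of
Watson–Crick/G·U pairs closed by a terminal loop of ≥ 3 nt, with free 5'/3'
tails:

ΔG = Σ stack(pairₖ, pairₖ₊₁) + loop_init(loop length) + terminal A·U/G·U
penalty at the open helix end.

Constants are the published Turner 2004 ΔG°37 set (36 stack steps including
wobble, hairpin-loop initiations for 3–30 nt, terminal penalty 0.50
kcal/mol), shipped as a versioned TSV (`turner2004-v1`) and swappable through
`NearestNeighborTable`. Loops beyond the table extrapolate as
ΔG(n) = ΔG(30) + 1.75·RT·ln(n/30). Two deliberate simplifications: no
bulges/internal loops/multiloops (the candidates are 15–20-nt near-perfect
palindromes, for which the optimal structure is a single stem), and no
terminal-mismatch terms (they shift all candidates comparably and would break
the exhaustive-enumeration oracle's simplicity). The published
loop-initiation series is not monotone between 4 and 8 nt, so table
validation enforces non-negativity everywhere and monotonicity only from
9 nt up.

Consequences: absolute ΔG values are not comparable to full secondary-
structure predictors, and the package relies only on orderings and signs.
The packaged table of printed folding energies was produced by a different
(unknown-configuration) predictor and is treated strictly as *input* to the
group statistics, never as numbers this model should match; the one
cross-model assertion kept is ordinal (the best candidate folds far below
the weakest random control).

The open chain defines ΔG = 0; a sequence whose best stem is non-stabilizing
reports no structure and scores 0 in batch output.

## Consensus docking normalization

Per candidate and engine, the mode scores E₁..Eₘ (m = 10 by default, any
m ≥ 2 accepted) are reduced to Z = min over modes of (Eᵢ − Ē)/SD. SD is the
sample (n−1) standard deviation — the convention is configurable (`ddof`)
and recorded in output headers, since the source analysis does not state it.
All scores must be on a lower-is-better scale; score sets ingested with
`orientation="higher"` (e.g. shape-complementarity scores) are negated once
at ingestion. Z_T is the strict three-engine sum — a missing engine is an
error, never a silent two-engine sum. Ranking is ascending in Z_T with
lexicographic id tie-break (the printed table has no ties).

Note an intrinsic bound: the studentized minimum of m samples cannot fall
below −(m−1)/√m (≈ −2.85 for m = 10), so per-engine Z-scores live in a
bounded range no matter how deep the best mode is.

## Group statistics

Pooled (equal-variance Student) two-sample t with df = n₁ + n₂ − 2 and
two-sided p — the pooled form is identifiable from the reported degrees of
freedom, and the reported folding-energy comparison (t(8) = 1.92,
p = 0.0911) reproduces exactly under it. Degenerate inputs: two groups with
zero pooled variance and equal means give t = 0, p = 1; with unequal means
the statistic is undefined and rejected. Group membership (candidate vs
control) is always declared by the caller.

## Contact counting

Heavy-atom, distance-only criteria, chosen because docked models and most
crystal structures carry no hydrogens:

- hydrogen bond: protein-typed donor/acceptor vs nucleotide-typed
  acceptor/donor at 2.4–3.35 Å (both directions tried, each unordered pair
  reported once);
- hydrophobic contact: apolar carbon vs apolar carbon at ≤ 3.9 Å.

Typing tables ship as editable JSON. Protein apolar carbons are those with
no bonded N/O; for nucleotides the sugar CH/CH₂ carbons other than C1' are
kept by convention despite ether/hydroxyl neighbours (matching common
contact-diagram practice), plus base CH carbons (A: C2, C8; G: C8; C/U: C5).
Carbonyl and amine-bearing carbons are never hydrophobic. Atoms are classed
protein/nucleic by residue name, so swapping argument lists changes labels,
not counts; counts are monotone in the cutoffs and invariant under rigid
motion. Published bar-chart contact counts are *not* reproduction targets
(figure-read values with unstated criteria); correctness is established on
generated complexes with planted contacts.

PDB input is parsed with gemmi behind a fixed-column pre-check that reports
malformed coordinate fields by line number; alternate locations resolve to
the highest-occupancy conformer (ties to 'A') and waters are dropped by
default.

## One-site ITC model

Titrant totals follow the displaced-volume convention: after injection *i*
of volume *v* into cell volume *V₀*, M = M₀·f^i and X = Xs·(1 − f^i) with
f = 1 − v/V₀. Bound complex is the closed-form physical root of the 1:1
quadratic with site concentration n·M (its discriminant is positive by
construction). The normalized heat is

q_i = V₀·ΔH·(C_i − f·C_{i−1}) / (Xs·v),

which yields exactly q = ΔH before saturation in the strong-binding limit
and a total heat approaching V₀·ΔH·n·M₀ when dilution is negligible.
Simulation adds i.i.d. Gaussian noise to the heats (kcal/mol of injectant);
the default noise used in recovery studies is 2% of |ΔH|.

The injection volume is not stated in the source protocol (only 25
injections of 10 µM titrant into 1 µM protein); the default of 10 µL per
injection is the standard VP-ITC choice and spans molar ratios up to ~1.8.
The first-injection artefact common in real instruments is not modelled.

Fitting: `scipy.optimize.least_squares` over (n, log Ka, ΔH) — log Ka for
conditioning — with starting values from the data (n from the molar ratio at
half cumulative heat, ΔH from the first two heats, Ka from a c ≈ 10 guess)
and tight tolerances (1e−14). Standard errors come from the asymptotic
Gauss–Newton covariance σ²(JᵀJ)⁻¹ with the delta method for Ka. Flat
isotherms, fewer than 6 injections, and non-increasing injection schedules
are rejected before fitting. Zero-noise round trips recover parameters to
machine precision across Wiseman c from 5 to 500.

Thermodynamic derivations use R = 1.987×10⁻³ kcal/(mol·K) and T = 298.15 K
for 25 °C: ΔG = −RT ln Ka and TΔS = ΔH − ΔG, so ΔG + TΔS = ΔH identically.
The packaged printed thermodynamic table is internally consistent with
ΔG = ΔH − TΔS at its printing precision (ΔH and TΔS carry one decimal, so
residuals up to ~0.1 kcal/mol are rounding, with three rows exact at two
decimals) but *not* with −RT ln Ka (gaps of 0.1–0.4 kcal/mol; −0.17 for the
best candidate). Rather than silently choosing a convention, `audit_table`
computes both residuals and flags disagreements and sign anomalies — the
audit surfaces one row with a positive printed ΔH, one whose identity is off
by 2.9 kcal/mol, and one with a positive printed ΔG, all presumed typos and
stored verbatim in the fixture.

## Synthetic generators

The generators reproduce the statistical structure each stage consumes, not
the physics behind it.

- **Docking mode scores**: per engine, modes are loc + Gamma(shape 1.95,
  scale θ) with lower = better — mode lists pile up near their best score
  with a tail of worse poses. θ is set so the mode-score SD equals the
  engine's `scale`. For binders the single best mode is pulled a further
  0.39 SD down. The shape and boost were calibrated by Monte Carlo so the
  consensus means match the reported group contrast (binders ≈ −4.45,
  non-binders ≈ −3.56); the mechanism then implies within-group Z_T SDs of
  ≈ 0.49/0.45 — tighter than the reported 0.76/0.51, which include
  between-candidate heterogeneity the generator deliberately does not model.
  With these defaults an 18-vs-5 pool reaches pooled-t significance at
  α = 0.05 in ≈ 96% of replicate generations.
- **Sequences**: palindromic RNAs compose the 5' arm to a target GC
  fraction (± 1 base), mirror it, and plant exactly the requested number of
  non-pairing mismatches at the *outermost* arm positions, which keeps the
  full-arm register uniquely best so detectors recover the planted counts;
  random RNAs are uniform i.i.d.
- **Complexes**: each planted hydrogen bond is a lysine NZ 3.0 Å from an
  adenosine OP1, each hydrophobic contact a leucine CD1 3.5 Å from a C5';
  sites are ≥ 12 Å apart and all other intermolecular pairs > 5 Å, so
  detection at default cutoffs is exact. A seeded random rigid motion is
  applied to the whole complex.

All generators are pure functions of (parameters, seed). Passing tests on
this synthetic data demonstrates the *arithmetic* of the pipeline — it says
nothing about docking accuracy, real calorimetric baselines, or sequence-
dependent binding, none of which are modelled.

## Problem sizes

Defaults keep everything desk-scale: oracle-equivalence sweeps use 500
random sequences of ≤ 20 nt (exhaustive enumeration is exact there); ITC
recovery studies use 12–25 replicate fits of 25-injection isotherms; the
pool-calibration property uses 100 replicate 23-candidate pools. The full
test suite runs in a few seconds on one CPU.

## Known limitations

- The hairpin model's magnitudes are not comparable across energy models;
  only orderings are meaningful.
- Raw per-mode docking scores behind the packaged Z-score table were never
  published, so only the derived Z arithmetic is replayable; the reported
  18-vs-5 consensus t-test against random controls likewise rests on
  unpublished control values and is asserted only as a directional property
  on synthetic pools.
- Contact detection has no angle terms by default and no π-stacking,
  salt-bridge or water-mediated categories.
- The ITC module fits a single site class; multi-site or sequential models
  and raw power-curve integration are out of scope.
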