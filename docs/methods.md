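# Methods

This note documents the models implemented in `nanovax`, the conventions
and defaults chosen where the design was genuinely open, what the
synthetic-data generators do and do not emulate, and known limitations.

## Peptide constructs and charge convention

Constructs are one-letter sequences over the 20 standard amino acids
(B/J/O/U/X/Z rejected, input case-normalized). Annotation is greedy
left-to-right against a priority-ordered motif library (default:
CALNN→anchor, KK→spacer, GPGPG→spacer, PKYVKQNTLKLAT→epitope,
RKKRQRRR→cpp); at a given position the first matching library motif wins,
claimed motifs cannot overlap, and unmatched stretches carry no region.
Annotation is therefore deterministic and never errors on overlap.

The positive-charge convention counts Lys and Arg side chains plus one
free N-terminal amine and excludes His at neutral pH (both choices
exposed as flags). This is the only convention that makes the composition
of the TAT-bearing 28-mer simultaneously "5 Arg + 7 Lys" and "13 basic
residues". The C-terminus is treated as amidated by default — these
constructs are made on Rink amide resin — so it contributes no negative
charge; a free-acid flag adds one.

Limitation: charge counting is integer bookkeeping, not a pKa model; it
predicts rank order of surface charge between constructs, not zeta
potentials.

## Cleavage-site prediction

Subsites P4 P3 P2 P1 | P1′ P2′ P3′ P4′ align to residues p−3 … p+4 around
the scissile bond p. Only fully interior windows are scored (p ∈ [4,
L−4]); an optional `pad_score` scores all bonds 1..L−1 with a neutral
fill, off by default. Scores are summed exactly as given in the matrix —
no log transform or background normalization; any such preparation
belongs to matrix provenance. Ranking is by descending score with ties
broken by ascending bond position, which makes ranks deterministic.
`select_top_sites` keeps k = 3 by default (three cuts × two fragments =
the six putative fragments reported per construct).

Fragmentation is single-cut: each selected bond is applied independently
to the intact parent, giving fragments [1..p] and [p+1..L]; fragments are
deduplicated by exact sequence keeping the first (rank-order, N-side
first) occurrence. An exhaustive multi-cut digest is deliberately not the
default — the single-cut model is the one that corresponds to the
reported fragment tables. Epitope release is a substring test of the
query core against the fragment set.

### The bundled matrix fixture is synthetic

The real cathepsin-B substrate-specificity matrix is a licensed database
export that is not redistributed here. The bundled fixture
(`data/cathepsin_b_synthetic.tsv`) is a **synthetic stand-in**,
constructed once by `scripts/build_cleavage_fixture.py`: starting from a
biologically motivated prior (dibasic preference at P1/P2, mild Leu/Phe
at P2, Gly/Ala/Ser tolerance at P1′), a linear program finds the
L1-minimal perturbation such that the top-3 ranked bonds of the four
study constructs reproduce their published fragment sets with a 0.5-score
margin (scores rounded to 2 decimals; the margin makes rounding safe).
Scores are in arbitrary additive units; the provenance string in the file
records all of this.

Consequence: fragment-set concordance for p1–p4 is a property of this
calibrated fixture and validates the *algorithm* (windowing, ranking,
fragment enumeration), not the transferability of the score table to
other substrates. For real predictions, load an actual database-derived
matrix via `read_matrix` and record its version in `provenance`.

## Nanoparticle dosimetry

Spheres: V = πd³/6, A = πd², N_Au = ρ·N_A·V·10⁻²¹/M with bulk gold
ρ = 19.3 g/cm³, M = 196.97 g/mol (stored in one constants table). The §
geometry comparisons use nominal diameters 23 and 68 nm, under which
volume and atom ratios round to 26 and the area ratio to 9; TEM mean
diameters (23.4, 68.2 nm) are equally valid inputs but round differently
(25 and 8) and are not used for those checks.

Extinction: ln ε = a + k·ln d with defaults k = 3.32111, a = 10.80505
(empirical calibration for citrate-stabilised spherical AuNPs, Liu et al.
2007; the source study only cites this calibration without printing the
constants, so they are transcribed here and carried in
`ExtinctionCalibration.provenance`). Concentration is c = A/(ε·ℓ).

Coverage scale: the study's density unit "nmol-peptide/nm²" anchored at
0.3 for ratio 1:100,000 is implemented verbatim as a linear bookkeeping
scale even though, read literally, 0.3 nmol/nm² is physically implausible
for a peptide monolayer (it would be ~10¹⁴ peptides/nm²); every
computation is linear in it, so nothing downstream depends on the literal
unit. Printed-parity formatting truncates (never rounds) to two decimals:
0.225 → "0.22", 0.375 → "0.37".

Conjugation recipes compute R = coverage × 100,000, optionally × the
area ratio to the 23 nm reference particle (default on, so both particle
sizes receive equal surface densities); peptide moles = particle moles ×
R; pipetting volume from the stock concentration. For 2 mL of 2.47 nM
23 nm particles at coverage 0.75 and a 30 mM stock this gives 12.35 µL,
agreeing with the lower end of the reported 12.6–179.9 µL mixing range to
within its rounding; the full printed range is not reconcilable with the
printed particle concentrations and ratios under either normalization
mode (the worked-example appendix is unavailable), so the recipe op
implements first-principles arithmetic and this discrepancy is simply
noted here.

## Population coverage

Per locus, phenotypic coverage is 1 − (1 − p)² with p the summed
frequency of covered alleles (Hardy–Weinberg diploidy); loci combine as
1 − Π(1 − p_l)² under cross-locus independence — the standard
epitope-coverage convention. Frequency shortfall (locus sums < 1) is
uncovered mass by default; `renormalize=True` rescales each locus to
sum to 1. Binding sets are user inputs or synthetic: no MHC binding
predictor is implemented, and published coverage figures that depend on a
specific predictor plus a specific allele-frequency extract are out of
scope.

## Assay statistics

- `percent_of_control`: 100 × mean(values)/mean(control), plus
  per-replicate percentages; requires a positive control mean.
- `fit_4pl`: r(d) = lower + (upper − lower)/(1 + (d/IC₅₀)^h), least
  squares on all replicates at positive doses (≥ 4 distinct).
  Initialization is fixed for reproducibility: upper = max response,
  lower = min response, IC₅₀ = dose nearest mid-response, h = 1. Standard
  errors come from the covariance at the optimum; IC₅₀ is constrained
  positive. Degenerate inputs (constant responses, singular curvature,
  upper ≤ lower) return `converged=False` rather than a silent number.
  Both asymptotes are free (4PL, not 3PL).
- `normalize_activity`: normalized = raw/(survival/100). The "activity
  per survival" statistic is read as division by the survival *fraction*,
  the only reading that keeps values in the observed ~150–300 AU range
  when raw activity is O(150) AU; the alternative (divide by percent) is
  a one-line change confined to this function. Survival is contract-bound
  to (0, 100]; genuinely super-control survival must be capped by the
  caller.
- `charge_activity_summary`: per-zeta-bin mean ± sample SD (ddof = 1) and
  an OLS line (slope, intercept, r²) of normalized activity on zeta
  potential; r² is defined as 0 for constant activities. Bins must cover
  all points.

Standard hypothesis tests (normality, t-tests, ANOVA with post-hoc
corrections) are deliberately not wrapped; use scipy/statsmodels
directly.

## Synthetic-data generators

All generators are pure functions of `GeneratorConfig` (which carries the
seed); repeated calls are identical, and different generators derive
independent streams from the same seed. Ground truth (planted regions,
planted cut bond, true curve parameters) is always returned alongside the
data.

- `make_peptides`: anchor + optional spacer (KK or GPGPG) + random
  epitope-like core (9–15 residues) + optional TAT tail, with planted
  region truth. Emulates the construct grammar, not real epitopes.
- `make_matrix`: N(0, 1) background scores with a +8 bonus (default) for
  K/R at P1 and P2. Under this planting the preferred cut for a KK pair
  at positions i, i+1 is bond i+1 (both P2 and P1 basic). As the bonus
  grows relative to the background SD the planted bond is top-ranked with
  probability → 1; at the default the preference is strong but not
  deterministic.
- `make_dose_response`: 4PL truth (defaults: lower 5, upper 100,
  IC₅₀ 3308 pM, h 1 — the nanoconjugate viability estimate; the
  peptide-free-particle value 7280 pM is used as a second truth in the
  recovery tests) plus additive Gaussian noise. Noise SD is in response
  units on the 0–100 viability scale, so 2.0 ≈ 2% of the dynamic range;
  five replicates on an 8-point log dose grid (10–10⁵ pM) bracketing both
  IC₅₀ values.
- `make_allele_table`: per-locus Dirichlet(1.0) frequencies over 10
  alleles, scaled to a typed fraction of 0.95 (realistic incomplete
  typing), valid by construction.

What passing tests on these data do **not** show: real substrate
specificity (the matrix planting encodes only the dibasic preference),
real assay error structure (heteroscedasticity, plate effects and edge
effects are absent), or linkage disequilibrium between MHC loci (the
independence assumption of the coverage formula is exactly true of the
generator by construction).

## Numerical choices

- Ranking ties: descending score, then ascending bond position — total
  order, no RNG.
- Truncation formatter: floor(x·100 + 10⁻¹²)/100 guards against binary
  representation of decimal inputs while preserving truncation semantics.
- Monotonicity of ranking under single-cell score increases holds in
  exact arithmetic; with floats it can be violated by absorption
  (tiny + large == large manufactures ties), which the property tests
  avoid by using exactly representable scores.
- Allele-frequency sum tolerance: per-locus sums may exceed 1 by ≤ 10⁻⁹
  to absorb float round-off in otherwise valid tables.
- 4PL fitting is bounded only where mathematically required
  (IC₅₀ > 0); no log-reparameterization, so the reported covariance is in
  the natural parameters.

## Problem sizes used in the checks

Oracle-equivalence checks compare the window scorer against an explicit
double-loop scorer on 1,000 random peptide/matrix pairs (lengths 8–40).
4PL recovery uses 60 simulated plates per noise level (2 and 5 response
units) per truth value, asserting that the Monte-Carlo mean estimate is
within three standard errors of the generating truth, plus exact (0.1%)
recovery at zero noise. Coverage monotonicity is exercised on 1,000
random Dirichlet tables. These sizes give stable verdicts for the
properties asserted while keeping the default test run quick.
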