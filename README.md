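# nanovax

A design-and-analysis toolkit for peptide–gold-nanoparticle (p-AuNP)
nanovaccines. It covers the computational workflow around conjugating
modular immunogenic peptides to spherical gold nanoparticles and reading
out their cell-biology assays:

- **`nanovax.constructs`** — model and annotate modular vaccine peptides
  built from a gold-binding anchor (CALNN), protease-cleavable or flexible
  spacers (KK, GPGPG), a CD4+ T-cell epitope, and an optional
  cell-penetrating peptide (the arginine-rich HIV TAT segment), with
  charge/composition descriptors.
- **`nanovax.cleavage`** — predict endosomal cathepsin-B cleavage sites by
  sliding an 8-residue window (subsites P4…P4′) over every scissile bond,
  summing position-specific residue scores from a specificity matrix,
  ranking bonds, enumerating single-cut fragments, and testing whether a
  query epitope core is released intact.
- **`nanovax.nanoparticle`** — sphere dosimetry (volume, surface area,
  gold atoms per particle), size-dependent extinction coefficient at the
  surface-plasmon band, Beer–Lambert concentration from absorbance, and
  molar-ratio ↔ surface-coverage conversion for conjugation recipes.
- **`nanovax.coverage`** — theoretical MHC population coverage from allele
  frequencies under Hardy–Weinberg diploidy.
- **`nanovax.assay`** — control-normalized viability, four-parameter
  logistic (4PL) dose–response fitting with IC₅₀, survival-normalized
  cathepsin-B activity, and the activity-vs-zeta-potential summary.
- **`nanovax.synth`** — seeded generators for every input (constructs,
  matrices, plates, allele tables), so the whole pipeline runs and is
  testable without any downloads.

## The core models

**Cleavage scoring.** For a peptide of length *L* and a specificity matrix
*S*(subsite, residue), the score of the bond between residues *p* and
*p*+1 is

    score(p) = Σ_{i=-3..4} S(P_i, seq[p+i]),    4 ≤ p ≤ L-4,

where the eight subsites P4…P1 | P1′…P4′ align to residues *p*−3 … *p*+4
and hydrolysis occurs between P1 and P1′. Bonds are ranked by descending
score (ties by position), the top *k* = 3 sites are kept, and each cut is
applied independently to the intact peptide (single-cut model), yielding
up to 2*k* deduplicated fragments.

**Dosimetry.** A particle of diameter *d* has V = πd³/6, A = πd², and
N_Au = ρ·N_A·V/M with bulk-gold ρ = 19.3 g/cm³ and M = 196.97 g/mol.
The extinction coefficient follows ln ε = a + k·ln d (empirical
calibration), and c = A₅₂₀/(ε·ℓ) by Beer–Lambert. The coverage scale is
anchored at 1:100,000 peptides per particle ≡ coverage 1.00 ≡ 0.3
nmol-peptide/nm², and scales linearly in the molar ratio.

**Population coverage.** With covered allele-frequency mass *p_l* at locus
*l*, the fraction of a diploid population carrying at least one presenting
allele is 1 − Π_l (1 − p_l)².

**Dose–response.** r(d) = lower + (upper − lower)/(1 + (d/IC₅₀)^h), fit by
least squares with standard errors from the curvature at the optimum.

## Worked example

```python
from nanovax.constructs import study_constructs, charge_summary, EPITOPE_CORE
from nanovax.cleavage import load_cathepsin_b_matrix, predict_cleavage
from nanovax.nanoparticle import sphere_quantities, conjugation_recipe

p2 = study_constructs()["p2"]          # CALNN-KK-epitope-TAT, 28-mer
print([(r.kind, r.start, r.end) for r in p2.regions])
# [('anchor', 1, 5), ('spacer', 6, 7), ('epitope', 8, 20), ('cpp', 21, 28)]

print(charge_summary(p2))
# ChargeSummary(n_lys=7, n_arg=5, n_his=0, n_nterm=1, n_positive=13, n_negative=0)
# 7 lysines + 5 arginines + the free N-terminal amine = 13 positive charges

report = predict_cleavage(p2, load_cathepsin_b_matrix(), k=3, core=EPITOPE_CORE)
print([s.bond for s in report.selected])        # [9, 15, 17]
print([f.sequence for f in report.fragments])
# ['CALNNKKPK', 'YVKQNTLKLATRKKRQRRR', 'CALNNKKPKYVKQNT',
#  'LKLATRKKRQRRR', 'CALNNKKPKYVKQNTLK', 'LATRKKRQRRR']
print(report.epitope_released)                  # True — YVKQNTLKL survives

au23 = sphere_quantities(23.0, "Au23")
print(f"{au23.atoms_per_particle:.3e}")         # 3.759e+05 gold atoms
plan = conjugation_recipe(2.47, 2.0, 0.75, au23,
                          peptide_stock_mM=30.0, normalize_by_area=False)
print(f"{plan.peptide_volume_uL:.2f}")          # 12.35 µL of 30 mM peptide
```

The same operations are exposed on the command line via the `nanovax`
console script (`annotate`, `cleave`, `conjugate`, `coverage`, `assay`,
`synth`); run `nanovax --help` for details.

Note that the bundled cathepsin-B matrix
(`src/nanovax/data/cathepsin_b_synthetic.tsv`) is a synthetic,
calibrated stand-in for a database-derived specificity table; see
`docs/methods.md` for how it was constructed and what that implies.

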