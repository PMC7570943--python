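# Methods notes

## Scope and model

The package reimplements the statistical and arithmetic core of a
pharmacophore-based COX-2 virtual-screening campaign: activity
modelling by exhaustive descriptor-subset multiple linear regression,
residual validation, and the candidate triage formulas. Everything that
requires heavy external computation — geometry optimisation,
pharmacophore extraction, database screening, ADMET web services,
docking and molecular-dynamics execution — is out of scope by design;
where such stages produce numbers the package consumes (docking ΔG
values, MM-GBSA terms), those numbers are inputs, and only the
bookkeeping applied to them is implemented.

Activity is pIC50 = −log10(IC50 [M]); IC50 is stored in nM throughout
(the unit the reference tables use) and converted only inside
`pic50_from_ic50`. Descriptors are non-negative integer counts emitted
by pharmacophore alignment; they are never computed from structures
here. Missing descriptor values are a hard error in modelling, not
imputed — the reference tables are complete, and silent imputation
would change fits.

## Descriptor selection

Selection keeps descriptors with |ρ(descriptor, pIC50)| ≥ cutoff
(default 0.4). The absolute value matters: the acceptor count
correlates at −0.64 and carries as much linear information as a
positive correlate; sign-blind selection is the only reading consistent
with the reference descriptor set. Selection is a screen, not an
inference procedure — no multiple-testing correction is applied
anywhere, matching the source methodology.

## Regression and statistics

Fits are ordinary least squares (statsmodels behind `fit_mlr`), with
statistics computed from the residual and total sums of squares:
R² = 1 − SSE/SST, R = +√R², adj-R² = 1 − (1−R²)(n−1)/(n−p−1),
SEE = √(SSE/(n−p−1)), F = (R²/p)/((1−R²)/(n−p−1)). The SEE denominator
is the residual degrees of freedom n−p−1; this is verified consistent
with the reference mono-descriptor F (25.4183) and adjusted R² (0.5623)
at n = 20. A perfect fit reports F = +∞ rather than failing. Rank
deficiency raises a collinearity error; the independent cross-check in
the tests is a hand-written normal-equations solver, kept separate from
the statsmodels path.

The leaderboard fits every subset of the retained descriptors up to
`max_p` (C(n,p) per size, 2ⁿ−1 total) and ranks by R² descending, ties
broken by smaller subset then lexicographic subset signature — the
source states only "best fit", so the tie rule is this package's
choice. The reference leaderboard omits one tri-parametric subset
(ATM+ARO+DONN) without explanation; this implementation always emits
all C(n,p) models, so that row exists here but has no published
counterpart to compare against.

## As-printed vs refit evaluation

Published prediction equations carry coefficients rounded to 4
decimals. Internally all fits keep full precision; an explicit
`as_printed` mode (and the bundled `prediction_equations.csv`) rounds to
4 decimals so that published predictions and residuals reproduce digit
for digit. Reference statistics are compared at |diff| ≤ 1e-4 because
the source tables truncate rather than round some final digits (e.g.
the ACC correlation −0.639991 printed as −0.6399, the tri-model R
0.959966 printed as 0.9599).

## Reference data and known errata

The bundled CSVs carry the reference training set (20 molecules,
pivot = rofecoxib), internal (21–25) and external (26–31 + celecoxib)
validation sets, candidate descriptors, property profiles, prediction
equations, and the published per-model predictions. Two data issues are
preserved and flagged rather than corrected:

- molecule 15's printed pIC50 (8.3000) is inconsistent with its IC50
  (5 nM → 8.3010); the printed value is kept because the reference fits
  demonstrably used it;
- celecoxib's activity-series pIC50 (8.4390) conflicts with the
  validation table's observed value (9.2839, consistent with IC50
  0.52 nM); the validation fixture stores 9.2839 as observed.

Descriptor counts for the validation molecules are not printed
anywhere; they were reconstructed uniquely from the four published
equations (the mono equation pins ATM, bi pins ACC, tri pins DONN,
tetra pins ARO) and verified to reproduce all 48 published predictions
exactly; the fixture rows are flagged as reconstructed.

## Screening filters

Tanimoto similarity uses the strict inequality "greater than cutoff"
(default 0.35; 0.3 is the documented alternative cut used earlier in
the source workflow). An all-zero/all-zero pair returns 0 with a
warning instead of NaN so batch filtering stays total. RMSD is the
paired-distance formula with no superposition or atom matching — pose
alignment belongs to docking software, so inputs must arrive
index-paired. Rule-of-five bounds are inclusive (MW = 500 is not a
violation). Fingerprint generation from structures is deliberately
absent; fingerprints arrive as bitstring text, keeping the core free of
chemistry dependencies. The published screening hit counts
(1451/491/58) depend on an external candidate pool and are not
reproducible here.

## Energetics conventions

ΔG = −RT ln K_i as printed yields *positive* energies for sub-molar
K_i, which conflicts with the negative docking energies reported
alongside it; both the printed and the standard thermodynamic sign
(+RT ln K_i) are implemented behind a mode flag, defaulting to
as-printed for fidelity. The entropy term −TΔS defaults to 0 when
absent and its absence is flagged. The trajectory-derived MM-GBSA
binding energies (−48.15 kcal/mol etc.) require 100 ns simulations and
are shipped only as a reference table, never recomputed.

## Synthetic data

The generator emulates the statistical structure of the reference
training table: descriptor counts uniform on its empirical ranges
(ATM 29–50, ARO 1–4, DONN 0–3, ACC 2–5), pIC50 from the published
four-descriptor equation plus Gaussian noise, IC50 back-computed as
10^(9−pIC50) nM. Defaults are n = 20 and noise_sd = 0.22 pIC50 units
(the residual scale of the reference fit); under these conditions the
mean fitted R² across replicates (~0.94) brackets the reference R²
0.925. All generators take an explicit integer seed into a dedicated
`numpy.random.default_rng`; no global random state is touched, and
identical specs produce bit-identical output.

What passing synthetic tests shows — and does not: the generator is
exactly the model the regression assumes (uniform integer descriptors,
additive homoscedastic Gaussian noise, no descriptor correlation
structure), so recovery tests validate the fitting machinery, not the
adequacy of linear QSAR for real chemistry. Real descriptor sets are
correlated (e.g. ATM–ARO ≈ 0.57 in the reference data), activities are
heteroscedastic across potency ranges, and molecules are not i.i.d.

## Problem sizes and determinism

Every bundled computation is desk-scale: the largest fit is 20×5, the
benchmark driver runs 400 replicate fits, and the distributional checks
use at most 10⁴ atoms/bits; the entire suite and the acceptance script
each run in seconds. Reports are byte-identical across reruns with the
same config; timestamps appear only in logs.

## Limitations

- The fixed internal/external split is reproduced verbatim; the rule by
  which the source assigned molecules 21–25 to internal validation is
  not stated, and no alternative cross-validation is offered.
- No regularisation; with 4 descriptors and n = 20 the exhaustive OLS
  enumeration is exact, but the approach does not scale to large
  descriptor sets.
- Tanimoto values depend on the (unstated) fingerprint type of the
  original similarity server; no attempt is made to reproduce any
  specific published similarity value.
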