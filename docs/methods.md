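# Methods

This document records the statistical model, the estimation algorithm, and
the design choices behind the simulator and the power harness.

## 1. Model

For `n` individuals and `d` variates, phenotypes are stacked variate-major
(record `j·n + i` is variate `j` of individual `i`):

```
y = X_m B_m + u + e
u ~ N(0, Σu ⊗ A)        A: n × n genomic relationship matrix
e ~ N(0, Σe ⊗ I_n)      Σu, Σe: d × d covariance matrices
```

The fixed-effect design is block diagonal, `X_m = I_d ⊗ X`, so each variate
gets its own intercept and SNP-dosage coefficient.  With missing phenotype
cells, the rows/columns of unobserved records are deleted from every stacked
quantity; `build_Vm` assembles the observed-record covariance

```
V_m[rs] = Σu[v_r, v_s] · A[i_r, i_s] + Σe[v_r, v_s] · 1{i_r = i_s}
```

where `v` and `i` are the variate and individual of each observed record.
A structural consequence asserted exactly in the tests: at maximal
missingness (every individual observed on exactly one variate) no pair of
records shares an individual off the diagonal, so the residual part of
`V_m` reduces to per-record variances and the residual correlations drop
out of the model entirely.

## 2. F-test

For a SNP with contrast matrix `H` (selecting its `d` dosage coefficients),

```
F = (H'B̂)' [H' (X_m' V_m⁻¹ X_m)⁻¹ H]⁻¹ (H'B̂) / (f · σ̂²)
```

with `B̂` the GLS estimate, `f = rank(H)` the numerator degrees of freedom,
and denominator degrees of freedom `N_obs − p_total`.  Because `V_m` is the
full phenotypic covariance (not a correlation structure to be scaled), the
residual scale `σ̂²` is fixed at 1 by default; a computed quadratic-form
scale can be supplied, and with `V = I` and a single contrast the statistic
then reduces exactly to the squared OLS t statistic (tested).

Under the null model's variance components (P3D: the components are
estimated once without any SNP and reused for every marker), the per-SNP
cost is one cached Cholesky solve, ~1 ms per SNP at `n = 200`, `d = 2`.
An exact mode refits REML per SNP behind a config flag.  Monomorphic
dosages on the analysed samples yield an NA row and the scan continues; a
non-convergent null fit aborts the scan, and the replicate-grid harness
drops and counts such replicates.

For `d = 2`, `A = I`, per-record covariance `[[1, r], [r, 1]]`, and a
second effect equal to `a₂` times the first, the numerator collapses to the
closed form

```
numerator = B̂₁² · (x'x) · f(a₂, r),    f(a₂, r) = (a₂² − 2a₂r + 1)/(1 − r²)
```

implemented in the `analytic` module and verified to 1e−8 on constructed
fixtures.  `f` predicts when the multivariate test gains power: `f = 1` at
`a₂ = r` (its minimum in `a₂`), large when effect signs oppose the residual
correlation, and divergent as `|r| → 1`.

## 3. EM-REML

Variance components are estimated by classical EM-REML on the observed
records.  Each EM step computes the GLS solution, the BLUP-style
conditional moments of `u` and `e`, and updates

```
Σu ← Σu + Σu (W'AW − Qu) Σu / n,    Σe ← (analogous residual moment) / n
```

entirely without `A⁻¹`.  Two algebraically identical evaluations exist:

- **direct**: builds the `N_obs × N_obs` covariance each step (any
  missingness pattern);
- **rotated**: for complete records, rotates into the eigenbasis of `A`,
  where the model factorises over individuals and one step costs
  `O(n d³)`.  The two paths agree to ~1e−10 and the rotated path is
  dispatched automatically for complete data.

Phenotypes are standardised per variate internally (estimates and the
likelihood path are mapped back), initialisation puts half of each sample
variance on each component, and convergence is declared when a plain EM
update moves no component by more than `1e−6` (standardised scale), with a
cap of 5000 outer EM iterations (the acceleration scheme's internal
stabilisation and backtracking evaluations are not charged against the cap,
so acceleration can never leave a fit with a smaller effective budget than
plain EM).

### Acceleration

Plain EM on this likelihood is slow near the `Σu ≈ 0` boundary (thousands
of iterations).  The driver wraps EM in a guarded SQUAREM scheme: after the
plain increments fall below `1e−3`, it forms the usual quadratic
extrapolation from three EM iterates, stabilises the candidate with one EM
step, and accepts the subsequent EM image only if the stabilised point's
restricted log-likelihood is at least the plain iterate's; otherwise the
step length is halved toward plain EM (up to 6 backtracks).  Candidates
whose covariances leave the PSD cone are backtracked rather than projected.
The warm-up and the likelihood guard exist because unguarded jumps launched
far from the optimum were observed to settle on inferior stationary points,
and accepting projected candidates pinned later updates to the projection
floor.  The recorded likelihood path remains monotone (asserted in tests),
and the accelerated fixed point is a fixed point of plain EM.

Non-convergence is reported honestly (`converged = False`) when the cap is
hit, three consecutive updates require PSD projection, or a candidate
covariance turns singular.  Null fits at heavy missingness sit on the
`Σu ≈ 0` boundary (the relationship matrix is built from non-QTL SNPs and
tags the causal loci only weakly) and routinely exhaust the cap; the power
harness drops and counts those replicates rather than masking them.

## 4. Genomic relationship matrix

VanRaden method 1 over polymorphic SNPs:

```
A = (M − 2p)(M − 2p)' / (2 Σ_k p_k (1 − p_k))
```

with `p_k` the counted-allele frequency.  The estimate is clipped to the
PSD cone at eigenvalue `1e−8` before use.  Monomorphic SNPs contribute
nothing (tested), and MAF pruning at 0.02 precedes all analyses.

## 5. Simulator

- **Genotypes**: fully inbred lines (dosages {0, 2}) built as recombinant
  mosaics of 24 founder haplotypes per chromosome (founder mutation rate
  0.10, per-SNP switch probability 0.02), giving within-chromosome LD that
  decays with distance and independence across chromosomes (tested).
  Default panel: 200 individuals, 5 chromosomes × 2000 SNPs.
- **QTLs**: 4 per chromosome (20 total), one designated target.  Target
  effects on the `d` variates follow the evenly spaced schedule
  `a_j = linspace(1, a_d, d)` scaled by one standard-normal draw;
  background-QTL effect rows are i.i.d. `MVN(0, Σ)` with `Σ` the
  compound-symmetry correlation matrix with off-diagonal `r`.
- **Phenotypes**: `y = u + e` with `u` the dosage-weighted QTL effects and
  `e ~ MVN(0, S Σ S)` where `S` is the diagonal of realized genetic
  standard deviations — each variate's heritability is ~0.5 by
  construction (acceptance target).  With no QTLs, `S = I` and phenotypes
  are pure correlated noise.
- **Missingness**: exactly `round(m · n · d)` cells are masked; one
  randomly reserved cell per individual is never masked, so the
  bound `m ≤ (d − 1)/d` is attainable and at the maximum every individual
  keeps exactly one variate.
- **Seeds**: a splitmix64-style stream derives per-replicate,
  per-component seeds below 2³¹ from one master seed, so any single
  replicate can be regenerated in isolation.

## 6. Power harness

For each scenario `(d, r, a_d, m_prop)` the harness simulates replicates,
builds the relationship matrix from the non-QTL SNPs, fits the null model,
and records the difference of −log₁₀ p between the multivariate test and
the univariate test on variate 1 at the target QTL.  Scenario means,
success/failure counts and per-replicate deltas go into a long-format grid
table (no interpolation of untested cells).  Negative-SNP QQ diagnostics
take the SNPs on the target chromosome with `r² < 0.1` against every QTL
and compare observed −log₁₀ p against uniform order statistics; the
regression slope is the no-inflation summary.

## 7. Desk-scale choices and limitations

- Replicate counts default to 20 (not 100); acceptance asserts sign-level
  agreement with the `f(a₂, r)` prediction on a reduced 3 × 3 grid, not
  full-surface fidelity.
- The maximal-missingness range property (gain driven by `a_d`, not `r`)
  is evaluated with the replicates' true variance components, because at
  `m = (d−1)/d` the null REML fits mostly hit the iteration cap (see
  §3); the REML-driven pipeline is exercised everywhere else.
- `d > 2` is interpreted through the `d = 2` surface; no closed form is
  derived for higher `d`.
- No family-wise significance thresholds: comparisons are on −log₁₀ p
  directly.
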