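# Methods

This note documents the models, the numerical choices, and the synthetic data
design behind `tensormda`, including the places where the design was genuinely
open and a choice had to be made.

## Discriminant model

Trials are real J₁ × J₂ matrices X₁, …, X_N with class labels y_n ∈ {0, …, C−1}
(classification downstream is binary, but the scatter machinery is
class-count generic). With per-class means X̄_c and global mean X̄, the
vectorised scatter matrices are

    W = Σ_c Σ_{n∈c} vec(X_n − X̄_c) vec(X_n − X̄_c)ᵀ
    B = Σ_c N_c vec(X̄_c − X̄) vec(X̄_c − X̄)ᵀ,

with column-major `vec` throughout; mode-p matricisation orders the remaining
modes ascending with the lowest varying fastest, so that `U⁽²⁾ ⊗ U⁽¹⁾`
pairs with `vec` ((U⁽²⁾⊗U⁽¹⁾)ᵀ vec X = vec(U⁽¹⁾ᵀ X U⁽²⁾)). The joint
projection is `U_s = U⁽²⁾ ⊗ U⁽¹⁾` (Tucker) or `U⁽²⁾ ⊙ U⁽¹⁾` (PARAFAC,
Khatri–Rao), and the two objectives maximised over per-mode orthonormal
factors are the scatter ratio Tr(U_sᵀBU_s)/Tr(U_sᵀWU_s) and the trace of
matrix ratio Tr((U_sᵀWU_s)⁻¹U_sᵀBU_s).

All objective and gradient evaluations go through per-observation projected
cores (cost O(N·J₁·J₂·K) per evaluation); the (J₁J₂)² vectorised scatter is
only ever formed for small problems (J₁J₂ ≤ 4096 by default), because at
realistic trial sizes it is both too large and unnecessary.

### Gradients

The objectives' Euclidean gradients are derived by writing each as a function
of the projected deviation vectors y_m (the vectorised core of a within- or
between-deviation matrix under Tucker, its diagonal under PARAFAC). For a
symmetric matrix S, perturbing Σ_m y_m y_mᵀ inside a trace contracts to
per-mode terms 2 A_m U⁽²⁾ Z_mᵀ and 2 A_mᵀ U⁽¹⁾ Z_m with Z_m = unvec(S y_m)
(Tucker) or Diag(S y_m) (PARAFAC). The scatter ratio uses S = I/Tr(M) and
S = f/Tr(M)·I on the between/within parts; the trace ratio uses S = M⁻¹ and
S = M⁻¹NM⁻¹ with M = U_sᵀWU_s, N = U_sᵀBU_s. Correctness is owned by the
finite-difference tests (20 random instances, all four structure × criterion
combinations, relative error ≤ 1e−5; observed ~5e−10).

### Riemannian optimisation

The constraint set is the cross-product of two Stiefel manifolds. The fitter
is a conjugate-gradient ascent built from:

- tangent projection Ξ = G − U·sym(UᵀG);
- QR retraction with sign-fixed positive R diagonal;
- Polak–Ribière⁺ directions with projection transport (β clipped at 0, reset
  to steepest ascent whenever the direction loses positive slope);
- Armijo backtracking (c₁ = 1e−4, halving, accepted step doubled as the next
  initial step). A step is accepted only if the objective does not decrease,
  so the recorded objective trace is non-decreasing by construction — the
  property the alternating heuristics lack.

Convergence: Riemannian gradient norm < 1e−6·max(1, |f|), or relative
objective change < 1e−10 over 5 consecutive iterations, capped at 5000
iterations. Three restarts from random orthonormal (QR of Gaussian)
initialisations by default; best final objective wins, ties to the lowest
restart index; a warm start from supplied factors (e.g. a CMDA solution) is
available. The choice of CG variant and line search was open; any monotone CG
satisfying the tangent/retraction contracts would do, and Polak–Ribière⁺ with
projection transport is the standard robust default.

The trace-ratio inversion adds a ridge (explicit `ridge`, or automatically
1e−10·Tr(M)/dim) only when the condition number of the projected
within-scatter exceeds 1e12 — small-N projected scatters can be singular. The
ridge is deliberately conditional: an unconditional ridge would be invisible
in well-posed problems anyway, and the conditional form keeps the dense-oracle
equivalence exact.

## Heuristic baselines

CMDA, DATER and DATEReig alternate single-mode updates using the
mode-projected scatter pair (computed per observation, never via the dense
scatter): CMDA takes leading left singular vectors of W⁻¹B, DATER leading
generalised eigenvectors of (B, W) (hence W-orthogonal factors), DATEReig
leading eigenvectors of W⁻¹B, real parts taken and re-orthonormalised with a
warning if a complex pair appears. Three numerical choices matter:

- **Spectral floor.** In the N < J₁J₂ regime the projected within-scatter is
  rank-deficient; all W-inversions use an eigenvalue floor at 1e−10 of the top
  eigenvalue (a pseudo-inverse-like ridge). Objective values recorded along
  the iteration floor the scatter-ratio denominator at 1e−14 of the total
  within energy rather than raising, because the heuristics can legitimately
  visit near-null projected directions where the empirical ratio diverges.
- **DATER column normalisation.** W-orthonormal eigenvectors (vᵀWv = 1) have
  wildly different column scales; columns are rescaled to unit Euclidean norm
  after each update. Diagonality of UᵀWU is unaffected; conditioning of the
  subsequent other-mode projection is restored.
- **Best-iterate return.** The scatter ratio typically rises fast, peaks and
  then declines under these updates ("sawtooth"); the factors at the best
  recorded value are returned, not the last ones. A consequence: the returned
  pair is generally not a fixed point, so DATER's W-orthogonality holds for
  the update that produced each factor, not jointly for the returned pair.
- **Convergence** is declared when every mode's subspace projector UUᵀ moves
  less than tol·√(J_p·K_p) (default tol 1e−6) in one sweep; raw factor
  differences would never converge due to eigenvector sign/rotation
  indeterminacy. One trace entry = one single-mode update.

When heuristic solutions are compared against the manifold optimiser on the
scatter-ratio objective, each heuristic's subspace is first re-expressed with
an orthonormal basis (QR; a no-op for CMDA and DATEReig). DATER's
W-orthogonal factors carry arbitrary column scalings, and a non-orthogonal
basis — in the extreme, columns piling onto the single best discriminant
direction — can exceed *any* value attainable under the orthonormality
constraint, so comparing raw DATER values against Stiefel-constrained optima
would conflate feasible sets.

DGTDA is a deterministic single pass: per mode, ζ = largest singular value of
W₍p₎⁻¹B₍p₎, then U⁽ᵖ⁾ = top-K eigenvectors of B₍p₎ − ζW₍p₎ by descending
algebraic eigenvalue. Since that matrix is negative semidefinite,
magnitude-ordered singular vectors would select the *least* discriminative
directions; the eigenvalue ordering implements the intended maximisation of
Tr(Uᵀ(B − ζW)U).

## Bilinear logistic regression

BDCA scores a trial by w₀ + Tr(U⁽¹⁾ᵀXU⁽²⁾) (equal K in both modes, no
orthogonality constraints — the model is invariant under U⁽¹⁾→U⁽¹⁾Q⁽¹⁾,
U⁽²⁾→U⁽²⁾Q⁽²⁾ with Q⁽²⁾Q⁽¹⁾ᵀ = I). BDCA_Tucker adds an interaction matrix V
with unit diagonal to remove the scale ambiguity between V and the factors.
The Bernoulli log-likelihood is evaluated with `logaddexp` (no overflow) and
maximised by BFGS with analytic gradients; off-diagonal V entries start at 0
(so a Tucker fit with off-diagonals frozen reproduces the PARAFAC fit),
factors at i.i.d. N(0, init_std²) with init_std = 0.01 by default and a
smaller preset (1e−5) for ill-scaled data. Multiple restarts, best
log-likelihood kept. No regularisation by default; an L2 hook exists but is
off.

## Classification and evaluation

Downstream classification is unregularised maximum-likelihood logistic
regression (Newton/IRLS with step-halving). Under perfect separation the ML
optimum is at infinity; the fit stops with a warning once every training
trial is scored past saturation (|η| > 30) or the coefficient norm passes a
cap — rankings, hence AUC, are unaffected. AUC is the rank-based
Mann–Whitney statistic with ties counted ½. Cross-validation is stratified
k-fold (seeded) or leave-one-group-out; extractor and classifier see training
folds only, and train-fold AUC is reported alongside for overfitting
inspection. Features are not standardised before the logistic fit (a flag
enables it). The vectorised-LDA baseline computes w ∝ W⁺(vec X̄₁ − vec X̄₀)
via a minimum-norm solve, so it runs (and overfits, by design of the
comparison) in the singular N < J₁J₂ regime.

## Synthetic data

Each replicate draws: a shared base core G ~ N(0,1)^{K×K} and a difference
core Δ ~ N(0,1)^{K×K}; class cores G_c = G ± (s/2)Δ with s the signal scale
(levels low/medium/high → 0.5/1/2, or an explicit `signal_scale`, 0 giving a
null-signal control); orthonormalised Gaussian mode components U₁ (J₁×K),
U₂ (J₂×K) and independent noise components V₁, V₂. A trial of class c is

    X = U₁ (G_c + E) U₂ᵀ + V₁ H V₂ᵀ + S,

with E, H i.i.d. normal cores (sd 1 each by default) and S an i.i.d.
sensor-noise floor (sd 1 by default). Defaults: 10 × 80 trials, K = 3,
balanced classes, train and test drawn from distinct RNG streams of the same
truth.

The sensor-noise floor deserves its rationale: with only core and structured
noise, every trial lies in a ~2K-dimensional subspace per mode, vectorised
LDA never encounters the singular regime that motivates multilinear methods,
and it empirically matches or beats them. Real recordings always carry
broadband measurement noise, and with the floor at sd 1.0 the medium signal
level produces non-saturated held-out AUC (~0.65–0.88 over 50–200 training
trials per class) with the supervised tensor methods above vectorised LDA —
the regime of interest. The floor sd was fixed once from a coarse scan (0.5
leaves LDA unharmed, 2.0 pushes medium signal toward chance) and not
revisited.

What the generator does **not** emulate: temporal autocorrelation and 1/f
spectra, inter-channel correlation beyond the planted components, artifacts,
class imbalance, non-stationarity. Passing tests therefore demonstrate
correctness of the estimators and the qualitative regime (structured signal +
broadband noise + limited trials), not performance on real recordings.

Problem sizes in the test suite and acceptance script — e.g. 20 simulated
instances with 50 training trials per class for the objective-dominance
check, and 10 replicates × {50, 100, 200} trials per class for the simulation
study — are the package's chosen desk-scale study conditions; iteration caps
of 500–2000 with the convergence tests above are ample at these sizes (the
optimisers typically converge in a few hundred steps).

## Visualisation

Projection factors are filters; for interpretation they are converted to
patterns by pre-multiplying the mode covariance of the trial-mean-centred
data: pattern = Σ_p · U (training data only, to avoid test leakage; plain
centring, no baseline correction). Pattern columns are unit-normalised with
the largest-magnitude entry made positive, since filters are scale- and
sign-ambiguous across methods. Patterns are only defined for PARAFAC models
and one-component Tucker models — multi-component Tucker factors are
rotationally ambiguous, so their individual columns carry no identity.

## Known limitations

- Only matrix (order-2) observations are supported end to end; the mode
  machinery is generic but untested beyond matrices.
- First-order manifold optimisation only; no trust-region or second-order
  solvers.
- The trace-ratio objective overfits aggressively when N ≲ J₁J₂ (its empirical
  optimum exploits near-null within-scatter directions); this is faithful to
  the method, not a defect of the optimiser, and is why the simulation study
  reports held-out rather than training AUC.
- Degenerate inputs (constant datasets, single-class data) raise; they do not
  return 0/0.
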