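# Methods

## Model and assumptions

The library estimates class-conditional probability mass functions on the
binary hypercube {0,1}^L by the Parzen-window method with the
Aitchison–Aitken kernel

K(x, xᵢ; λ) = λ^L ((1−λ)/λ)^{d(x,xᵢ)},  0.5 < λ < 1,

and classifies by maximal Bayes posterior. The kernel is a proper
probability mass function in x for every center xᵢ (the binomial identity
Σ_d C(L,d) λ^{L−d}(1−λ)^d = 1), so the Parzen estimate — a mean of kernels —
is automatically normalized; the test suite verifies this by exhaustive
enumeration up to L = 12. All misclassification costs are treated as equal;
exact posterior ties break to the lexicographically smallest class label (a
documented convention — the decision rule itself says nothing about ties).

## The compressed form and its fidelity

With α = ln(λ/(1−λ)) and βᵢ = e^{−α·popcount(xᵢ)}, the per-class statistics
a = Σβᵢ, z = Σxᵢ, z′ = Σβᵢxᵢ, Q = Σβᵢxᵢxᵢᵀ are accumulated in one pass and
the prototypes discarded. The density is evaluated as

p̂(x|ω) = B [ a + 2α(x·z′) + g(μ)(xᵀQx) ],  μ = 2α(x·z),

with g(μ) = 4α²(e^μ−μ−1)/μ² summing the series tail r ≥ 2.

The choice Q = Σβᵢxᵢxᵢᵀ is the unique symmetric one-pass accumulator that
(i) reproduces the second-order series term Σβᵢ(x·xᵢ)² exactly via xᵀQx,
(ii) makes the whole expression an algebraic identity for a
single-prototype class, and (iii) is an L×L matrix as the representation
requires. For N_ω > 1 the collapse of Σᵢβᵢ(x·xᵢ)^r onto (xᵀQx)(x·z)^{r−2}
is **an approximation, not an identity**: because z sums the prototypes,
the r-th tail term is inflated by up to N_ω^{r−2} (the extreme case being
N_ω identical prototypes). Consequently the compressed density
*overestimates* the exact one, often by orders of magnitude for large,
dense classes, while the r = 0, 1 terms remain exact for any N_ω. The
library does not attempt to repair or renormalize this; instead
`compression_error_report` measures it — per query and per class — against
the brute-force estimator, and reports Bayes-decision agreement, which is
the operationally relevant quantity. On the separable synthetic benchmark
the two backends agree on every test decision even where the density ratio
is astronomically large, because the inflation grows with x·z and therefore
favors the class the exact estimator already prefers; on less separated
data agreement must be checked per application with the report.

## Parameters

- **λ (smoothing)** — dimensionless, open interval (0.5, 1); default 0.75
  in the CLI (the midpoint emphasis; there is no canonical default).
  λ → 0.5 flattens the kernel toward uniform, λ → 1 sharpens it toward a
  delta; both endpoints are rejected because α = ln(λ/(1−λ)) degenerates.
  Summaries are λ-specific (βᵢ depends on α) and evaluation with a
  different λ is a hard error rather than a silent misestimate.
- **prior mode** — `empirical` (class frequency N_ω/N) or `uniform` (1/J);
  default uniform.
- **r_max (truncated backend only)** — series order, default 60; see the
  truncation analysis below.

## Numerical policies

- **Log domain everywhere it matters.** λ^L underflows linear doubles
  around L ≈ 2000 (λ = 0.75) and much earlier for smaller λ; all three
  backends expose log densities, and posteriors are normalized by
  log-sum-exp (max subtraction). If every class-conditional is −∞ the
  library raises a dedicated `EvidenceUnderflowError` rather than dividing
  by zero.
- **Tail factor g(μ) in three regimes.** For μ < 10⁻⁴ the closed form
  cancels catastrophically and the Taylor form 2α²(1 + μ/3 + μ²/12) is used
  (truncation error ∼ μ³/60 < 10⁻¹³ relative); for moderate μ, expm1-based
  evaluation; for μ ≥ 40 the log-scale asymptote
  log g = log 4α² + μ − 2 log μ is exact to double precision (the dropped
  correction (μ+1)e^{−μ} is below 2·10⁻¹⁶), and the linear-scale function
  returns inf beyond μ ≈ 700 where e^μ is unrepresentable. μ = 2α(x·z)
  grows with class size, so the compressed backend always uses the log
  route.
- **Series truncation.** The order-60 truncation of e^{2αt} has relative
  remainder ≈ μ⁶¹/61! at μ = 2αt: about 10⁻¹³ at μ = 20, 2·10⁻¹⁰ at
  μ = 24, and 10⁻³ at μ = 40. The truncated backend therefore matches the
  exact one to 10⁻¹⁰ only while the largest pattern overlap keeps
  2α(x·xᵢ) ≲ 24; for half-dense random 16-bit patterns at λ = 0.75 the
  realized maxima sit near that boundary, which is why the measured
  order-60 error hovers around 10⁻¹⁰–10⁻¹².
- **Summation.** Kernel sums are evaluated with vectorized numpy reductions
  (pairwise summation), making densities invariant to prototype order to
  ≈10⁻¹² relative.
- **Ties and degenerate inputs.** Empty prototype sets, non-binary entries,
  ragged files and λ outside (0.5, 1) are rejected with specific errors;
  the all-zero query exercises the μ = 0 limit g(0) = 2α² exactly.

## Synthetic data

The generator draws each bit of a class-j pattern independently as
Bernoulli(p_{j,l}) from a per-class probability profile, with one seeded
`numpy` Generator per call: identical configs give bit-identical datasets.
Presets: `disjoint-blocks` (each class dense at `block_density`, default
0.9, on its own contiguous L/J block, 0.01 elsewhere — a separable
benchmark on which the classifier must score ≥ 95%), `overlapping`
(half-block overlap between adjacent classes), and `iid-uniform` (a null
benchmark with indistinguishable classes). The default benchmark size used
throughout the tests and the acceptance script — two classes, L = 64, 100
training and 100 test patterns per class, λ = 0.75 — is large enough for
stable accuracy estimates yet runs in seconds.

What the generator does *not* emulate: within-pattern bit correlation
(substructure co-occurrence), scaffold/cluster structure, and the heavy
sparsity skew of real molecular fingerprints. Passing tests therefore
demonstrate the estimator mechanics — normalization, identities, series
convergence, backend agreement under separation — not classification
performance on real chemistry data.

## Model persistence

A versioned JSON container (`magic`, `version`, L, λ, prior mode, priors,
and per class N_ω, a, z, z′, and the upper triangle of Q as triplets).
Integers round-trip bit-exactly; reals at full double precision. A corrupt
or truncated file raises an integrity error, an unknown version a
dedicated unsupported-version error. Round-tripping changes no log density
by more than 10⁻¹² (measured, and typically 0).

## Design choices made where the design was open

- The general factorizable kernel family (arbitrary A, f, ρ) is not
  abstracted over; only the AA instance is implemented, and the continuous
  (Gaussian) analogue is out of scope.
- The 0/1 class-membership indicator is never materialized; membership is
  an index list per class.
- Q is stored as a scipy CSR matrix and serialized as its upper triangle;
  with bit density p the expected nonzero count scales as O((pL)²).
- Incremental fitting is supported because all four statistics are linear
  in the prototype set (`ClassSummary.__add__`).
- The CLI defaults to the compressed backend and logs a note when a class
  has a single prototype (where compression is exact).

## Known limitations

- The compressed tail overestimates multi-prototype class densities (see
  fidelity section); absolute density values from the compressed backend
  should not be interpreted quantitatively — use the exact or truncated
  backend, or check `compression_error_report`, when densities themselves
  matter.
- The truncated backend is a validation oracle, not a fast path: it needs
  the prototypes and O(r_max · N_ω) work per query.
- No bit-correlation model in the generator, no cost-sensitive decision
  rule, no fingerprint generation from molecular structures (precomputed
  fingerprints are the input).
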