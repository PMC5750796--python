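# Methods

## Model and assumptions

The classifier treats each class as locally linear in spectral space: a
query is compared not to individual training spectra but to the affine
hull ("local hyperplane") of its k nearest same-class spectra, which
interpolates between prototypes and so fills in the gaps of a sparse
training set. Two assumptions follow. First, classes must be locally
well approximated by low-dimensional affine patches — reasonable for
absorbance spectra, which vary smoothly with composition. Second, the
informativeness of a wavenumber channel is taken to be measurable from
the *unlabeled* training matrix alone: the entropy weight
`w_j ∝ 1 − H_j` rewards channels whose values are spread unevenly
across samples. This is an unsupervised proxy for class separation; a
channel can in principle be high-variance for reasons unrelated to
class (a failure mode noted under Limitations).

The ridge term `λ αᵀα` keeps the hyperplane coefficients small, which
matters when k approaches the intrinsic dimension of a class patch and
the affine hull would otherwise extrapolate far beyond the prototypes.
At `λ → ∞` the score degenerates to the weighted distance to the
prototype centroid; at `k = 1` it reduces to per-class weighted 1-NN.

## Entropy weights on signed data

The share normalization `z_ij = x_ij / Σ_i x_ij` requires nonnegative
entries, but SNV output is signed. Columns containing any value ≤ 0 are
shifted by `−min + ε` (with `ε = 10⁻¹² ×` column range, or `10⁻¹²` for a
constant column) before the entropy is computed; strictly positive
columns are used as-is, so the weight formula is applied verbatim
wherever it is well defined. The shift preserves within-column ordering
and spread — the only properties the entropy responds to. `0 ln 0 := 0`;
entropies are clipped at 1 to absorb floating-point overshoot. If every
channel attains maximal entropy (e.g. a constant matrix) the weight
denominator vanishes and the weights fall back to uniform with a
warning.

## Numerical choices

- The hyperplane coefficients solve the k×k system
  `(VᵀWV + λI) α = VᵀW(q − m_c)` directly (`numpy.linalg.solve` for
  λ > 0, where the matrix is positive definite). At λ = 0 a singular
  system is resolved by minimum-norm least squares; every minimizer
  yields the same J_c, so the choice only pins down α. The closed-form
  solve is validated in the test suite against derivative-based numeric
  minimization of the objective on hundreds of random instances
  (relative tolerance 10⁻⁶).
- Neighbor ties break toward the lower training-row index (stable
  argsort); class-score ties toward the lexicographically smaller
  label. Both rules exist purely for determinism.
- J_c is clipped at 0 to absorb negative floating-point dust.
- Savitzky–Golay boundaries use polynomial evaluation on the first/last
  full window (`mode="interp"`), never mirroring, so polynomials up to
  the filter order pass through exactly and the filter is deterministic
  and documented at the edges.
- SNV uses the n−1 (sample) standard deviation. A flat region segment
  is an error naming the offending sample, not a silent NaN.
- CSV I/O renders floats with `%.17g` and parses with round-trip
  precision, so write→read is the identity on float64 data.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 5 | prototypes per class; clipped to the class size. Small k keeps the hyperplane local. |
| `lam` (λ) | 1.0 | ridge strength in absorbance² units of the weighted metric; 0 disables regularization. No canonical value exists for this method, so it is explicit configuration. |
| `sg_window` | 5 | smoothing window in points (the standard light-smoothing choice). |
| `sg_polyorder` | 2 | quadratic local fit; the usual order for a 5-point window. |
| `snv_regions` | 1000–1800, 2800–3800 cm⁻¹ | informative FTIR regions; the 1800–2800 cm⁻¹ window has no bio-molecular bands. |
| `positive_label` | `"cancer"` | sensitivity means cancer detection. |

## The synthetic generator

Each spectrum is `scatter × (Σ Gaussian bands + linear baseline) +
white noise`, with per-sample band-amplitude jitter (coefficient of
variation `amp_cv`). The band table places Gaussians at the wavenumbers
where colorectal tissue absorbs (1080, 1160, 1240, 1310, 1400, 1460,
1550, 1643, 1743, 2858, 2924, 2958, 3300 cm⁻¹) and encodes the known
directional contrasts between cancerous and inflamed tissue: lipid
bands (1743, 2858–2958) suppressed in cancer, the 1080 cm⁻¹
nucleic-acid band elevated, the 1160 cm⁻¹ carbohydrate band reduced,
1240 and 1310 weaker in colitis, the 1460-vs-1400 intensity ordering
flipped between classes, and the amide-II/amide-I ratio lower in
cancer. The 1400 and 1550 bands are class-neutral in amplitude: their
documented contrasts are *relative* (the ordering flip and the amide
ratio respectively), and giving them small absolute cross-class
differences as well would make those differences statistically
invisible at realistic sample sizes while complicating the generator's
directional contract.

Band magnitudes are engineering values — the literature reports
directions, not intensities. Defaults (`amp_cv = 0.40`,
`noise_sd = 0.02`, lognormal scatter sd 0.15, baseline slope sd
3×10⁻⁵ /cm⁻¹, intercept sd 0.05) were chosen so the two classes are
separable but not trivially so: held-out EWHK accuracy lands in the
85–95 % range at the default 44-per-class size, which keeps classifier
comparisons meaningful.

What the generator does **not** emulate: ATR penetration-depth physics,
water-vapor/CO₂ interference lines, Mie scattering, correlated noise,
instrument drift between sessions, or biological covariates (age, sex,
biopsy site). Passing tests on synthetic data therefore demonstrate
algorithmic correctness and the claimed qualitative behaviors — not
clinical performance on real tissue spectra.

## Evaluation protocol

Stratified random splits at fixed per-class training counts, without
replacement, deterministic per seed; five repeats by default with seeds
1…5. Averaged metrics are the arithmetic mean of per-split metrics.
The pooled-count alternative (metrics of the summed confusion matrix)
is computed and reported separately under the `pooled` label: the two
conventions genuinely differ whenever split compositions differ, and
published summaries do not always say which was used, so the package
reports both rather than adjudicating. The SVM baseline is
scikit-learn's `SVC(kernel="linear", C=1.0)` — a documented fixed
choice for comparison, not a tuned competitor.

## Design choices where the design was open

- **Library-first shape.** The public face is the importable API plus
  `examples/`; the CLI is a thin argparse layer because the pipeline is
  also genuinely useful as a shell tool.
- **Entropy weights are computed once on the full concatenated-region
  training matrix**, not per region: the weight formula is defined over
  all n features and no per-region weighting is described anywhere.
- **Uniform mode uses w_j ≡ 1 exactly** (plain Euclidean), reproducing
  classical HKNN. Rescaling uniform weights to 1/n would leave the
  argmin unchanged at λ = 0 but is equivalent to rescaling λ otherwise.
- **β = 1/ln m is a normalization constant**, not a free parameter: it
  maps entropies into [0, 1].
- **Problem sizes** in the test suite and acceptance script (88-spectrum
  datasets, 10 evaluation seeds, 200 random oracle instances) are chosen
  to exercise the method at the scale of a realistic biopsy study while
  keeping the whole suite interactive (seconds, not minutes).

## Known limitations

- The entropy weight is unsupervised; a nuisance channel with high
  cross-sample dispersion (comparable to the class-separating bands
  after SNV) receives high weight. The advantage over HKNN on
  noise-contaminated data is an average tendency, not a guarantee.
- Binary classification with a single positive class; multi-class input
  is accepted by the classifier but the evaluation metrics assume
  one-vs-rest binary framing.
- All spectra in one analysis must share a wavenumber grid; no
  interpolation between grids, and no instrument formats (JCAMP-DX/SPC)
  — plain CSV only.
- No baseline-correction beyond what SNV removes (offset and scale);
  nonlinear baselines will leak into the normalized spectra.
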