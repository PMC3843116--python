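# Methods

This note documents the model, the numerical choices and the validation
strategy of `lamellae` in the package's own terms.

## Notation and tensor algebra

All fourth-order stiffness tensors are stored as 6×6 matrices in the
**orthonormal Mandel basis** (component order 11, 22, 33, 23, 13, 12; rows
and columns 4–6 scaled by √2 relative to Voigt). In this basis matrix
inversion, products and congruence transforms coincide exactly with the
corresponding tensor operations, so the Eshelby/Mori–Tanaka algebra needs no
factor-of-two bookkeeping. Voigt matrices appear only at I/O boundaries
(`to_voigt`, CSV files). Rotations act through the 6×6 orthogonal operator
induced by R⊗R⊗R⊗R; transverse isotropy is verified numerically by rotating
about the candidate axis and measuring the relative Frobenius deviation.

## Mineral calibration

qBEI grey values calibrate to the local calcium weight fraction ψ_ca. With
the mineral idealized as hydroxyapatite Ca₁₀(PO₄)₆(OH)₂, the stoichiometric
calcium mass share computed from standard atomic masses is 0.39894, giving
the mineral (HA) mass fraction ψ_mi = ψ_ca / 0.39894. An empirical relation
between mineral mass fraction and ultrastructural density then yields the
mineral volume fraction of the fibril array:

    φ = B ψ_mi / (ψ_mi − A ρ_HA),   A = 0.59 ml/g, B = −0.75, ρ_HA = 3.16 g/cm³.

The relation has a pole at ψ_mi = A·ρ_HA ≈ 1.864, far above physical mass
fractions, but the implementation guards the domain and reports offending
pixels when calibrating rasters. The anchor value: ψ_ca = 0.25 → ψ_mi =
0.6267 → φ = 0.3799 ≈ 0.38.

## Three-level homogenization

The fibril array is homogenized bottom-up with the Mori–Tanaka scheme for
aligned spheroids (symmetry axis e₃):

| level | matrix | inclusion | aspect ratio | fraction |
|---|---|---|---|---|
| (a) mineralized fibril | collagen (E = 5 GPa, ν = 0.3) | mineral (E = 110.5 GPa, ν = 0.28) | 14 | q φ / f_fibril |
| (b) extra-fibrillar foam | mineral | voids (C = 0) | 1 | 1 − (1−q) φ / (1−f_fibril) |
| (c) fibril array | foam | fibril from (a) | 100 | f_fibril = 0.53 |

with mineral quota q = 0.25 by default. Infeasible partitions (any phase
fraction outside [0, 1]) raise an error rather than clipping.

The Eshelby tensor of a prolate spheroid in an isotropic matrix is evaluated
in closed form from the Mura-type I-integrals. At level (c) the matrix (the
foam) may in principle be anisotropic; two routes are provided and
cross-validated: (i) the default isotropizes the matrix (Frobenius-closest
isotropic tensor) *for the polarization tensor only*, and (ii) a fully
numeric Hill polarization by angular integration of the acoustic-tensor
inverse over the unit sphere (Gauss–Legendre in the polar cosine with a
tangent substitution that resolves the sharply peaked metric at aspect ratio
100, periodic trapezoid in azimuth). At the default parameters the foam is
exactly isotropic (isotropic mineral, spherical voids) and the two routes
agree to ~10⁻⁷ relative.

Validation oracles: the closed-form sphere and infinite-cylinder Eshelby
limits, the Hashin–Shtrikman upper bulk bound for spherical voids (which the
Mori–Tanaka void foam attains), Reuss–Voigt eigenvalue bounds, and exact
dilute/equal-phase/full-fraction limits.

## Virtual indentation

The equivalent indentation modulus of an anisotropic half-space indented
along the surface normal r is computed from the Barnett–Lothe surface
impedance: for each in-surface direction t,

    L(t) = −(1/π) ∫₀^π [ R T⁻¹ Rᵀ − Q ](ω) dω,

with Q, R, T the acoustic-tensor contractions of the rotated vector pair
m = t cos ω + r sin ω, n = r cos ω − t sin ω. L is real, symmetric and
positive definite; the circular-contact equivalent modulus is the angular
harmonic mean M = 2 / ⟨ r·L(t(φ))⁻¹·r ⟩_φ. This all-real integral route
avoids the degenerate Stroh eigenvalue problem of isotropic media, is exact
when r is a material symmetry axis, and reduces to M = E/(1−ν²) exactly for
isotropic materials (machine-precision test). The on-axis value for
transversely isotropic materials is cross-checked against the independent
closed form M₃ = 2·√[ (C₁₁C₃₃−C₁₃²)/C₁₁ / (1/C₄₄ + 2/(√(C₁₁C₃₃)+C₁₃)) ].

Both angular integrals use the periodic trapezoid rule on π-periodic smooth
integrands, which converges spectrally: the bulk quadrature (48 × 24 nodes)
matches a 720 × 360 reference to ~10⁻⁸ relative. The out-of-plane fibril
angle θ maps to the indentation direction r(θ) = [0, sin θ, cos θ] in the
material frame.

For cohort-scale evaluation a bilinear (φ, θ) interpolation grid
(φ ∈ [0.15, 0.60] step 0.01, θ ∈ [0°, 90°] step 3°) reproduces the exact
chain to better than 0.01 GPa (tested); per-site predictions in the pipeline
are nevertheless evaluated exactly in batch.

## Site matching

Modality rasters are registered to the indent frame by minimizing the mean
squared difference of z-scored overlapping pixels over an in-plane rigid
transform: an exhaustive coarse grid (one-pixel steps over the search
window) followed by Nelder–Mead refinement, making the optimization
deterministic. The objective subsamples large rasters to ≈4·10⁴ pixels,
which leaves the optimum of smooth fields unchanged. Recovery of known
offsets is tested to half a pixel (0.25 µm), including under noise and small
rotations.

Per-indent covariates are disk averages over the indenter interaction zone
(radius 1.75 µm): the mean over valid pixels whose centres fall inside the
disk. The centre-in-disk rule is unbiased on linear fields and its
discretization error vanishes with pixel size (tested); sites whose disk
contains no valid pixels (pores) are flagged `near_pore` rather than
dropped silently.

## Synthetic cohorts

Because the original raw images were never deposited, the pipeline is
exercised on seeded synthetic cohorts emulating the published summaries:
φ fields with mean 0.38 (SD 0.02, osteonal) and 0.39 (SD 0.03,
interstitial); θ fields with an exact truncated-normal marginal (mean 32.3°,
SD 14.7°, support [0°, 73.2°]) obtained by a Gaussian-copula transform of a
spatially correlated Gaussian field; 29 patterns of 33 indents on 0.5
µm/pixel rasters (957 sites, 74 flagged, 883 retained); elliptical pores; a
known rigid misregistration between modalities; and measured moduli = model
prediction + configurable Gaussian noise, with a *decoupled* mode (moduli
drawn independently of the covariates) reproducing the near-zero-r² regime.
The 5 µm spatial correlation length is a realism choice the published
summaries do not constrain. With zero noise, identity misregistration and
disk-basis measurement, the full pipeline returns r² ≈ 1 (self-consistency);
the decoupled mode returns r² < 0.02.

## Statistics

Squared Pearson correlations of measured moduli against each covariate and
prediction; Tukey HSD (statsmodels) across tissue-region groups, validated
for power and for a familywise type-I error rate near α = 0.05 under the
null; Wilcoxon/Mann–Whitney rank and Welch/paired t tests (scipy) between
measured and predicted distributions. The sensitivity Monte Carlo draws
(q, f_fibril, θ) uniformly at fixed φ, rejects and redraws infeasible
partitions, and reports the per-draw moduli and extremes.

## Known limitations

* The Monte Carlo sensitivity extremes at φ = 0.34 computed by this
  implementation round to [11, 29] GPa, wider at the bottom and top than the
  historically reported [5, 21] GPa, while the same model chain reproduces
  the central predictions (27.5 GPa axial at φ = 0.38, 24.7 GPa at the mean
  orientation) to ≈0.1 GPa. No parameter reading we probed (clipping vs
  rejecting infeasible draws, mass- vs volume-fraction interpretation of
  0.34, directional Young's modulus instead of indentation modulus)
  reproduces both reported extremes simultaneously; notably, any such Monte
  Carlo containing near-axial draws near the default (q, f_fibril) must
  exceed the model's own axial modulus at φ = 0.34 (≈24 GPa), which already
  exceeds the reported maximum. The reported *span* (16 GPa) is close to
  ours (≈18). The implementation keeps the faithful protocol and reports its
  own numbers.
* The equivalent-modulus formula is the standard approximation for
  off-symmetry indentation directions (exact on-axis and for isotropy).
* Mori–Tanaka with aligned inclusions ignores fibril orientation dispersion
  within the interaction volume; θ enters only through the indentation
  direction.
* The synthetic generator reproduces published *summary* statistics, not the
  actual tissue microstructure; spatial covariances beyond the stated means
  and SDs are modelling choices.
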