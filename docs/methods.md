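# Methods

## Model and procedure

`enfret` evaluates Förster resonance energy transfer for a covalently
linked donor–acceptor dyad using an ensemble representation of the nuclear
degrees of freedom. Per snapshot *i* the orientation factor and coupling
are

κᵢ = μ̂_D·μ̂_A − 3(μ̂_D·r̂)(μ̂_A·r̂),
|V_DA|²ᵢ = κᵢ² |μ_D|²ᵢ |μ_A|²ᵢ / ((4πε₀)² η⁴ rᵢ⁶),

with the TDMs read in atomic units and converted to C·m, r in Å converted
to m, so |V_DA|² is in J². The ensemble coupling is the *unweighted
arithmetic mean* over snapshots (no reweighting is applied because the
snapshots are assumed to be an equilibrium thermal sample). The rate is
the golden-rule expression

k_RET = (2π/ħ) ⟨|V_DA|²⟩ J/(hc),

with the spectral overlap J in cm (see below); J/(hc) is the per-Joule
density of resonant transitions. This prefactor convention reproduces the
standard closure k ≈ 1.2×10¹² s⁻¹ for ⟨|V_DA|²⟩ = 5.2×10⁻⁴⁴ J² and
J = 7.44×10⁻³ cm, which the test suite asserts.

Deliberate separation of effects: the coupling is ensemble-averaged, while
J is taken from *equilibrium-structure* vibronic spectra, whose line
broadening already encodes thermal and vibrational width. Combining an
ensemble-derived J with the ensemble-averaged coupling would double-count
thermal broadening; the pipeline refuses that combination unless an
explicit override flag is set.

All physical constants are pinned to CODATA-2018 in `enfret.constants`;
every unit conversion routes through that table. Dipole-strength
conversions act on the squared quantity (1 a.u.² = 2.541746² ≈ 6.4605 D²).

## Geometry and angles

Fragment centers are midpoints of user-supplied nitrogen pairs (N4–N5
donor, N1–N2 acceptor); the distance vector points donor → acceptor (κ²
is insensitive to this choice; it is fixed for reproducibility). Five
diagnostic angles are reported per snapshot: θ_A (μ_A vs the acceptor
axis), θ_Ar (μ_A vs r⃗), θ_D, θ_Dr (donor analogues) and θ_AD (between
the TDMs). All reported angles are folded into [0°, 90°] via
arccos|û·v̂| because a TDM's overall sign is unphysical; the dot product
is clamped to [−1, 1] against floating-point overshoot. κ² itself is
computed from raw vectors, so folding never touches it. The
intensity-weighted ensemble angle uses weights |μ_D|²|μ_A|² and is a
linear (not circular) mean of folded angles. Angle histograms default to
5° bins covering [0°, 90°] (configurable).

## Spectra and overlap

Spectra live on a strictly increasing wavenumber grid (cm⁻¹) with
intensities per wavenumber; unit-area normalization uses the trapezoid
rule (tolerance 10⁻⁹ on the flag check). Stick spectra are broadened
with Gaussians of a stated FWHM — the width has *no default* and must be
supplied, since it is a physical modelling choice — and the grid must
cover every stick ± 3 FWHM. The overlap integral interpolates both
spectra linearly onto the union grid restricted to the shared range and
integrates the pointwise product with the trapezoid rule; disjoint
ranges give 0 with a warning; unnormalized inputs are normalized
internally with a logged note. Intensity Jacobians for nm- or eV-axis
inputs are *not* applied; inputs are assumed already expressed per
wavenumber. Only Gaussian line shapes are implemented.

## Donor diabatic-state classification

The two donor characters (bright in-plane ππ* vs weak CT-like) are
assigned from the operational proxy θ_D: below the threshold (default
45°, configurable) → ππ*, at or above → CT (ties to CT). An alternative
backend replaces the fixed threshold by an exact two-class 1-D k-means on
θ_D (enumerating split points — deterministic and exact in 1-D); when the
two backends disagree on more than 10% of snapshots both splits are
reported in a warning. The orientation–intensity relation is quantified
by the Spearman (rank) correlation between |μ_D|² and κ², because the
claim being tested is monotone inverse proportionality, not linearity.

## Synthetic ensemble generator

The generator emulates the statistical structure of a thermal ensemble of
an orthogonally arranged dyad; it is the test bed for every pipeline
stage. Construction, in a lab frame with r̂ = x̂ and the donor N4–N5 axis
ẑ ⊥ r̂:

- mixing coordinate λ ~ Beta(2, 1) per snapshot (configurable; a scalar
  λ collapses the distribution for degenerate-limit tests);
- donor TDM as a trigonometric superposition
  μ_D(λ) = √m_b cos(λπ/2) ẑ + √m_c sin(λπ/2) x̂ with bright intensity
  m_b = 6.5 a.u.² and CT intensity m_c = 0.5 a.u.², so the TDM rotates
  off-axis while |μ_D|² = m_b cos²φ + m_c sin²φ decays — the
  orientation–intensity anticorrelation arises by construction, and
  because m_c ≪ m_b any snapshot with κ² > 1 automatically has
  |μ_D|² < 2 a.u.²;
- acceptor N1–N2 axis tilted from r̂ by a uniform angle ≤ 11° (uniform
  azimuth), acceptor TDM jittered about that axis in a uniform cone ≤ 5°,
  so θ_A < 5° always and θ_Ar ≤ 16° by the spherical triangle
  inequality; |μ_A|² uniform in [9, 12] a.u.²;
- center distance uniform in [16.7, 17.3] Å; default n = 100 snapshots,
  seed 1234, one explicit pseudo-random stream (no global state).

The Beta(2, 1) default was fixed once from the target orderings: the
median mixing must exceed ≈ 0.59 for θ_D > 20° in a majority of
snapshots, and the bright-state dominance of the weights makes the
intensity-weighted θ_AD exceed the plain mean. Because the donor plane
contains ẑ and r̂, θ_D + θ_Dr = 90° holds exactly, which is tested
exactly.

The generator also emits toy four-nitrogen XYZ frames consistent with the
sampled centers and axes (N–N half-separation 5.7 Å), so the geometry
readers are exercised by the same fixtures, and three-stick
Poisson-weighted Franck–Condon progressions (Huang–Rhys S = 1, spacing
1400 cm⁻¹, FWHM 600 cm⁻¹, donor-emission 0–0 at 20800 cm⁻¹ mirrored
downward, acceptor-absorption 0–0 at 19200 cm⁻¹) — values chosen as
typical of perylene-diimide chromophores, giving the characteristic
three-peaked band shape. What the generator does **not** emulate:
time-correlated dynamics, anharmonic donor–acceptor coupled modes,
non-Gaussian line shapes, or any electronic structure beyond the
two-state TDM superposition. Passing tests therefore demonstrate the
correctness of the analysis chain under the stated distributions, not the
accuracy of those distributions for any real molecule.

## Analytic oracles

Two independent cross-checks back the implementation:

- **Point-charge dipole oracle** (tests): each TDM is represented as ±q
  charges separated by d along its axis; the four-charge Coulomb energy
  divided by μ_D μ_A/(4πε₀ r³) converges to κ as d/r → 0. Agreement to
  4 decimals at d/r = 10⁻³ is asserted over 1000 random triples.
- **Closed-form coupling expectation**: under the generator's
  distributions E[|V_DA|²] factorizes as
  E[κ²|μ_D|²]·E[|μ_A|²]·E[r⁻⁶] times the SI prefactor. With
  μ̂_D = (sin θ_D, 0, cos θ_D), κ²|μ_D|² = a_z² m_b cos²φ +
  4a_x² m_c sin²φ − (cross term), and azimuthal symmetry of the acceptor
  direction about x̂ kills the cross term and gives
  E[a_z²] = (1 − E[a_x²])/2 with E[a_x²] in closed form from the uniform
  tilt and cone angles; the Beta moment E[cos²(λπ/2)] is a 1-D
  quadrature. The sample mean at n = 10⁵ is required to sit within 3
  standard errors of this value.
- **Closed-form overlap**: for unit-area mixtures of equal-width
  Gaussians, J = Σ ŵᵢŵₖ exp(−Δ²/(4σ²))/(2σ√π), exact up to the 4·FWHM
  grid truncation; the numerical trapezoid overlap matches it to < 0.1%.

## Numerical choices and problem sizes

- Trapezoid integration on the union grid for overlaps (robust for
  tabulated spectra of unequal gridding); halving a 1 cm⁻¹ grid changes J
  by < 10⁻⁴ relative for smooth spectra.
- Full-chain parameter recovery runs at the default n = 100 with a
  declared relative band of 0.20, set at roughly four relative standard
  errors of the mean coupling (measured relative std of per-snapshot
  |V_DA|² ≈ 0.44 at n = 10⁵). Convergence checks use n = 10⁵ samples;
  statistical smoke tests use two-sample Kolmogorov–Smirnov at n = 2000.
- Degenerate inputs: coincident fragment centers are an error (r = 0);
  a degenerate center *pair* (coincident atoms) is allowed with a
  warning; zero vectors are rejected wherever a direction is needed;
  snapshots lacking a complete donor/acceptor TDM pair are dropped with a
  logged warning rather than failing the run.
- JSON reports serialize floats at 12 significant digits with sorted
  keys; a run with a fixed seed is byte-identical on re-execution. The
  report schema carries a version string and the configuration hash
  (output paths excluded from the hash).

## Known limitations

- Ideal-dipole approximation only: no transition charges, multipoles or
  distance-exponent corrections; at r ≈ 17 Å for ~10 Å chromophores the
  point-dipole error is not negligible in absolute terms.
- The rate uses a single ensemble-averaged coupling; no time-dependent or
  non-equilibrium rate theory.
- Spectral overlap depends on the supplied broadening; no attempt is made
  to derive the FWHM from first principles.
- The classifier is a geometric proxy; it cannot detect character changes
  that leave θ_D unchanged (true state characters require orbital
  analysis, out of scope).
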