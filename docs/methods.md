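# Methods

## Signal model

Every proton site is simulated to first order (weak coupling): a stick at
the chemical shift is split successively by each homonuclear coupling into
±J_HH/2 pairs at half amplitude, and finally by the single heteronuclear
coupling into two ¹⁹F spin-state components at ±J_HF/2. In an in-phase (IP)
multiplet both components are positive and the multiplet integrates to the
site amplitude; in an anti-phase (AP) multiplet the component at −J_HF/2 is
negated and the integral is zero. Each stick is convolved with a unit-area
Lorentzian of the site's FWHM.

Synthesis is performed analytically in the frequency domain — the Lorentzian
is evaluated pointwise on the requested grid — rather than via an FID and
FFT. This makes simulated intensities exactly grid-independent (doubling the
sampling reproduces shared points to machine precision) and integrals exact,
which the test suite exploits. The cost is that effects intrinsically tied
to time-domain processing (window functions, truncation wiggles) are not
modelled; the lineshape of real processed spectra is assumed Lorentzian.

Edited spin-system spectra are sums over the member protons only:
suppression of all other signals by the fluorine-selective editing is
assumed perfect, and the TOCSY transfer complete. The differential
relaxation of anti-phase coherences is modelled by a single scalar
attenuation ρ ∈ (0, 1] applied to the whole AP spectrum. A per-site ρ is a
plausible refinement (whether the attenuation is multiplet-uniform in real
data is an open experimental question) but is deliberately not implemented;
the scalar model is what the k-compensation below inverts exactly.

Strong coupling is not simulated. This mirrors the analysis itself, which is
only valid for weakly coupled, resolved multiplets; strongly coupled systems
are a documented limitation of both.

### Sign conventions

The AP convention — the component at −J_HF/2 is the negated one — fixes
everything downstream: the sum subspectrum IP + k·AP carries the component
at +J_HF/2, so the displacement of the difference subspectrum relative to
the sum equals J_HF, sign included. Which ¹⁹F spin state is labelled α is a
global gauge; `assign_signs` fixes it the way practitioners do, by declaring
a chosen reference coupling (conventionally a geminal ²J_HF, which is
reliably positive) to be positive and flipping all signs together if needed.

### Δ delay

The spin-echo evolution delay matched to the selected coupling is
Δ = 1/(2|J_HF|) for AₙX and AₙX₃ systems and 1/(4|J_HF|) for AₙX₂. For a
geminal coupling near 49 Hz this gives ≈ 10.2 ms, inside the 9–12 ms range
used experimentally. The delay enters the simulation only through its
idealized outcome (clean IP/AP phase structure); pulse shapes, gradients and
phase cycling are out of scope.

## k optimization

With AP amplitudes attenuated by ρ, the subspectra formed with scaling k are
mixtures: IP ± k·AP = (1 ± kρ)·α + (1 ∓ kρ)·β. Cross-talk (the residue of
the unwanted component) vanishes exactly at k = 1/ρ, where the two
subspectra become congruent up to the J displacement. The implemented
objective operationalizes that observation directly:

    R(k) = min_δ Σ_f [ S₊(f; k) − S₋(f − δ; k) ]²

evaluated over a window, minimized first on a coarse k grid (31 points over
the bounds, default (0.5, 2.0)) and refined with bounded scalar
minimization. For a single-multiplet window the minimizer is k = 1/ρ
exactly; the parameter-recovery tests confirm sub-1% recovery across
ρ ∈ [0.7, 1.0] and J_HF from 2 to 50 Hz. The objective is normalized by the
squared IP peak intensity, making it invariant to overall rescaling, and an
identically zero AP spectrum (every J_HF = 0) is rejected as unidentifiable
rather than silently returning a boundary value.

The congruence argument holds per multiplet, not across multiplets with
different couplings, so the window matters: it must contain *both*
spin-state components of one multiplet. The pipeline therefore runs a
provisional displacement fit at k = 1 on the strongest multiplet, expands
that multiplet's window by the provisional |J| plus a margin, and optimizes
k there. Because ρ is modelled as uniform, the k found on one multiplet
applies to the whole spectrum; per-multiplet optimization remains available
through the `region` argument.

## Displacement fitting

The coupling is the displacement minimizing the in-region least-squares
misfit between the subspectra. The search has two stages:

1. **Exhaustive integer-lag scan** at the digital resolution over the whole
   search bracket (default ±80 Hz, covering geminal H–F couplings), computed
   exactly in O(n log n) via a cross-correlation plus cumulative sums — this
   is a true global grid search, immune to local minima from multiplet
   self-similarity.
2. **Bounded refinement** (golden-section/parabolic, scipy) within ±2 grid
   steps of the best lag, with the difference subspectrum shifted by a
   band-limited method: multiplication of its DFT by a linear phase ramp,
   after mirror-padding to suppress circular wrap-around. Band-limited
   shifting preserves the Lorentzian shape far better than polynomial
   interpolation at the 0.001 Hz refinement targets used here. Shifts that
   reach past the sampled window treat the outside as zero, consistent with
   baseline-level tails.

The reported uncertainty is the 1σ half-width of a local quadratic expansion
of the (normalized) objective around its minimum — an internal precision
metric, not a full error model; it ignores correlated noise and baseline
errors. A minimum within two grid steps of the bracket edge raises an error
("bracket too small") instead of returning a clipped value; a near-flat
objective is returned flagged low-confidence.

On noiseless synthetic data at 0.01 Hz resolution the fit recovers signed
couplings from 0.05 to 60 Hz to better than 0.01 Hz — in particular well
below the 1 Hz linewidth, where the conventional anti-phase peak-to-peak
reading is biased high because the opposing components partially cancel.
That biased estimator is kept (`naive_ap_splitting`) as the explicit
baseline for the paired-bias tests.

### Segmentation

Multiplet windows are found on the sum subspectrum as contiguous support
above a threshold (default 5% of the maximum absolute intensity), merging
runs closer than `min_gap` (default 10 Hz). Segmenting the *subspectrum*
rather than the raw IP data is important: the subspectrum contains one
spin-state component per multiplet, so windows are compact and do not
straddle the J splitting. Overlapping multiplets from different spin systems
in one window are out of scope (no deconvolution is attempted); the
displacement fit will flag such windows through its residual.

## Conformer averaging

Populations follow the Boltzmann distribution over relative Gibbs energies,
pᵢ = exp(−Gᵢ/RT)/Σⱼ exp(−Gⱼ/RT), computed with the minimum-energy shift for
numerical stability (R = 8.31446 × 10⁻³ kJ·mol⁻¹·K⁻¹, default
T = 298.15 K to match room-temperature acquisition). Conformers differing
only in a silent degree of freedom (hydroxyl rotamer orientation) are
grouped by a generic label map: group populations add and group couplings
are population-weighted member means, which leaves every site's overall
average invariant to machine precision (an associativity property the tests
assert). Observed couplings are compared with ⟨J⟩ = Σ pᵢ Jᵢ per site;
quantum-chemical inputs (energies, conformer-specific J values) are consumed
from CSV only — no electronic-structure code is invoked.

Isomer ratios of slowly interconverting species are trapezoidal integrals of
one resolved signal per isomer, normalized to their sum.

A tolerance note: published conformer percentages are typically rounded to
integer percent, which propagates to roughly ±0.1 Hz in weighted averages of
~50 Hz couplings; comparisons against tabulated averages use that tolerance.
Two tabulated cells for the fluorohydrin system disagree with recomputation
from the rounded percentages by 0.13–0.18 Hz and are attributable to that
rounding; they are excluded from exact comparisons.

## Synthetic data and what passing tests show

The canonical fixtures emulate the two study systems: a three-site spin
system coupled to a steroid's ring fluorine (J_HF = +48.9, +14.1, −0.6 Hz,
ρ = 0.935 so that the compensating k is ≈ 1.07) and the cis/trans
fluorohydrin conformer ensembles in three solvents. The generator reproduces
first-order multiplet structure, IP/AP phase relations, uniform AP
attenuation, and optional white Gaussian noise. It does **not** reproduce
strong-coupling roofing, baseline distortion, lineshape errors from
imperfect shimming or processing, t₁ noise, or site-dependent relaxation —
so passing recovery tests demonstrate correctness of the estimators under
the stated model, not robustness to every artifact of real spectra. Real
experimental values (the measured couplings and isomer ratios) enter only as
fixture parameters; tests assert recovery of the parameters used, which is a
property of the software, not a re-measurement.

Problem sizes used in the tests and the acceptance script — single-site
grids of ~5 000–10 000 points at 0.01 Hz and a three-site grid of 64 001
points — were chosen as the smallest grids on which the multiplets are
comfortably contained and the 0.01 Hz digital resolution of the headline
small-J claim is honoured.

## Numerical choices and degenerate inputs

- Lorentzians are unit-area; a grid is flagged (warning, not error) when it
  cannot contain ~99% of a multiplet's area (sticks ± 32 linewidths).
- Frequency axes are stored in Hz relative to the carrier; ppm is derived at
  presentation time from the spectrometer frequency (500 MHz default).
- Non-uniform input axes are resampled to a uniform grid with a logged
  warning; NaNs in input files are rejected with the offending line number.
- JCAMP-DX support is limited to the AFFN/XYDATA dialect with fixed-point
  ordinates (YFACTOR scaled to ~9 significant digits), sufficient for 1D
  real spectra.
- `compute_delta` rejects J = 0 explicitly; `optimize_k` rejects a zero AP
  spectrum; `fit_displacement` rejects empty regions and bracket-edge
  minima. Ties in the integer-lag scan resolve to the first (lowest-δ) lag,
  then refinement decides.
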