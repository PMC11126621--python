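# Methods

## Physical model

The sensor is treated as a one-dimensional acoustic network in the
plane-wave regime: every duct segment is a lossless two-port relating
pressure and volume velocity at its ends, and every side branch is a shunt
admittance at a point junction.  This is valid while the wavelength is
much larger than the duct diameter (here λ ≳ 11 cm against ~1 cm bores
below 3 kHz) and while viscothermal boundary-layer losses, temperature
gradients and mean flow are neglected — the sample is taken as a
stationary, dried breath column at room temperature.  Losses would lower
the transmitted amplitude roughly uniformly; they broaden the resonance
but barely move it, so the frequency-shift readout is the robust
observable.

A duct segment of length L and characteristic impedance Z = ρc/S has the
two-port

    [[cos kL,      jZ sin kL],
     [ (j/Z) sin kL,  cos kL]],

unimodular by construction.  The closed stub loads the duct with
y_C = j·tan(k d₂)/Z₂ (rigid termination), the open stub with
y_O = −j·cot(k d₃)/Z₃ (pressure-release termination); both are purely
imaginary, so the network is lossless and the transmittance never exceeds
100%.  A unit cell is the symmetric product half-duct · shunt · half-duct.

### Structure layout

The full sensor is

    [cell]^N · [defect guide d_d] · [cell]^N ,    N = 10 per side,

terminated on both ends by semi-infinite main ducts of admittance
Y₁ = S₁/(ρc).  Two layout readings are possible from the design
description ("N = 10" with a central defect): ten cells in total split
5|5, or ten-cell mirrors on each side.  Only the second reproduces the
reference operating points quantitatively (defect peak 1887.59 Hz for air
at the starting design, linewidth 0.558 Hz at d_d = 20 cm, quality factors
of the d₃ study within 0.2%), and it is adopted; `SensorGeometry.n_cells`
is the per-side mirror count.  The defect two-port is the full guide of
length d_d, implemented as the square of the half-guide matrix
(`defect_half_matrix`), mirroring the half–shunt–half construction of the
unit cell.

### Band structure

The infinite lattice satisfies cos(K d₁) = cos(k d₁) + (j/2) Z₁ y_OC
sin(k d₁).  Because y_OC is imaginary the right side is exactly real; the
implementation raises if roundoff ever leaves more than 1e−9 of imaginary
part.  The same relation is also built from the resonators' Green surface
functions, g_c⁻¹ = −j y₂ tan(k d₂) and g_o⁻¹ = +j y₃ cot(k d₃) with
yᵢ = Sᵢ/(ρc) and inertial prefactor z₁ = jωZ₁; the two routes agree
identically and the second exists purely as a cross-check (the sign and
the (y₃, d₃) arguments of the open-branch term are fixed so that the two
forms coincide with the shunt admittance definition above).  Band gaps are
the maximal intervals with |cos(Kd₁)| > 1, scanned at 0.25 Hz and edge-
refined by Brent bisection to 1e−3 Hz.  Gap ordinals count from the lowest
frequency; the low-frequency stop band created by the open stubs (which
extends to DC) is gap 1, and the defect mode of the starting design sits
in gap 3.

## Gas model

Pure-gas constants at room temperature (kg·m⁻³, m·s⁻¹): CO₂ 1.8393/267,
Ar 1.661/319, O₂ 1.314/326, Air 1.2047/343, N₂ 1.165/349.  A mixture with
volume fractions αᵢ has ρ = Σαᵢρᵢ and c = Σαᵢρᵢcᵢ/Σαᵢρᵢ.  Normal dry
exhaled breath is 78% N₂, 16% O₂, 5% CO₂, 1% Ar, giving c = 338.51 m/s
and ρ = 1.2275 kg/m³.

CO₂ enrichment is parameterized in units of +0.01 volume parts of CO₂
added to the normal 100-part sample without removing other gases, i.e.
the sample is diluted by the added CO₂: at 100 units the composition is
78/16/6/1 parts of a 101-part total.  This additive (dilution) convention
— rather than holding the total fixed and rescaling the other gases — is
what reproduces the reference red-shift sequence (endpoint 1857.02 Hz)
and the calibration slope (−0.0567 Hz/unit) simultaneously; the rescaling
convention misses the slope by ~5%.  Humidity and volatile organics are
outside the model (the sample is assumed dried), as are real-gas
corrections.

## Peak location and linewidth

The optimized resonance has Q of order 10⁶ — a ~0.3 mHz linewidth at
1.8 kHz — which no practical uniform grid resolves.  The locator therefore
(1) scans each band gap coarsely (≤ 4000 samples), (2) zooms on every
local maximum by iterated 41-point grid refinement, shrinking the bracket
tenfold per pass down to a 1e−9 Hz half-window (robust where
golden-section search stalls on the flat Lorentzian tails), and (3)
measures the FWHM by expanding-bracket Brent bisection on the two
half-maximum crossings, resolved to better than 1e−7 Hz.  Half maximum is
defined relative to the peak height, T_peak/2.

Mode tracking conventions, used where several cavity modes coexist:

- Standalone location picks the in-gap peak closest (in units of the gap
  half-width) to its gap's center, resolving near-ties toward the lower
  frequency; gaps truncated by the scan limits are skipped.
- A parameter sweep anchors on the base geometry's resonance and follows,
  per row, the candidate closest in frequency — one physical mode family,
  no hopping between gaps.
- Candidates narrower than `min_width` = 2e−4 Hz are treated as
  effectively uncoupled: no measurement chain of realistic frequency
  resolution would register them, and following such a mode would report
  figures no instrument could see.  `min_width=0` disables the floor.

Because the wave equation here depends on frequency only through k·L =
2πf·L/c, peak frequencies scale exactly with the sound speed and are
independent of density (all impedances scale together); both facts are
enforced as tests.

## Indicators and calibration

S = Δf_R/Δc, FoM = S/FWHM, Q = f_R/FWHM, LoD = f_R/(20·S·Q),
SNR = Δf_R/FWHM, RS = 2·FWHM/(3·SNR^0.25).  Δf_R and Δc are magnitudes
over the full enrichment range (0 vs 100 units), and the linewidth is the
baseline mixture's.  The factor 20 in the detection limit is the field's
conventional prefactor and is taken as given.  The identities
FoM·FWHM = S, Q·FWHM = f_R and LoD·20·S·Q = f_R hold to machine precision
by construction.  The calibration line is an ordinary least-squares fit of
f_R on the enrichment label over six levels {0, 20, …, 100}; with the
dilution convention the response is linear to R² > 0.9999.

A known divergence from the reference operating point: at the optimized
design the converged linewidth is 2.80e−4 Hz (Q ≈ 6.4×10⁶, peak
transmittance → 100% as a lossless mirror-symmetric resonator must),
whereas the reference reports 0.0005 Hz, Q ≈ 3.5×10⁶ and a 71% peak.
Every reference linewidth of 0.018 Hz and above is matched here to 0.2%,
and sub-unity peak transmittance cannot occur in this lossless symmetric
model; the residual factor of ~1.8 on the narrowest width has the
signature of a finite frequency-step measurement of an unresolved
Lorentzian.  The adaptive-refinement values are reported as computed.

## Design sweeps and selection

`run_sweep` varies one parameter over an explicit value list (defaults in
the packaged studies are the reference value lists) and recomputes the
full metric suite per row; rows whose resonance vanishes are flagged, not
fatal.  `select_optimum` maximizes the figure of merit among rows with
peak transmittance above a floor (default 50%), treats FoM differences
within 1% as equivalent — below the reproducibility of a linewidth
measurement — and, among equivalents, keeps the incumbent (base) value:
a design change must buy a material improvement.  This convention
recovers the reference design choices for d_d (100 cm), d₁ (20 cm), d₂
(6.0 cm), d₃ (6.0 cm), S_d (1.0 cm²), S₁ (1.0 cm²) and S₂ (0.9 cm²); for
S₃ the converged linewidths of the tracked mode grow monotonically with
S₃, so the figure of merit genuinely peaks at 0.8 cm² rather than the
reference's 0.9 cm².

## Numerical parameters (defaults)

| quantity | value | note |
|---|---|---|
| spectrum grid step | 0.05 Hz | display/export only; never used for peaks |
| band-structure step | 0.25 Hz | gap detection grid |
| gap-edge tolerance | 1e−3 Hz | Brent bisection on abs(cos Kd) − 1 |
| peak refinement | 1e−9 Hz half-window | iterated 41-point grid zoom |
| FWHM crossing tolerance | 1e−13 Hz (xtol) | expanding bracket + Brent |
| peak threshold | 1% transmittance | below: not a usable resonance |
| detectability floor | 2e−4 Hz | sweep/auto tracking only |
| pole guard | abs(sin/cos) < 1e−12 | branch resonance; sample nudged |

All geometry is SI internally; the CLI and config layer accept cm/cm² and
convert on ingest.  Scans start at 0.5 Hz to stay clear of the open-stub
DC divergence.  Everything is deterministic: identical configurations
produce byte-identical output tables.

## What the tests do and do not show

The test suite checks the closed-form gas rules against independent
arithmetic, every matrix element against hand expansion, the algebraic
identity of the two dispersion routes, the lossless invariants
(unimodularity, T ∈ [0, 100], density invariance, exact speed
proportionality of the peak), the coincidence of Green-method gaps with
TMM transmittance collapse, and the reference operating points quoted
above.  All of this validates the idealized lossless 1-D model, not a
physical device: wall losses, three-dimensional junction effects, end
corrections at the stub mouths, humidity and temperature drift are not
modelled, and real linewidths will be broader (and peak transmittance
lower) than the ideal figures computed here.
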