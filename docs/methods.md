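# Methods

## Model overview

`mammomc` is an analog Monte Carlo photon-transport code specialized to a
layered compressed-breast geometry in the mammographic energy band
(nominally 26–36 keV; the physics data span 1–100 keV). A history starts at
a point source, is collimated onto the phantom entrance, and alternates
free flights and collisions until the photon is absorbed, falls below the
energy cutoff, or leaves the geometry. Three interaction channels are
modeled:

- **Photoelectric absorption** — the full photon energy deposits at the
  collision site and the history ends. No fluorescence is emitted: the
  K-shell binding energies of H, C, N and O are all below 0.6 keV, under
  the transport cutoff, so relaxation radiation could never travel.
- **Incoherent (Compton) scattering** — the polar angle is sampled from the
  free-electron Klein–Nishina density and the scattered energy follows
  `E' = E / (1 + α(1 − cos θ))` with `α = E / 511 keV`. The electron energy
  `E − E'` deposits locally (kerma approximation: the CSDA range of a
  ≤36 keV electron in tissue is below ~25 µm, negligible against every
  region dimension). An optional incoherent-scattering-function correction
  (rejection with `S(x)/Z` built from the packaged form factors) exists
  behind `incoherent_sfunc=True`; it is off by default, matching the plain
  free-electron treatment, and changes band-energy results at the percent
  level.
- **Coherent (Rayleigh) scattering** — elastic redirection. The scattering
  atom is picked with probability ∝ `w_i (μ_coh/ρ)_i(E)`; the angle is
  sampled by drawing `x²` from the atom's cumulative `∫F²(x) dx²` table
  (inverse-CDF) and accepting with the Thomson factor `(1 + cos²θ)/2`.

Transport is strictly analog: weight ≡ 1, no implicit capture, splitting
or roulette. Energy is conserved exactly by construction — per history and
globally, source energy = deposits + escaped energy to float precision —
and the suite asserts this at 1e-9 relative.

## Cross-section data

Element tables (H, C, N, O) ship as plain-text CSVs on an 81-point
log-spaced 1–100 keV grid with photoelectric, incoherent and coherent mass
attenuation coefficients. They are generated once by
`mammomc.oracles.generate_xsec_fixtures` (optional `gemmi` backend; never
required at run or test time):

- photoelectric: Cromer–Liberman anomalous-scattering `f''`
  (`σ = 2 r_e λ f''`); hydrogen instead uses the exact nonrelativistic
  hydrogenic (Stobbe) 1s photoionization formula, since Cromer–Liberman
  starts at Z ≥ 3;
- coherent: quadrature of Thomson × squared IT92 atomic form factor;
- incoherent: quadrature of Klein–Nishina × the Waller–Hartree-type
  approximation `S(x) = Z (1 − (F(x)/Z)²)`.

A water-mixture cross-check against standard published attenuation values
agrees within ~3% over 10–100 keV (~2% in the mammographic band); the test
suite pins this at 5%. This few-percent table provenance is the dominant
systematic of the package and is inherited by all absolute tallies; ratios
(layer percentages) are much less sensitive. Interpolation is log–log
linear per element; the mixture rule is applied after interpolation, so
linearity in mass fractions is exact, and `total = pe + inc + coh` holds to
machine precision everywhere. Published tissue-composition rows that sum
to 99.8–100.1% are renormalized to exactly 1.

## Geometry and defaults

Coordinates: right-handed, z vertical (beam travels −z), origin at the
breast-top center, chest wall at y = 0, lengths in cm. Regions are
disjoint by construction; `locate` resolves points in priority order and
`trace` walks primitive surface crossings (axis planes plus the vertical
cylinder of the D-shaped footprint) until the containing region changes,
advancing 1e-9 cm past a boundary as the documented tie-break.

| parameter | default | note |
|---|---|---|
| breast footprint | D-shape, radius 8 cm | box mode available for closed-form tests |
| layer thicknesses | 1.5 / 1.5 / 1.5 cm | total 4.5 cm; fully configurable |
| layer materials | GF25 / GF50 / GF75 top→bottom | top layer least dense (0.955 g/cm³) |
| skin | 1.5 mm shell on 5 faces | chest-wall face open |
| plates | 2 mm PMMA above and below | span the collimated field |
| body block | 30×15×30 cm soft tissue | flush behind the chest wall |
| SID | 65 cm | point source over the field center |
| cutoff | 1 keV | residual deposits locally |
| batches | 10 | batch-means relative errors |
| repeats | 3 | seeds `seed + 1000·energy_index + r` |

The layer thicknesses are the one genuinely open geometric choice: the
study this package re-creates never prints them. The default splits a
typical 4.5 cm compressed breast equally. The per-mass layer split depends
strongly on this choice — a sensitivity scan over 1.5 / 2.0 / 2.5 / 3.0 cm
equal layers moves the sweep-averaged top-layer share from ~42% to ~56%,
and thicker layers also flatten the middle-layer energy trend from falling
to flat/rising. Users comparing against published three-layer results
should treat the thicknesses as the calibration parameter they are
(`phantom.layer_thicknesses_cm` in the config).

## Source

Cone beam: directions are drawn uniformly in solid angle inside the
circular cone circumscribing the rectangular entrance field and rejected
onto the rectangle, giving an exactly uniform-in-solid-angle collimated
pyramid; every emitted photon crosses the entrance field. A pencil-beam
mode supports the closed-form slab oracles.

## Tallies and statistics

Per region, the run reports MeV per source photon and MeV/g (deposit
divided by the exact region mass ρV), with a batch-means relative error
`SD(batch means) / (√B · mean)`. Repeated runs (distinct seeds) are
averaged element-wise; the repeat "deviation rate" is the conservative
`max_i |x_i − mean| / mean` of the total deposited energy per photon. Layer
percentages are computed from the per-mass (MeV/g) tallies of the three
layers and normalized to sum to exactly 100 (float precision); a
mass-weighted variant is available (`mass_weighted=True`). The energy-sweep
driver also reports a weighted-least-squares slope of the summed three-layer
absorption on the 26–30 and 30–36 keV segments, with 1σ slope errors from
the tally uncertainties.

## Sampling algorithms and numerics

- Klein–Nishina: uniform proposals on cos θ accepted under the constant
  envelope 2 (the forward value of the unnormalized density for every
  energy). At α ≪ 1 acceptance is ≈ 2/3. This plain rejection was chosen
  over composition–rejection schemes for vectorizability; correctness is
  enforced by Kolmogorov–Smirnov tests against a quadrature-normalized pdf.
- Free path: `d = −ln(1−U)/μ`.
- Boundary handling: collisions are only sampled up to the nearest
  primitive-surface crossing; crossing a surface without changing region
  simply resamples the (memoryless) free path.
- A runaway guard aborts any history exceeding 10⁶ steps (a geometry bug,
  not a physics outcome).
- Histories advance in vectorized chunks (default 200k) with compaction of
  finished photons; results are independent of chunk size ordering only
  through the single NumPy generator, so a fixed (config, seed) is
  bit-reproducible.

## Validation protocol

`validation_run` mirrors the repeat-run protocol used to qualify transport
engines against the standard mammography reference phantom: a homogeneous
80/20 adipose/glandular breast (Hammerstein-type compositions, pre-mixed as
`Adipose80Glandular20`), three seeded repeats, the mean total deposit in
eV/photon, the max relative deviation, and the percent difference against a
user-supplied reference value. The external reference case's exact
geometry and spectrum are not bundled, so the packaged check of the same
machinery is the closed-form route: in photoelectric-only "absorber" mode
the engine must reproduce `exp(−Σμ_j t_j)(1 − exp(−μ_i t_i))` per layer
within Monte Carlo error, and uncollided transmission must match
`exp(−μt)` in full analog mode.

## What the defaults do and do not show

Passing tests demonstrate: exact energy bookkeeping, correct exponential
attenuation and layered-absorber limits, correctly distributed Compton and
Rayleigh angles, correct batch statistics, and the qualitative dose
physics of a layered breast (top-layer dominance at 26 keV falling with
energy, monotone growth of the chest-block dose). They do not certify
absolute dosimetric accuracy beyond the few-percent cross-section
provenance, nor any particular published layer split — that quantity is
controlled by the unprinted layer thicknesses discussed above. Known
limitations: no electron transport, no fluorescence, no bound-Compton
Doppler broadening, no polyenergetic spectra, no image-receptor or grid
model, single-process execution only.

## Problem sizes

Default study sizes are desk-scale by design: 2×10⁵ histories per repeat
per sweep energy (three repeats, eleven energies) and 10⁶ per repeat for
the repeatability check, which keeps the full reproduction script in the
minutes range on one CPU while leaving all trend assertions guarded by
3σ combined Monte Carlo errors.
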