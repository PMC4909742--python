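# Methods

## Scope and model

`dendrocomp` implements a passive (subthreshold) analysis: no
voltage-gated conductances, no synaptic conductance waveforms — synaptic
activity is represented by current injection, steady-state or 50 Hz
sinusoidal. Each neuron is one isopotential soma compartment plus a tree
of cylindrical dendritic compartments. Only the soma's membrane area
matters electrically, so its shape is left unspecified; the default
452 μm² can be overridden per morphology.

Spines are never explicit compartments. A compartment that carries spine
area `A_s` on smooth area `A_d` has its membrane conductance and
capacitance multiplied by `q = (A_s + A_d)/A_d`; axial properties follow
the smooth cylinder. Consequences used throughout: total membrane
(shaft + spines) is conserved; the local time constant `Rm·Cm` is
unchanged by folding (q cancels); the local space constant shrinks,
`λ = sqrt(d·(Rm/q)/(4·Ra))`.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| soma area | 452 | μm² | isopotential soma |
| spine area | 1.5 | μm² | per spine, identical spines |
| spine density | 2.0 (WT) / 1.5 (TG, TG′) | /μm | group-level, uniform along dendrites |
| Ra | 150 | Ωcm | axial resistivity |
| fixed Rm (non-uniform models) | 50 | kΩcm² | the non-fitted side |
| target R_in | 130 ± 0.1 | MΩ | per-neuron resistance fit |
| target τ | 17.0 (WT) / 16.9 (TG) | ms | population capacitance fit |
| Cm grid step | 0.5 | μF/cm² | grid-mode capacitance fit |
| compartment length | ≤ 37 | μm | electrical discretization |
| site spacing | ≤ min(37 μm, 0.2 λ) | — | injection-site placement |

Binning for comparison graphs (chosen here; configurable): 25 μm path
distance, 0.05 for transfers, 1 ms for delays, 5% on normalized axes;
bins are tested only when ≥ 5 neurons per group contribute; α = 0.05,
Mann–Whitney per bin, no correction across bins (per-range significance
is reported raw).

## Fitting

R_in is strictly increasing in the free specific resistance (extra
membrane leak anywhere only loads the soma), so the resistance fit is a
plain bisection on [0.5, 500] kΩcm², stopped at |R_in − 130| ≤ 0.1 MΩ,
with R_in measured by a fresh DC solve each step. Spine folding uses the
same resistance being fitted (spines share the local membrane).

The neuron-wide time constant is defined as the slowest eigenmode of
`G v = (1/τ) C v`. This equals `Rm·Cm` exactly for spatially uniform
membrane and, for non-uniform membrane, agrees with an exponential peel
of the simulated somatic step response (checked to 1% in the tests,
where the peel serves as the oracle). With fixed resistances τ is exactly
linear in Cm, so the capacitance fit is closed-form: grid mode selects
the 0.5-step value whose population mean τ is statistically
indistinguishable from the target (one-sample t-test, p > 0.05) while
both neighbours are rejected; continuous mode solves Cm per neuron. When
the population's τ dispersion is too wide for the grid criterion (wide
morphological dispersion at fixed R_in target produces wide fitted-Rm
dispersion), the best candidate is returned with a flag rather than an
error.

TG′ construction: each fitted TG neuron's free resistance is multiplied
by (mean fitted WT resistance)/(mean fitted TG resistance) for the same
membrane model, and the WT population's Cm is adopted; nothing is refit
afterwards, so TG′ input resistances deviate from 130 MΩ by design.
Spine density stays at the TG value — spine loss is part of the
morphology being isolated.

## Transfer and delay metrics

All delays come from the first two temporal moments of the impulse
response: `G u = e_site`, `G w = C u`; the centroid of the voltage
transient at node j is `w_j/u_j`. Local delay = centroid at the site
(impulse input has centroid zero); propagation delay = soma centroid −
site centroid. This is exact for passive systems — the Crank–Nicolson
transient integrator is kept only as the independent test oracle (delays
and charge ratios agree within 1–2% at 0.0125–0.025 ms steps).

Current transfer is operationalized as charge dissipated through the
soma membrane per unit injected charge, `g_soma · u_soma`: at DC every
unit of charge that reaches the soma node exits through its membrane, so
this is well defined for arbitrary trees and satisfies the conservation
identity `Σ g_i u_i = 1` used as a solver invariant.

Site weights equal the spiny membrane area of the dendrite stretch each
site represents, so surface-weighted metric distributions read as
"percent of synapses operating in this range" (dendritic surface tracks
synapse counts when spine density is uniform).

## Synthetic morphologies

The reconstructions behind the reference morphometrics are not deposited,
so populations are generated to match the published group summaries:
total apical length (1083 ± 92 WT / 806 ± 60 TG, mean ± SEM), apical and
basal spiny areas, oblique and bifurcation counts, diameters by
centrifugal order, spine density and curvature ratio. Per-neuron
dispersion is SEM·√29 (the published cohorts had n = 29), truncated at
3σ.

Generator design (the data constrain only marginals; structure is the
package's choice):

* Headline totals are drawn by **stratified** truncated-normal quantiles,
  so a 29-neuron population mean sits on the target far more tightly than
  independent draws would allow while per-neuron spread is unchanged;
  apical length and area share one permutation (big neurons are big in
  both); branch counts share it too (big arbors branch more), which keeps
  terminal path lengths realistic across the size range.
* The apical trunk has an absolute length draw (120 ± 25 μm — set by
  cortical depth, not arbor size). Obliques are one to two orders deep;
  the terminal tuft is a balanced binary tree consuming the remaining
  bifurcation budget, with short inter-branch stretches and longer
  terminal branches.
* Each neuron's spiny-area target is met exactly (diameters fixed at
  their order-label draws) by tilting the non-shaft length allocation
  between thick and thin branches — weights `w_i · exp(−β d_i)` with β
  solved by bisection — after shrinking the trunk share if the thick
  trunk alone would make the target unreachable.
* Basal arbors are 3–6 unbranched dendrites; the published tables give
  basal area but not basal length, so basal length is back-computed from
  the area target using an inferred basal diameter (0.75 ± 0.10 μm) —
  this is inference, not data.
* The curvature ratio (path/euclidean meandering) only affects the 3D
  layout used for SWC export; path lengths are generated directly.

Populations are a pure function of (profile, n, seed); identical seeds
give byte-identical SWC files. Because totals are stratified across the
population, changing n re-draws the strata — determinism is per
(profile, n, seed), not per neuron index.

What the generator does **not** emulate: real branch-order statistics
beyond the published counts, Sholl profiles, 3D space embedding, tapering
within sections, and — importantly — the exact electrotonic compactness
of the real reconstructions. The synthetic trees fit to somewhat lower
specific resistances (≈ 3–6 kΩcm² uniform-model) than the original
analysis (≈ 8.5 kΩcm², implying very compact neurons), and the fitted
capacitances land correspondingly higher. The fitted WT/TG resistance
ratios keep the reference ordering (leaky soma smallest, uniform, then
leaky dendrite: ≈ 1.04 / 1.19 / 1.23 on seed 1) but are smaller in
magnitude. Compensation at synthetic scale is therefore partial rather
than near-complete: WT–TG′ comparisons differ more than WT–TG in the
large majority of metric × arbor × model combinations, and rescue is
strongest for current transfer in the leaky-dendrite model, but overall
success rates are below the reference values. Passing tests demonstrate
the correctness of the machinery and the direction of the effect, not
the exact published percentages, which depend on the unreleased
reconstructions.

## Numerical choices

* Units are SI internally (S, F, s; areas converted from μm² to cm² at
  assembly); results are reported in MΩ, ms, μm.
* DC/AC solves use sparse LU; transfer metrics per neuron use one dense
  inverse of the (small, ≤ a few hundred nodes) conductance matrix plus
  one matrix product for all first moments at once.
* The eigen time constant uses a symmetric whitening
  (`C^{-1/2} G C^{-1/2}`) and a dense symmetric eigensolver restricted to
  the smallest eigenvalue.
* The transient oracle is Crank–Nicolson (unconditionally stable, second
  order); default step 0.025 ms.
* Sealed-end closed forms: the discretization reproduces
  `cosh((ℓ−x)/λ)/cosh(ℓ/λ)` within 0.5% at 37 μm compartments and
  converges as O(h²). Delay closed forms: τ·ΔX/2 between interior points
  of a long cable; (τ/2)·X·tanh(X) when recording at a sealed end (the
  reflection shortens the centroid delay).
* Degenerate inputs: zero-length or zero-diameter sections are rejected
  at construction; empty arbors yield flagged N/A predictors; bins with
  too few neurons are reported untested rather than tested at low power;
  a group compared against itself yields exactly 0% significant ranges.
* Statistical estimator choices: population (divide-by-n) variance for
  the predictor statistics; per-neuron bin means as the Mann–Whitney
  sampling unit (sites within a neuron are not independent); weighted
  two-sample KS with Kish effective sample sizes for surface-weighted
  distributions.

## Known limitations

* Passive membrane only; conclusions about suprathreshold excitability
  are outside the model.
* The 0.1 MΩ figure is treated as the fit tolerance (the alternative
  reading — a population SEM — would not change the procedure, only its
  stopping rule).
* Whether electrotonic distances for the pattern-recognition predictors
  should use spine-folded or smooth λ is not settled by the source
  material; spine-folded is used for consistency with the transfer
  analysis.
* "Dendritic segment" for the predictors means the unbranched section
  (branch point to branch point), matching the one-synapse-per-segment
  framing of the pattern-recognition literature.
* Bin widths for the comparison graphs are not specified by the source
  analysis; the percent-difference summaries are therefore comparable
  across runs of this package but not bit-comparable with the original
  figures.
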