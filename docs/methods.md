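# Methods

## The elongation-cycle Markov model

One round of translation elongation at a sense codon is a continuous-time
Markov process on twelve ribosomal states.  State 0 is the ribosome with
an empty A-site delivery channel.  Ternary complexes bind with
pseudo-first-order rates kon·c_cog, kon·c_nea and kon·c_non, where the
three concentrations are the summed free ternary-complex pools of the
codon's cognate, near-cognate and non-cognate tRNA species and kon is the
bimolecular association rate constant (1/(µM·s)).  A non-cognate complex
occupies state 11 and simply dissociates (rate ω_off).  The cognate
branch runs 1 → 2 → 3 → 4 → 5 (recognition ω_rec, GTPase activation +
GTP hydrolysis ω_gtp_c, Pi release / EF-Tu rearrangement ω_conf,
accommodation ω_acc_c) with escape routes 1 → 0 (ω_off), 2 → 1
(ω_back_c) and 4 → 0 (ω_drop_c, proofreading).  The near-cognate branch
6 → 7 → 8 → 9 → 10 is parallel, with initial-selection rejection 7 → 6
(ω_rej_n), slow forward steps ω_gtp_n, ω_acc_n and proofreading 9 → 0
(ω_drop_n).  Accommodation (entry into state 5 or 10) is followed by
peptide-bond formation + translocation at the processing rate ω_proc.
The tie structure — one ω_off for the three dissociations, one ω_rec for
both recognitions, one ω_conf for both conformational steps, one ω_proc
for both processing steps — leaves 12 distinct rates for 17 transitions
and is encoded structurally in `RateSet`, so it cannot be violated.

The model assumes the same internal rates for all cognate and all
near-cognate species at every codon; codon specificity enters only
through the concentrations.  `CodonContext` accepts per-codon rate
overrides at the call level but no per-tRNA parametrization is shipped.

## Dwell-time decomposition

The mean first-passage time from state 0 to full accommodation (the
codon-specific accommodation time t_acc) decomposes exactly into the
total dwell in state 0, in state 11, and in the intermediate states of
the two branches.  First-step analysis of a branch gives two
concentration-independent quantities: the accommodation probability per
initial binding,

    v = n4 · ω_acc/(ω_acc + ω_drop),

and the mean residence time per entry,

    τ = n1/(ω_rec+ω_off) + n2/(ω_fwd+ω_back) + n3/ω_conf + n4/(ω_acc+ω_drop),

with loop-resolved visit counts n1 = 1/q, n2 = p1/q, n3 = n4 = n2·p2,
where p1 = ω_rec/(ω_rec+ω_off), p2 = ω_fwd/(ω_fwd+ω_back) and
q = (1−p1) + p1·p2.  Writing q as that sum of positives (rather than
1 − p1(1−p2)) avoids catastrophic cancellation when rejection dominates.
With a_c = kon·c_cog etc., the four dwell components are

    t0     = 1 / (a_c·v_cog + a_n·v_nea)
    t_non  = t0 · a_x / ω_off
    t_cog  = t0 · a_c · τ_cog
    t_near = t0 · a_n · τ_nea

and t_acc is their sum.  The codon elongation time adds 1/ω_proc; the
overall elongation rate is the inverse of the codon-usage-weighted mean
elongation time.  Zero cognate concentration with positive usage is a
hard error (the cycle cannot complete), not an infinity; zero-usage
codons are skipped.

Two independent oracles pin these closed forms.  The absorbing-chain
oracle builds the explicit 10-transient-state generator and solves the
occupancy system (−Q)ᵀx = e₀ **in exact rational arithmetic**: the
system's condition number grows without bound as rates spread over
orders of magnitude, and float LU (even with iterative refinement)
loses up to seven digits on the randomized test spans, whereas the
rational solve is exact for the given float rates.  The Gillespie oracle
draws exponential residences and categorical exits per state and is
bit-reproducible given a seed.

## Missense errors and selection efficiencies

Every completed cycle ends with exactly one accommodation, so the
probability that near-cognate species j (concentration c_j within the
near-cognate pool) is accommodated is its share of accommodation flux,
p_j = c_j·v_nea / (c_cog·v_cog + c_nea·v_nea) — manifestly independent
of the non-cognate concentration, which only delays the cycle.  The
species-level error frequency averages p_j over the species' near-cognate
codons with codon-usage weights normalized over that codon set.

The efficiency coefficients are defined here as branch-probability
ratios: initial selection is the cognate-to-near-cognate ratio of the
probabilities of reaching GTP hydrolysis after initial binding (with the
recognition loop resolved), proofreading the ratio of post-hydrolysis
accommodation probabilities.  Both equal one when the branches carry
identical rates.  The error-reduction factor between two rate sets
compares their error frequencies at identical (in-vivo) concentrations.

## Kinetic distance and constrained deduction

Barrier shifts are Δ = ln(ω_other/ω_reference); Δ > 0 means the rate is
larger than in the reference assay.  Attempt-frequency changes are
absorbed into Δ — no separate representation.  The distance is the
tie-weighted Euclidean norm over the 12 distinct coordinates
(multiplicities 3/2/2/2 for ω_off/ω_rec/ω_conf/ω_proc); changing the
reference assay is a Euclidean translation of the coordinates and
preserves all distances between fixed kinetics.

The deduction minimizes the weighted squared norm subject to
v(Δ) = v_target.  kon is **not** a free coordinate: in-vivo binding is
slowed by molecular crowding, and the default fixes kon_vivo at 54% of
the in-vitro value (configurable).  The optimizer is SLSQP with the
analytic objective gradient and finite-difference constraint gradients,
run from 10 starting points (Δ ~ U(−2, 2), seeded, plus the bracketing
point on the all-coordinates-equal ray); feasibility is pre-checked by a
sign change of the constraint along that ray within shifts of ±8.
Multistart solutions disagreeing by more than 1e-3 in any coordinate are
reported via `multistart_spread` (non-uniqueness diagnostic).  The best
solution is polished by a 1-D radial root solve onto the hypersurface,
bringing the relative constraint residual from optimizer tolerance to
machine precision; the polish is skipped for boundary minima, which are
flagged instead.  Free coordinates carry a wide default box (±20) purely
to keep the line search out of overflow territory.  Fixed coordinates
are honored and still contribute their tied weight to the reported
distance.  Tolerances: constraint residual ≤ 1e-8 relative (achieved
~1e-15), objective ftol 1e-14.

The processing-rate calibration exploits that t_acc does not involve
ω_proc, so the overall rate is strictly increasing in ω_proc with
supremum 1/⟨t_acc⟩; a bracketed Brent solve on log ω_proc finds the
unique root, and speeds at or above the supremum raise an
infeasible-speed error carrying the achievable bound.

## Temperature extrapolation

Transition-state theory with temperature-independent activation enthalpy
and entropy, anchored to a reference rate measured at both temperatures
(the cognate accommodation rate in the intended application), gives

    ω_i(T2) = ω_ref(T2) · (ω_i(T1)/ω_ref(T1))^(T1/T2)

after eliminating the enthalpy and dropping the entropy-difference term,
which is suppressed by the relative temperature difference (≈5.5%
between 293 K and 310 K, the defaults for the 20 °C/37 °C assay pair).
The construction is exact when rate and reference share an activation
entropy — the forward-generation oracle used in the tests.  The
association constant instead uses a plain Arrhenius factor with a
default activation energy of 2.4 kcal/mol for initial binding.

## Uncertainty propagation

Each in-vitro rate carries a relative error ε.  Over a chosen coordinate
subset (default: the three coordinates with the largest |Δ| at the mean
solution; full enumeration is available but costs 2^12 deductions) all
sign combinations ω(1 ± ε) define 2^m fictitious assays — the corners of
an error polyhedron.  The deduction is re-run from every corner; the
absolute coordinate error δΔ of each predicted rate is half the max–min
spread of ln(rate_corner/rate_mean) over corners, and the RSD of the
predicted in-vivo rate combines the two sources in quadrature,
RSD = √(ε² + δΔ²).  The quadrature combination and the log-spread
measure of the corner scatter are this package's concrete choices for an
interval construction that admits several arithmetizations.  ε ≥ 1 would
allow nonpositive corner rates; such factors are clamped to 1e-3 with a
warning.  Infeasible corners are excluded and reported.  kon is not
deduced, so its RSD is its in-vitro ε.

## Pulse-labeling time course

Ribosomes initiate on one mRNA species at a constant rate λ from time
zero (gene induction) — or as a single synchronized ribosome — and step
codon-by-codon at the codon-specific elongation rates.  Label (Met by
default) incorporated during the pulse window is counted either in all
peptide (nascent chains included, the TCA-precipitable default) or in
completed protein only.  The deterministic mode is the exact mean-field
solution: a ribosome initiating at s incorporates codon j at s + T_j
with T_j the cumulative mean stepping times, so each labeled codon
contributes λ·max(0, min(t, pulse_end) − max(pulse_start, T_j)) (with an
extra completion offset in full-length mode) — no ODE grid, no
discretization error.  The stochastic mode draws Poisson initiations and
exponential stepping times and averages seeded replicates.  Ribosome
exclusion (footprint collisions) is off by default; the mean-field
construction deliberately models independent ribosomes.

## Synthetic study conditions

The generator draws a decoding matrix (each codon one cognate species,
assigned cyclically so every species also has a cognate codon;
additional pairs near-cognate with probability 0.2), species
concentrations log-uniform on 0.1–10 µM (the magnitude range of E. coli
tRNA pools), codon usage from a symmetric Dirichlet (α = 5, mimicking
moderately uneven usage), and rates log-uniform within per-class bounds
that bracket the measured elongation-cycle values (fast binding,
recognition and GTPase steps in the 1e2–5e3 1/s range; slow near-cognate
forward steps below 10 1/s; processing 50–500 1/s).  These synthetic
conditions preserve the structural features the methods rely on —
competition between pools, strong branch asymmetry, tied rates — but not
the empirical codon–tRNA wobble topology, real abundances, or codon
usage of a genome; passing tests therefore demonstrate correctness of
the machinery on realistic magnitudes, not agreement with measured
E. coli data.  The bundled `paper_in_vivo_rates()` table carries the
published in-vivo rates for the four growth conditions;
`reconstructed_in_vitro_37c()` is a synthetic stand-in for the in-vitro
assay rebuilt from those published values and published scale factors,
suitable for demonstrations but not a transcription of measured data.

Problem sizes used by the default test run and the acceptance script —
100 randomized oracle instances, 1e5 Gillespie cycles, 40-codon ×
20-species conditions, 10 multistarts, 8 error-polyhedron corners, 400
stochastic time-course replicates — were chosen as the smallest sizes at
which the statistical checks (3-standard-error bands, 1e-9 oracle
agreement) are meaningful.

## Known limitations

- Internal rates are branch averages; codon-specific decoding or
  processing rates (e.g. inosine-wobble codons) are not parametrized.
- The crowding reduction of kon is a configuration parameter, not
  derived from a diffusion model.
- The error polyhedron is an interval construction, not a posterior;
  RSDs inherit its min–max character.
- The time-course model has no initiation bursting, ribosome collisions
  or drop-off; frameshifting and readthrough errors are out of scope.
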