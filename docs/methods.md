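# Methods

## Scope and model

`emuflux` quantifies how glucose carbon reaches nucleotides in
proliferating cells, through three routes that compete for glycolytic
intermediates: the oxidative pentose phosphate pathway (ribose of IMP and
UMP), the serine synthesis pathway through PHGDH (glycine and one-carbon
units of the purine ring), and the TCA cycle (aspartate carbons of the
pyrimidine ring).  The workflow mirrors a [U-¹³C]glucose tracing
experiment read out by LC-HRMS: steady-state mass-isotopomer distributions
(MIDs) constrain the fractional contributions at metabolic branch points,
and the stoichiometric matrix turns those fractions into fluxes relative
to the growth rate.

### The reference network is a reconstruction

The packaged network (`data/phgdh_nucleotide.net`, 19 reactions and
21 metabolites spanning the PPP, serine synthesis, a condensed TCA cycle
and nucleotide synthesis/salvage) is a reconstruction: only the pathway
coverage, the model size and the twelve reported flux groups of the
original study design are fixed by public information, so every other
structural choice is our own and is listed here.  All downstream machinery
is network-agnostic — a corrected reaction file can be dropped in without
code changes.

* **Glucose enters as G6P.**  Hexokinase is not resolvable from MIDs (an
  identity carbon map), so the tracer is applied directly at the G6P
  source pool.
* **Condensed TCA cycle.**  Citrate synthase + isocitrate dehydrogenase
  are lumped into one step (AcCoA + OAA → AKG + CO₂) and the oxidative arc
  AKG → succinate → fumarate → malate → OAA into another.  Both released
  CO₂ derive from OAA carbons, as in the first turn of the real cycle.
* **Symmetric intermediates.**  Succinate/fumarate scrambling is written
  as two half-weight atom-mapping variants of the return step (`TCA2`),
  expanded before EMU decomposition rather than special-cased in the
  solver.  This matters for which aspartate carbon is lost during UMP
  synthesis.
* **One-carbon overflow.**  Methylene-THF not consumed by purine synthesis
  or biomass leaves as formate (`FOR_EX`).  Without this valve the
  methylene-THF balance would pin the serine→glycine flux to exactly twice
  the IMP synthesis flux, and the experimentally central situation
  — nucleotide synthesis falls while serine→glycine does not — would be
  stoichiometrically impossible.  Formate overflow is well documented in
  proliferating cells.
* **CO₂ is an unlabeled, infinite source/sink.**  Refixed CO₂ (pyruvate
  carboxylase, carbamoyl phosphate) is therefore unlabeled; back-labeling
  through CO₂ is not modeled.
* **Irreversible net fluxes.**  Each arrow carries one net flux; exchange
  (reversibility) fluxes are out of scope.
* **Salvage sources.**  IMP and UMP salvage draw on unlabeled extracellular
  nucleosides (10 and 9 carbons), matching medium-supplied salvage
  substrates.
* **Biomass.**  Growth drains serine 0.30, glycine 0.45, one-carbon units
  0.05, aspartate 0.35, IMP 0.06 and UMP 0.05 per unit growth rate —
  magnitudes consistent with dry-mass composition (protein amino acids far
  exceeding nucleic-acid monomers).  Coefficients live in the network file
  and are overridable.

Open questions we deliberately did not guess at: the exact identity of the
original 21 metabolites, whether CO₂ was counted among them, and whether
CO₂ refixation was modeled.  The packaged file documents the choices made.

## EMU simulation and its oracle

Steady-state label propagation is solved by elementary-metabolite-unit
(EMU) decomposition: starting from the target fragments, the minimal set
of carbon subsets is traced backwards through the atom maps; fragments
assembled from several substrates become convolutions of smaller EMUs, so
the balances stratify by fragment size into a cascade of small linear
systems A(v)·X = B(v)·Y solved by dense direct factorization (systems here
have at most a few dozen unknowns; no sparse machinery is warranted).
EMUs are ordered lexicographically by (metabolite, positions) so matrices
are reproducible.  MIDs depend only on the *relative* producer fluxes of
each pool — scaling all fluxes leaves them unchanged — which the test
suite asserts as a property.

The oracle, `enumerate_isotopomers_bruteforce`, shares no code with the
cascade: it iterates the full positional-isotopomer balance over all 2ⁿ
labeling patterns per metabolite (Gauss–Seidel, tolerance 1e-15, feasible
up to ~12 carbons) and marginalizes to MIDs.  The two routes agree to
better than 1e-10 on five packaged toy networks (linear chain with
decarboxylation, two-input serine pool, mapping-reversal diamond, TCA-like
cycle with condensation and a symmetric intermediate, transketolase-like
two-substrate/two-product exchange) and on the full reference network.

Tracer purity defaults to 100% with no residual unlabeled substrate;
both are configurable.  Natural isotope abundance is *not* baked into
simulation — it is an explicit data-processing step (below).

## Reading branch ratios off MIDs

Each branch point's reporter relation is data, not code: `BRANCH` lines in
the network file declare how the producer shares are computed, so the
estimation math ships with the model it belongs to.

* **Closed-form ratios.**  Where one input is unlabeled medium supply, the
  share of the labeled route is a ratio of observables: de novo serine =
  L(SER)/L(3PG) (L = labeled fraction), glycine-from-serine = GLY m+2 /
  SER m+3, aspartate synthesis = L(ASP)/L(OAA), de novo IMP = L(IMP) /
  L(R5P⊗GLY⊗CH₂-THF⊗CH₂-THF) — the m+0 of a convolution being the product
  of the precursor m+0 values, the denominator needs only measured MIDs.
* **One-dimensional inversion.**  The pyruvate→OAA share sits inside the
  TCA label-recycling loop, where simple component ratios are biased by
  multi-turn label return.  The registry therefore declares a reporter
  observable (OAA m+3) whose EMU-predicted value is a monotone function of
  the single unknown share; the relation is inverted by a bracketed root
  solve (Brent, tolerance 1e-14) on [0, 1].  The same mechanism handles
  the UMP branch, whose de novo contribution needs the positional (not
  just mass) distribution of OAA.  This is still "ratios solved from MIDs
  at branch points" — one scalar equation per branch, no flux fitting.
* The glycine m+2/serine m+3 reporter is exact for an all-or-none labeled
  serine precursor (the case under [U-¹³C]glucose at full purity); the
  labeled-fraction reporters are exact under any tracer.
* OAA itself is used as the aspartate-branch precursor reporter.  In the
  synthetic setting its MID is available; on real data one would substitute
  malate, the conventional OAA proxy.

Degenerate inputs: reporter denominators below 1e-4 flag the branch
unidentifiable (the replicate is excluded from the estimate with a logged
reason); shares outside [0, 1] from measurement noise are clipped to the
boundary with a logged warning rather than discarding the replicate.

## Analytical flux solution

With biomass flux ≡ 1, the steady-state system S·v = 0 for the reference
network leaves six degrees of freedom — exactly one per registered branch.
The solver stacks the balance rows with the share constraints
v_i = r_i·Σ_j v_j and solves once by linear algebra (null-space
parametrization + least squares, which reduces to the exact solution when
constraints are consistent).  Underdetermined systems raise an error
naming the unconstrained branch pools; negative solved fluxes raise an
infeasibility error.  Replicates are solved independently; the estimate
reports their mean and standard deviation, and condition comparisons use
per-flux unpaired Student's t-tests with no multiple-testing correction
(deliberately, matching common practice for such panels).

The independent cross-check, `fit_fluxes_least_squares`, never touches the
reporter relations: it searches all branch shares at once (bounded
trust-region least squares, multi-start) to minimize the residual between
EMU-simulated and measured MIDs, then maps shares to fluxes.  On
noise-free data the two routes agree to ~1e-13 relative.

## Natural-abundance handling

Measured MIDs are corrected by inverting the theoretical convolution
matrix for ¹³C natural abundance (0.0107); a full-formula option also
folds in the +1/+2 isotopes of H, N, O, P and S.  Small negatives after
inversion are clipped and the MID renormalized.  The correction is ON by
default for measured (raw-normalized) data — fluxes at the few-percent
level are sensitive to ~1.1% ¹³C — and OFF for simulated data, which is
generated without natural isotopes.  Ingestion tolerates sum-to-1
deviations up to 1e-3 (instrument rounding); internally 1e-6 is enforced.
Normalization of raw intensities is fraction-of-total; the alternative
reading "labeled/unlabeled ratio" is not implemented.

## Kinetic flux profiling

Labeled-fraction time courses are fit to the single-pool first-order model
F(t) = F∞·(1 − e^(−kt)) — the canonical kinetic-flux-profiling form; F∞ is
the plateau enrichment and k the turnover rate constant (1/min), equal to
flux/pool size.  Initialization is deterministic (F∞₀ = max observed
fraction; k₀ = 1/t_half).  Fits are refused (status `no-labeling`) when
the maximum observed fraction is below 0.02, rather than returning an
arbitrary rate.  Relative turnover between conditions is (k_t·P_t)/(k_c·P_c)
when pool sizes are known, otherwise the bare k ratio with a logged
caveat.  Precursor-enrichment correction is off by default (raw fractions
are the conventional readout for these panels).  Rate-constant fits are an
extension of the steady-state analysis: they quantify the trajectories
rather than reproducing any published rate constants.

## Synthetic data generator

The generator defines the study conditions.  Ground truth is expressed as
the six branch shares (control: de novo serine 0.15, glycine-from-serine
0.45, aspartate synthesis 0.70, de novo IMP 0.85, de novo UMP 0.80,
pyruvate→OAA 0.25 of OAA production) and converted to a balanced flux
vector by the analytical solver; the inhibition scenario scales serine
synthesis ×0.5, PPP ×0.4 and TCA ×0.4 with serine→glycine ×1.0, then
rebalances uptake, salvage and formate-overflow fluxes to restore
S·v = 0 (salvage rises because biomass nucleotide demand is held fixed).

Noise is additive Gaussian on MID fractions, clipped at zero and
renormalized — the simplest model consistent with symmetric replicate
s.e.m. bars.  Scenario defaults are noise 0 (ground truth) with three
replicates; robustness studies set sd 0.01 explicitly, a typical replicate
scatter for fractional isotopologue measurements.  Time courses place t=0
at the tracer switch (exactly unlabeled, no noise there) and use pool
sizes chosen to give turnover times from minutes (3PG, OAA) to hours
(aspartate); reporters are each pool's dominant labeled species at steady
state — for the TCA pools these are m+3/m+4, because in a closed
glucose-carbon model the m+2 species seen transiently in real cells (and
sustained there by unlabeled anaplerotic inflows such as glutamine) vanish
once labeling completes.

What passing tests on this generator do and do not show: closure tests
prove the estimator inverts the simulator exactly — they validate the
math, not the biology; the noise study quantifies estimator variance and
bias under the stated noise model only.  Real data add peak-integration
artifacts, non-Gaussian and intensity-dependent noise, incomplete
metabolome coverage (no methylene-THF or OAA MIDs; proxies required),
natural-abundance residuals, and isotopic non-stationarity — none of which
the generator emulates.

## Numerical choices and known limitations

* MID sums are enforced to 1 within 1e-9 after simulation; entries above
  −1e-12 are clipped to zero.
* Replicate statistics at or below rounding level (std of bit-identical
  replicates) are snapped to exactly zero.
* The share inversion brackets on [1e-9, 1−1e-9]; at a share of exactly 0
  the recycling loop would have no labeled inflow and the balance would be
  singular.
* Ratio estimators are mildly biased under noise (Jensen-type bias of
  ratios of noisy observables, amplified by clip-and-renormalize for
  fractions near 0): at 1% fraction noise the grand-mean bias reaches ~5%
  for the smallest branch share (de novo serine), within the 10% band the
  robustness study targets but larger than its pure sampling error.  The
  least-squares refit shares the property.
* Non-stationary (time-resolved) EMU simulation, reversible-flux
  estimation, confidence intervals by profile likelihood, and absolute
  flux calibration (mol/cell/h) are out of scope.
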