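# Methods

## The model

`cellecon` implements a coarse-grained whole-cell model of bacterial gene
expression as a coupled ODE system.  One lumped cell carries five native
transcription units — metabolic enzymes **E**, bulk housekeeping protein
**Q**, RNA polymerase **P**, ribosomal protein **R** and the rRNA operon
**rrn** — plus any number of heterologous circuit genes.  The model encodes
five constraints: finite biosynthetic capacity supplied by a one-step
metabolism; competition of all genes for a shared RNA-polymerase pool and of
all mRNAs for a shared ribosome pool; autocatalytic resource biosynthesis
(polymerases and ribosomes are themselves gene products); growth-rate
feedback through dilution and gene-dosage expansion; and a single global
regulator, the charged/uncharged tRNA ratio

    theta = t_c / t_u,

a proxy for (the inverse of) the alarmone ppGpp.

**Metabolism.** External substrate S is imported at rate
`v_E * S * p_E / (kappa_E + S)` per cell and converted to an internal
precursor pool M (amino acids/nucleotides/energy, lumped) with yield `phi`
— the nutrient-quality dial.  M drives tRNA charging
(`v_T * p_E / (1 + K_u/t_u + K_M/M)`), transcription elongation and, when a
product pathway is attached, product synthesis.

**Gene expression.**  Promoter–RNAP and mRNA–ribosome binding are assumed
fast (quasi-steady state), so complex abundances are algebraic:

    k~_j = K_jX * P_tot / (1 + sum_i K_iX),  K_jX = g_j R_j kp_f / (kp_r + tau_j + k_rf)
    c~_j = K_jL * R_tot / (1 + sum_i K_iL),  K_jL = m_j kr_f / (kr_r + gamma_j + k_cm)

The rRNA gene competes for polymerase but never for ribosomes.  Elongation
saturates in the driving pool: `tau_X(M) = tau_max * M / (K_tau + M)` (a
gene of n codons completes mRNAs at `tau_X / 3n`), and
`gamma_X(t_c) = gamma_max * t_c / (K_gamma + t_c)` (protein completion at
`gamma_X / n`).  Growth is total translational flux over cell mass:

    lambda = gamma_X(t_c) * sum_j c~_j / M0.

**Regulation.**  Four classes: housekeeping genes self-limit through
`R_Q = 1 / (1 + (p_Q/kappa_q)^h_q)`; resource genes (P, R, rrn) are
activated when charging outpaces demand, `R = theta / (theta + kappa_theta)`;
enzymes are activated by the complementary factor
`R_E = kappa_theta / (theta + kappa_theta)`; circuit genes carry the
enzyme-type factor scaled by an induction input `u` in [0, 1].  The knob
`D_g` rescales theta before all regulation functions, emulating
alarmone-pathway mutants.

**Ribosome assembly.**  Free rRNA (r) and free r-protein (p_R) associate at
`beta_rho * p_R * r` into functional ribosomes R_tot, which disassemble at
`mu_rho * R_tot`.  Gene dosage expands with growth as
`g_j = g0 * exp(q_x * lambda)`; the rRNA dosage is additionally scaled by
`D_r` (rrn-deletion/amplification strains).

**Antibiotics.**  `k_rf` (rifampicin-like) moves RNAP into an inert pool
P_ab; `k_cm` (chloramphenicol-like) moves ribosomes into R_ab.  Sequestered
pools dilute but never reactivate.

**Cultures.**  `single_cell` freezes S and N (mid-exponential growth at
fixed substrate); `batch` depletes a finite S while N grows; `chemostat`
feeds substrate at `k_in` and dilutes at `delta`, so a surviving culture
settles where `lambda = delta`.

## Units and default parameters

All intracellular species are molecules per cell, rates are per hour, and
M0 is in amino-acid equivalents per cell.  The external substrate has its
own arbitrary "medium units" (kappa_E merely sets the half-saturation
scale; the default kappa_E = 1e9 keeps the chemostat substrate balance
well-conditioned).

The shipped default cell is this package's own parameterization, assembled
from E. coli ballparks and then balanced so that the unperturbed cell grows
at ~1/h with a realistic proteome partition (about 26% ribosomal, 21%
enzyme, 48% housekeeping, 5% RNAP by mass) and sustains chemostat dilution
rates of 0.1–0.5/h.  Headline values: `gamma_max` 72 000 aa/h (20 aa/s),
`K_gamma` 3e5; `tau_max` 1.8e5 nt/h (50 nt/s), `K_tau` 1e6; `tau_r_max`
3.06e5 nt/h (85 nt/s) over a 4566-nt operon; mRNA decay `delta_m` 6/h
(~7 min half-life); `psi_max` 1.3e6 tRNA/h against a tRNA pool of ~1e6;
`M0` 2e8 aa; dosage expansion `q_x` 0.35/h; `kappa_theta` 2 so that the
regulation point theta* ≈ 1.5–3.3 sits on the responsive part of the
curves.  Gene lengths: E 400 aa, Q 300 aa, P 3400 aa (RNAP core), R 7500 aa
(summed r-proteins), rrn 4566 nt.  Circuit genes default to reporter size
(240 codons) on a 10-copy plasmid with the enzyme gene's binding kinetics,
so isocost slopes reflect induction rather than hidden kinetic asymmetries.

## Design choices where the formulation was open

- **Peptide elongation argument.**  `dp_j/dt` uses `gamma_j(t_c)`; the
  elongation rate is defined on charged tRNA, not on M.
- **rRNA elongation.**  The default follows the rRNA balance as written,
  `dr/dt = tau_r(M) * k~_rrn`, i.e. rRNA chain growth shares the metabolite
  saturation of mRNA elongation (`rrna_elongation_M_dependent = True`).
  This choice is load-bearing: with a metabolite-independent rRNA rate,
  slow (nutrient-poor) cultures over-produce rRNA relative to everything
  else — mRNA synthesis is M-starved while rRNA is not — and the
  steady-state response of circuit output to rRNA dosage D_r at 0.1/h
  vanishes or inverts.  With the M-dependent rate the response is monotone
  increasing at both 0.1 and 0.5/h.  The constant reading
  `tau_r = tau_r_max / n_r` remains available via the switch.
- **Circuit gene dosage.**  Plasmid copy number does not follow the
  replication-associated expansion `exp(q_x lambda)` (switch
  `circuit_copy_expansion`); growth-decoupled plasmid dosage is also what
  keeps reporter output falling with dilution rate.
- **D_g placement** multiplies theta before every regulation function;
  D_psi and D_gamma multiply psi_max and gamma_max.
- **Q-gene feedback** carries a configurable Hill exponent `h_q`
  (default 1, the literal reading).
- **theta at t_u -> 0** floors t_u at 1e-9 molecules inside the ratio only,
  keeping the RHS finite at integrator trial points.
- **Negative round-off states** are clipped to zero inside the rate laws; a
  warning fires once per model if any state falls below -1e-6.
- **p_Q in R_Q** counts only free Q protein (complexes are polymerase- and
  ribosome-bookkeeping, not protein bookkeeping).

## Simulation and steady states

Trajectories use SciPy's stiff LSODA with rtol 1e-7 (1e-6 for user-facing
`integrate`).  Steady states follow a horizon-doubling protocol: integrate
100 h, test `max |dy/dt| < 1e-3`, double the horizon (cap 1e6 h) until the
criterion holds.  Two accelerators sit on top, both required to pass the
same derivative criterion, so they change cost, not semantics:

- a **Newton polish** in log space (scipy `root`/hybr on `f(x)/x` over the
  non-frozen, non-structurally-zero species; structurally-zero species —
  sequestered pools without antibiotic, circuit genes at u = 0 — are pinned
  exactly);
- a **chemostat shortcut**: at an interior chemostat fixed point the
  intracellular state equals the single-cell fixed point at the residual
  substrate S*, so S* is found by a 1-D bracketing search on
  `lambda(S*) = delta` over cheap single-cell solves and N* follows from
  the substrate balance `k_in = import(S*) N* + delta S*`.  Washout (no
  bracket, or N* <= 0) falls back to time marching.

Sweeps warm-start each grid point from its neighbour.  Non-converged points
are flagged and excluded from fits, never silently used.  Batch cultures
have no fixed point and are rejected by the steady-state solver.

Steady-state integration legs request endpoint-only output; storing dense
trajectories over ~1e6 h horizons is a memory hazard.

## Mass fractions

`Phi_class = n * copies / total`, where copies count free protein plus
antibiotic-sequestered pools, and the ribosomal class counts the r-protein
content of assembled (and sequestered) ribosomes plus free r-protein.
Fractions sum to one by construction.

## Calibration

Growth rate is varied in the exponential regime through `phi` (nutrient
quality) and `k_cm` (translation inhibition); each condition yields
(lambda, Phi_R, Gamma = gamma_X, theta).  Observed tables are compared
condition-by-condition (each data row carries its phi/k_cm coordinates,
so the pairing is defined by the table itself) through normalized sums of
squared errors
`sigma = sum((sim-exp)^2) / sum(exp^2)` and the weighted cost

    cost = 10 sigma_lambda,DB + 5 sigma_lambda,Scott + 5 sigma_R,Scott
         + sigma_R,DB + sigma_Gamma,DB + sigma_theta,DB.

Fitting uses a hand-rolled gbest particle swarm (inertia 0.729, cognitive
and social weights 1.49, reflective bounds), 500 particles x 500
generations by default; candidates whose simulations fail or drop
conditions receive a finite penalty cost of 1e6 so the swarm survives.
Runs are deterministic given the seed.

The synthetic-data generator simulates a condition grid from known "true"
parameters and applies multiplicative Gaussian noise `(1 + sd*Z)` clipped
at zero.  It emulates growth-law tables (magnitudes, trends and their
condition coordinates); it does **not** emulate real measurement error
structure (correlated errors, condition-mapping uncertainty, model
misspecification), so parameter-recovery tests demonstrate identifiability
of the cost, not accuracy on laboratory data.  Default recovery conditions:
phi in {0.3, 0.5, 0.7, 1.0} at k_cm = 0, spanning growth 0.3–1.0/h.

## Protein-production capacity (FBA/FVA)

Networks are `cobra.Model` objects (SBML/FBC ingestion, LP and FVA through
cobrapy).  `add_protein_demand` appends a translation-demand reaction
consuming the protein's amino-acid composition plus `gtp_per_bond * (L-1)`
GTP (hydrolysed to GDP + Pi + H; default 2 per bond — EF-Tu delivery plus
EF-G translocation — configurable, since translation-energetics bookkeeping
conventions differ), producing one pseudo-metabolite `protein_c` with a sink.
Maximal protein flux is the LP optimum with the carbon exchange bounded in
the uptake direction and the biomass reaction *fixed* (equality) at each
grid value; infeasible combinations are reported as such, never as zero.
FVA holds the protein objective at its optimum and classifies a reaction as
flexible when |max - min| > 0.001 mmol/gDCW/h.  Subsystem net flux is the
signed sum over each subsystem's reactions, with a companion sum restricted
to inflexible reactions.  Subsystem labels round-trip through SBML as group
annotations, with group members serialized in sorted order so repeated
writes are byte-identical.

The toy fixture stands in for a genome-scale reconstruction: rich and poor
carbon sources yield 2 and 1 precursor per unit of uptake, a two-branch
parallel motif provides a known flexible set, and all twenty amino acids
plus GTP are derivable, so optima are hand-computable:
`protein_flux = (yield * uptake - biomass) / (L + g(L-1))`.  A
deterministic synthetic 239-residue GFP-sized sequence (random canonical
residues behind a fixed seed, initial Met) serves as the demand protein;
only length and composition arithmetic enter the stoichiometry.

## Known limitations

- The model is deterministic and spatially homogeneous: no stochastic gene
  expression, no explicit ppGpp species, no stress-response regulon.
- Default parameters are this package's own balanced set, not a fit to
  any laboratory dataset; absolute molecule counts are indicative only.
- In chemostat mode the residual-substrate feedback (lambda pinned at
  delta) compensates perturbations most strongly at slow growth.  Two
  consequences, verified over wide parameter scans: the relative response
  of circuit output to rRNA dosage D_r is somewhat *larger* at 0.5/h than
  at 0.1/h (both monotone increasing), and reducing the tRNA supply D_psi
  leaves the ribosomal mass fraction essentially flat (slightly falling)
  rather than rising, although circuit output falls as expected.
- Per-cell pathway product X* = flux/lambda rises monotonically and
  saturates as growth slows; this parameter family produces no interior
  maximum at very low growth rates.
- Peptide elongation gamma_X decreases mildly with dilution rate in the
  chemostat (charged tRNA accumulates when few ribosomes translate); in
  the phi-varied exponential regime used for calibration, faster-growing
  cells do have more charged tRNA in absolute terms, but Gamma still
  declines with growth there.  Treat Gamma trends from this default cell
  with care.
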