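# Methods

## Decision model

Individuals sit on an undirected weighted contact network; edge weight
w_ij is the closeness (interaction frequency) of the pair. Each holds a
binary vaccination decision d_i ∈ {+1, −1}. One iteration updates every
node once through three stages.

**Cost minimization.** The perceived infection risk is
λ_i = β_perc · n_unvac/(n_vac + n_unvac), the perceived transmission rate
scaled by the *unweighted* fraction of unvaccinated neighbors. The
individually optimal choice accepts vaccination when λ_i > r (with
r = c_vac/c_inf the cost ratio), rejects when λ_i < r, and keeps the
previous decision at an exact tie (compared with exact floating-point
equality; the tie is a real model feature, not a numerical guard — it is
what lets a fully protected individual free-ride at r = 0). Whether risk
perception should weight neighbors by closeness is a genuinely open
design point; the unweighted count is the default because risk here is a
prevalence estimate, not an influence measure. A weighted variant can be
obtained by passing a closeness-weighted neighbor fraction through the
same threshold rule.

**Social impact.** Camp o with n_o neighbor sources of total closeness
W_o exerts impact I_o = W_o / n_o^(1−a) with source-count exponent
a = 0.5 by default: impact grows with the number of sources at a
square-root diminishing rate and linearly with mean closeness, the
classic social-impact scaling. a is configurable (`sit_exponent`; a = 1
gives plain weighted sums) because the precise functional form is the
one place where reasonable formulations differ. The discrepancy is
normalized relatively, Δ = (I₊ − I₋)/(I₊ + I₋) ∈ [−1, 1], making the
Fermi responsiveness κ comparable across networks with different weight
scales. The social opinion is +1 with probability 1/(1 + e^(−Δ/κ)).
κ defaults to 0.1: sharp enough that a clear majority dominates
(q ≈ 1 at |Δ| = 1), soft enough that near-balanced neighborhoods stay
stochastic.

**Conformity.** With probability p the individual adopts the social
opinion, else the cost choice. Isolated nodes have no opinion sources and
always keep the cost choice (the loader accepts them; the generator never
produces them).

## Update scheme and steady state

The default scheme is **asynchronous random-order**: each iteration
permutes the nodes and updates them in place, so later nodes see earlier
nodes' fresh decisions. A fully synchronous scheme is provided
(`update_scheme="synchronous"`) but is not the default for a structural
reason: under synchronous updating the pure-cost dynamics (p = 0)
overshoot globally — everyone vaccinates, perceived risk collapses to
zero, everyone abstains, and the population locks into a parity 2-cycle
whose average coverage is ≈ 0.5 for every cost ratio below β_perc. That
artifact erases the cost–coverage relation the model exists to study.
Asynchronous updating removes it: p = 0 coverage then declines smoothly
with r (≈ 0.97, 0.71, 0.52, 0.36, 0.14, 0 at r = 0, 0.1, …, 0.5 on the
high-school preset), consistent with best-response dynamics settling near
the mixed equilibrium where the marginal individual is indifferent
(coverage ≈ 1 − r/β_perc).

Termination: at p = 0 a full update that changes no decision is a Nash
fixed point and stops the run (the synchronous map additionally detects
2-cycles, reported with cycle-averaged coverage). Stochastic runs
(p > 0, and asynchronous p = 0 runs that keep churning near the mixed
equilibrium) run a fixed horizon of `max_iters = 200` iterations and
report coverage as the mean over the final `window = 50`; on the 800-node
preset trajectories settle well within 100 iterations, so the window
averages a stationary stretch.

Randomness is consumed in a documented fixed order per iteration — node
permutation (asynchronous only), then one uniform per node for the
social-opinion draw, then one per node for the conformity draw, the last
two skipped entirely at p = 0 — so every run is exactly replayable from
its seed, and synchronous p = 0 runs are deterministic given the initial
state alone.

## Defaults and their provenance

| parameter | default | meaning / rationale |
| --- | --- | --- |
| γ | 0.312 / day | recovery rate; 3.2-day infectious period (influenza-like) |
| R₀ | 1.4 (sensitivity {1.2, 1.6, 2.0}) | 2009 H1N1-range reproduction number |
| β_perc | R₀·γ = 0.4368 | perception matches the actual transmission rate |
| r, p | grids 0…1, step 0.1 | full decision-regime sweep |
| w0 | {0.3, 0.5, 0.7} | initial willingness levels |
| κ | 0.1 | sharp-but-stochastic opinion dominance |
| replicates | 50 per cell | coverage standard errors below ~0.02 |
| I₀/N | 10⁻⁴ | epidemic seeding fraction |

## Synthetic contact network

The generator emulates a dense, clustered school proximity network from
its two published first moments — mean degree 35 and mean edge weight
115. Topology: a connected Watts–Strogatz ring lattice with ring degree
2⌊d̄/2⌋ and rewiring probability 0.1, topped up with uniformly random
extra edges so the realized mean degree equals the odd target exactly;
uniform-random and preferential-attachment topologies are available for
robustness checks. Weights are i.i.d. log-normal with the log-scale σ
fixed at 0.8 (heavy-tailed, as contact-frequency counts are) and the
log-mean solved so the distribution mean equals the target. The preset
uses 800 nodes; the node count is configurable because only the degree
and weight means of the emulated network are published.

What the generator does **not** emulate: the real network's degree and
weight dispersions, its community structure (classes, cliques), and any
degree–weight correlation. Tests passing on this preset therefore show
the model's mechanisms behave correctly on a dense clustered substrate —
not that coverage values transfer quantitatively to any particular real
school.

## Epidemic module

SIR with homogeneous mixing, force of infection βI/N, no demography.
Vaccination is all-or-nothing and perfectly immunizing: a coverage V
removes VN individuals from the susceptible pool before integration, so
S + I + R = (1−V)N is conserved (checked to 10⁻⁶N along every
trajectory). Integration uses an adaptive LSODA solve at relative
tolerance 10⁻⁸; the horizon starts at 500 days and doubles until the
infectious compartment falls below min(10⁻⁶N, I₀/2), after which the
still-infectious remainder is counted as eventually recovered. The attack
rate R(∞)/N includes the seeded infections.

The analytic cross-check solves the final-size relation
z = 1 − exp(−R₀(1−V)z) for the attack fraction among the unvaccinated by
damped fixed-point iteration (tolerance 10⁻¹⁰), returning (1−V)z, and 0
in the subcritical regime. The ODE-versus-analytic comparison in the
tests uses a seeding fraction of 10⁻⁷: near the threshold the ODE's
minor-outbreak size scales like I₀/(N(1−R_eff)), so any appreciable seed
would dominate the comparison for reasons unrelated to solver accuracy.
Threshold-behavior checks use the scenario seeding 10⁻⁴.

## Sweep protocol

Per cell (r, p, w0, R₀): `replicates` independent runs, each seeded from
`SeedSequence(base_seed, spawn_key=(ri, pi, wi, Ri, rep))` so any cell is
reproducible in isolation; mean coverage and its standard error are
aggregated, and the attack rate is computed at the cell's *mean* coverage
(per-replicate coupling behind `per_replicate_attack=True`). With the
default β_perc = R₀·γ coupling, decisions are re-run per R₀; with a fixed
β_perc the decision runs are shared across R₀ values. Failed replicates
are logged and marked, never silently dropped.

Test-suite and example sweeps use reduced problem sizes (60–200-node
networks, 5–10 replicates, 40–100-iteration horizons) — the package's
choice of desk-scale defaults for its own verification; the behavioral
conclusions they check are grid orderings and invariances, not absolute
coverage values.

## Known limitations

- Social influence is strictly local (no media/super-node, no influence
  beyond direct neighbors) and individuals are passive recipients of it.
- Disease transmission is homogeneous-mixing; the contact network shapes
  decisions only. Coupling transmission to the same network would lower
  attack rates relative to the well-mixed estimate at equal coverage.
- No season-to-season memory, waning immunity, or imperfect vaccines.
- The tie rule compares λ_i = r with exact equality; parameter choices
  that make ties measure-zero (generic β_perc) keep it inert except at
  the designed r = 0, λ = 0 free-riding case.
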