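# Methods

## The reduced proteostasis network

The model tracks one client protein species moving through the *E. coli*
proteostasis machinery. All reactions are elementary mass action in uM and
seconds; ATP and ADP are assumed saturating, so nucleotide state is carried
by species identity (`K_T` vs `K_D` for DnaK, `GrL_T` for ATP-bound GroEL).

**Client core.** U&harr;N (`k_fold`, `k_unfold = k_fold/K_fold`) and
U&harr;M (`k_mis`, `k_unmis = k_mis/K_mis`). The four built-in profiles
(default, slow folder, bad folder, aggregator) specify the six client
parameters (`k_fold`, `K_fold`, `k_mis`, `K_mis`, `k_ag`, `c_crit`); all
describe kinetically frustrated clients whose misfolding flux exceeds the
folding flux, differing in trap stability, folding speed and aggregation
propensity.

**Synthesis / degradation.** Bulk synthesis is zeroth order in client:
r_syn = (ribosome activation rate) × [Rib]. Degradation goes through Lon
binding and a committed proteolysis step into a bookkeeping `Null` species.
`Null` closes degradation to re-synthesis so a tagged molecule has
continuous dynamics: its tagged exit rate is r_syn / max([Null], 1e-6 uM).
Lon binds both unfolded and misfolded client by default
(`lon_binds_misfolded`); with only U degradable, a misfolded molecule could
never be degraded without first passing through the unfolded state, and the
degradation-plus-resynthesis correction channel would be topologically
empty. The flag restores the U-only topology when disabled.

**Aggregation.** Nucleation 2M&rarr;A&#8322; and growth
A&#8345;+M&rarr;A&#8345;&#8331;&#8321; at `k_ag`, reverse at
`k_dis = k_ag·c_crit`, with a reflecting cap at `n_max` (default 20; states
beyond the cap are not modelled, so runaway aggregation piles mass into the
largest size — adequate because analyses condition on the tagged molecule,
not on aggregate-size statistics). Only M aggregates; direct U aggregation
is not modelled.

**KJE.** DnaK(ATP) binds U or M; bound M is actively unfolded
(`k_kje_unfold`); the U-complex binds dimeric DnaJ, hydrolyses ATP, releases
DnaJ, and a GrpE-catalysed exchange step releases unfolded client and resets
DnaK. DnaJ totals are monomer concentrations; the functional species is the
dimer J2 (conservation weight 2).

**GroELS.** GroEL(ATP) binds U or M, GroES caps the cis cavity, the cis
client interconverts U/N/M at bulk rates, and a timed step (`k_cycle`)
releases cap and client. With `double_occupancy` a second client may bind
the open trans ring; on cis release the trans client becomes the new cis
client. No conformational conversion of the trans-bound client is modelled
(it is held, not encapsulated).

**B+KJE.** Aggregate preparation consumes one DnaK and one DnaJ dimer
(termolecular mass action, `k_prep`), ClpB extraction returns them and
releases one monomer as U, leaving A&#8345;&#8331;&#8321;; the dimer case
A&#8322;* yields one U and one M. The sequestration of DnaK/DnaJ on prepared
aggregates couples disaggregation load to KJE capacity.

**Trigger factor** is a pure holder (U + TF &harr; TF:U); it is never a
mediator of conformational transitions and is excluded from pathway
analyses by construction (its complexes are entered only from U).

### Parameter defaults

The six client parameters come from the built-in profiles and the chaperone
totals (Rib 20, TF 20, DnaK 30, DnaJ 1, GrpE 15, GroEL 42, GroES 35,
Lon 0.3, ClpB 1.8 uM) are geometric-average literature values for the
*E. coli* cytosol. Every remaining rate constant is a package default,
chosen once from literature-plausible ranges so that the canonical network
exhibits the known qualitative physiology — KJE-dominant correction of the
default client at low synthesis, chaperonin-dominant correction for the
slow folder, a shift of clearance toward disaggregation as synthesis (and
hence aggregate load) rises — and every constant is overridable through the
`overrides` map. Notable choices:

* DnaK association is slow (`k_km_on` 0.1, `k_ku_on` 0.03 uM&#8315;&sup1;s&#8315;&sup1;,
  ~1e5 M&#8315;&sup1;s&#8315;&sup1;), GroEL association faster for the
  hydrophobic misfolded state (`k_gm_on` 0.4) than for nascent unfolded
  chains (`k_gu_on` 0.03). This reproduces the observed pattern that the
  chaperonin's entrance rate from M exceeds DnaK's while its committor to
  the unfolded state is far smaller for fast-misfolding clients.
* `k_kje_unfold` 0.1 s&#8315;&sup1; against `k_km_off` 0.3 s&#8315;&sup1;
  gives a DnaK-bound-M correction committor of 0.25.
* `k_cycle` 0.3 s&#8315;&sup1; (a few seconds per chaperonin cycle): a
  default-client molecule converts M&rarr;U inside the cavity in only ~3% of
  cycles (k_unmis = 0.01 s&#8315;&sup1;), whereas the slow folder
  (k_unmis = 10 s&#8315;&sup1;) converts almost every cycle — the origin of
  its chaperonin preference.
* Lon is slow and scarce (`k_lon_cat` 0.02 s&#8315;&sup1;, 0.3 uM), so
  degradation caps at ~6e-3 uM/s and the degradation channel is a
  percent-level contributor.

The default ribosome activation rate is 1e-4 s&#8315;&sup1; (r_syn = 2e-3
uM/s); sweep grids default to four decades, 1e-7–1e-3 s&#8315;&sup1;,
log-uniform.

## Bulk integration

`propagate` integrates the mass-action ODEs with BDF and an analytic
Jacobian assembled from the stoichiometry (rate constants span more than
six orders of magnitude, so the system is stiff). Defaults: rtol 1e-8,
atol 1e-12 uM, logarithmic output grid ending exactly at the analysis time
t_eval (default 1e4 s, by which non-aggregating configurations are near
steady state). Chaperone conservation groups are exact linear invariants;
their drift is monitored and stays at roundoff (~1e-14 relative). Species
belonging to a conservation group whose total is zero (knocked-out systems)
are projected to exactly zero after integration, since they are
mathematically zero and would otherwise carry integrator noise at the
absolute-tolerance scale. Tiny negative values within 1e-9 uM are clamped
to zero on read. Steady state is always approached by integration; there is
no root-finding.

## The tagged rate matrix

Each bulk reaction carries *tagged moves* recorded at build time: the
transitions available to one tracked client molecule, with partner
concentration factors. Freezing at the analysis time gives K with the
column convention K[i,j] = rate j&rarr;i and diagonal set to the negative
column sum (columns sum to zero at roundoff). Specifics:

* Bimolecular steps with non-client partners use k·[partner](t).
* Client–client aggregation is linearised with the bulk concentration: the
  tagged monomer nucleates at k_ag·[M](t) and joins A&#8345; at
  k_ag·[A&#8345;](t); no combinatorial factor of two is applied to the
  self-reaction (the frozen-concentration convention).
* Monomer loss from an aggregate of size n (dissolution or ClpB
  extraction) carries the tagged monomer with probability 1/n; the
  remaining (n-1)/n stays in the shrunken aggregate.
* Doubly occupied chaperonin complexes split into a cis-tagged and a
  trans-tagged state, the untagged partner written lowercase. A tagged
  client binding the trans ring of a singly occupied complex distributes
  over the possible cis partners with bulk-composition weights
  k_on·[GrLd:{X}:GrS](t).
* The tagged re-synthesis rate Null&rarr;U is r_syn / max([Null](t), 1e-6).

With all systems enabled the tagged chain is irreducible, and at bulk
steady state the vector of per-position client concentrations lies in the
kernel of K; the stationary distribution of K therefore matches the
normalised concentrations (verified to ~1e-9 on a non-aggregating
configuration — the check uses a profile with K_fold = 100 and t_eval =
1e6 s so the slow native-pool mode, relaxation rate k_unfold, is fully
equilibrated within a short run).

## Committors, conditional committors, channels

Discretisation: &tau; = 1/(2·k_max) with k_max the largest total exit rate,
T = I + &tau;K. The factor 1/2 keeps diagonals &ge; 1/2 (aperiodicity);
absorption probabilities are &tau;-independent, and halving &tau; changes
committors and channel probabilities by < 1e-9 in practice. Committors are
computed by installing unit-column sinks at A and B and squaring the
modified matrix until non-sink mass falls below 1e-12 (&le; 200 squarings;
~30 on the shipped configurations — squaring reaches horizon 2^m in m
multiplications, which tames the slow modes such as the native pool's
1e-5 s&#8315;&sup1; exit). A direct linear solve of the committor system is
available as an independent route and agrees to ~1e-12.

Conditional committors use the doubled space (state, visited-C flag), flag
set on first entry into C, sinks at A and B in both ensembles; h and h&#773;
are the absorbed-at-B masses of the two ensembles and satisfy
h + h&#773; = q_B. Mediation probabilities average h over the first-jump
distribution out of the source, counting a first jump into C as a visit.

**Entry-channel decomposition.** Reactive source&rarr;target paths are
classified by the edge through which they first enter the target: direct
conversion edges from bare conformers, KJE release edges, GroELS release
edges, ClpB extraction edges, and the re-synthesis edge from Null. The
classification is exhaustive and mutually exclusive by construction, so
channel probabilities sum to one without any tie-breaking rule for paths
that touch several systems. Trigger-factor and Lon release edges form
structurally empty channels (their complexes are entered only from the
target itself). Mediation by visitation and the entry-edge channel agree
exactly whenever a system's release edges are its only exits toward the
target; on the full network a chaperonin-visiting path can fold in the
cavity, be released as N and enter U through the N&rarr;U edge, so the
GroELS mediation probability slightly exceeds the GroELS channel
probability. The entry-edge convention is the headline decomposition
because it is exact and exhaustive.

Fluxes weight the per-channel absorption probabilities by the source
concentration and outflow rates; for folding (U&rarr;N) the direct channel
flux reduces identically to k_fold·[U](t).

The constant-rate-matrix assumption (K frozen at t_eval) is checked by
recomputing the decomposition from K(2·t_eval); on the default
configuration the largest channel-probability shift is ~1e-4. In runaway
aggregation regimes the shift can be large; the check reports, never
asserts.

## Pseudo-trajectory sampler

Jump-chain sampling on K: next state proportional to off-diagonal column
rates, holding times exponential with the total exit rate (recorded but not
needed for absorption statistics). Paths start from the source's
rate-weighted first-jump edge, are absorbed at sink sets, and carry a
visited-set bitmask for mediator counting; a 1e6-step cap flags truncation.
Each path draws from a Philox stream keyed (seed, path index), so any
prefix of a batch is reproducible independently of batch size. At 1e5
paths, channel fractions, the reactive fraction and mediation probabilities
agree with the matrix engine within three binomial standard errors.

## Experiments

`run_sweep` executes build&rarr;integrate&rarr;freeze&rarr;decompose over a
grid of one parameter (ribosome activation rate, binding factor &lambda;,
or chaperonin capacity factor g) for any profile set, stacking tidy rows;
failed grid points are flagged and skipped, and the CLI writes every run's
fully resolved configuration beside its outputs. The binding factor
multiplies GroEL on-rates and divides DnaK on-rates; the capacity factor
scales total GroEL/GroES. Knockouts zero a system's chaperone
concentrations, leaving the reaction list intact. Substrate classification
uses the free native concentration at t_eval: class III if the yield at the
lowest capacity falls below &theta; = 0.5 (configurable) of the
full-capacity yield, class I/II otherwise.

What the shipped conditions show: the KJE/B+KJE usage ratio across a
synthesis sweep of the default, bad-folder and aggregator clients is
proportional to [M]/[aggregated monomers] (R&sup2; &approx; 1.0, slope
&approx; 21 under the default constants) — usage of the two unfolding
machines tracks the substrate pools they draw from; knocking out GroELS at
high synthesis raises B+KJE clearance flux ~4-fold while free native
protein barely changes, illustrating why concentration-level knockout
observables miss chaperone usage; and sweeping &lambda; over 1/2–8 moves
the preferred correction pathway from KJE to GroELS with the crossover near
&lambda; &approx; 2.6.

## Numerical conventions and edge cases

* Committor boundary values are pinned exactly (q_B = 1 on B, 0 on A;
  h&#773; = 1 on B) after absorption.
* Reducible generators (multiple recurrent classes) raise a dedicated
  error from `stationary_weights`; trap states that prevent absorption are
  reported with the trapped-state list after 200 squarings.
* The stationary vector is obtained by replacing one balance row with the
  normalisation constraint plus one step of iterative refinement, which
  keeps componentwise accuracy on stiff generators where an SVD null space
  loses the small weights.
* Zero reactive probability (every path returns to the source) is flagged
  as an error rather than returning undefined channel fractions.
* A knocked-out system keeps its states; all rates into them are exactly
  zero.

## What the defaults do and do not show

The default conditions are a self-contained, desk-scale parameterisation of
the canonical network, not a fit to any specific proteome-scale dataset:
absolute concentrations and fluxes should be read as order-of-magnitude
physiology, while the *relative* statements (which system mediates which
transition, how preferences shift with synthesis rate, binding factors,
capacity and knockouts) are the quantities the machinery is designed to
compute and are insensitive to the discretisation and solver settings, as
the invariance and oracle checks in the test suite demonstrate. Known
limitations: no co-translational folding detail, no ATP depletion, no
competition from the background proteome (single client only), no
positional structure within aggregates beyond the 1/n rule, and a
reflecting aggregate-size cap.
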