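# proteopath

Kinetic modelling and transition-path analysis of the *E. coli* proteostasis
network for a single client protein.

## The problem

Cells keep their proteins folded with a network of chaperones. In *E. coli*
three ATP-driven systems act on a misfolding-prone client: the DnaK/DnaJ/GrpE
cycle (**KJE**, an Hsp70 system that binds unfolded or misfolded protein and
releases it unfolded), the GroEL/GroES chaperonin (**GroELS**, which
encapsulates a client in a folding cavity and releases it on a timer), and
ClpB cooperating with DnaK/DnaJ (**B+KJE**) to extract monomers from
aggregates. Bulk kinetic models of this network report only concentrations
over time, which cannot answer the mechanistic question: *when a misfolded
molecule is eventually corrected, which chaperone system actually did it?*

`proteopath` answers that question by tracking a single tagged molecule.
The bulk mass-action network (folding U&harr;N, misfolding U&harr;M,
nucleation-growth aggregation, Lon degradation closed through a bookkeeping
`Null` state, and the three chaperone cycles) is integrated to an analysis
time *t*; the concentrations at *t* then linearise the dynamics of one tagged
molecule into a master equation

&nbsp;&nbsp;&nbsp;&nbsp; dp/dt = **K** p,

where bimolecular steps with partner *S* carry pseudo-first-order rates
k·[S](t), multi-client complexes split into one state per tagged position
(cis/trans ring of the chaperonin), and monomer loss from an aggregate of
size *n* removes the tagged monomer with probability 1/n.

On **K** the package computes, via the column-stochastic discretisation
**T** = **I** + &tau;**K** with &tau; = 1/(2 k_max) and iterative squaring of
sink-modified matrices:

* **committors** q_B(i) — probability of reaching state set B before A;
* **conditional committors** h, h&#773; with h + h&#773; = q_B — the
  committor split by whether a mediator set C was visited, giving
  **mediation probabilities**;
* **entry-channel decompositions** — each reactive source&rarr;target path
  classified by the edge through which it first enters the target (direct
  conversion, KJE release, GroELS release, ClpB extraction, or
  degradation-plus-resynthesis), with per-channel probabilities and fluxes;
* a **pseudo-trajectory sampler** that validates all of the above by direct
  counting on the same rate matrix.

Four built-in client profiles (`default`, `slow_folder`, `bad_folder`,
`aggregator`) span the characteristic behaviours: a kinetically trapped but
manageable default, a slow folder that depends on the chaperonin cavity, a
strong misfolder, and an aggregation-prone client.

## Worked example

Which system corrects misfolded protein for the default client at the
default synthesis rate?

```python
import proteopath as pp

model = pp.build_model(pp.PROFILES["default"])
final = pp.propagate(model, pp.AnalysisConfig())[-1]   # t = 1e4 s
K = pp.extract_rate_matrix(model, final)
T = pp.build_transition_matrix(K)

decomp = pp.pathway_probabilities(T, ["M"], ["U"], K=K)
fluxes = pp.pathway_flux(decomp, K, final)
print(f"{len(K.states)} tagged states, tau = {T.tau:.3e} s")
for ch, p in sorted(decomp.probabilities.items(), key=lambda kv: -kv[1]):
    if p > 0:
        print(f"  {ch:<12s} p = {p:.4f}   flux = {fluxes[ch]:.3e} uM/s")
q = pp.committor(T, ["M"], ["U"])
for lab in ("K_T:M", "GrL_T:M"):
    print(f"  committor({lab} -> U before M) = {q.q_B[K.index(lab)]:.4f}")
```

prints

```
67 tagged states, tau = 1.425e-02 s
  KJE          p = 0.8167   flux = 1.197e-02 uM/s
  GroELS       p = 0.1264   flux = 1.853e-03 uM/s
  direct       p = 0.0531   flux = 7.780e-04 uM/s
  degradation  p = 0.0030   flux = 4.331e-05 uM/s
  B+KJE        p = 0.0009   flux = 1.273e-05 uM/s
  committor(K_T:M -> U before M) = 0.2500
  committor(GrL_T:M -> U before M) = 0.0092
```

Reading: 82% of reactive misfolded&rarr;unfolded transitions are carried by
the KJE system. The chaperonin actually *binds* misfolded protein faster
than DnaK does, but a molecule entering the GroEL cycle only rarely leaves
it unfolded before returning to M (committor 0.009 vs 0.25) — entrance rates
alone mislead; the committor resolves the competition. The five channels
are exhaustive: direct conversion, the two release pathways, aggregate
extraction (B+KJE) and degradation followed by re-synthesis.

A command-line interface mirrors the library
(`proteopath build|simulate|matrix|committor|mediate|sweep|knockout|classify`),
reading JSON/YAML configs and writing CSV/TSV tables with a resolved-config
JSON sidecar.

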