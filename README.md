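# protoflux

Proteomics-constrained prediction of metabolic fluxes on the steady-state
flux polytope.

## The problem

A constraint-based metabolic model (CBM) fixes what a cell's metabolism
*could* do: at steady state the flux vector **v** over the N reactions
must satisfy mass balance **S v = 0** (S the M x N stoichiometric matrix)
and thermodynamic bounds **v**inf <= **v** <= **v**sup.  Because N > M,
the feasible set

L = { v : S v = 0, v_inf <= v <= v_sup }

is a polytope with infinitely many solutions, and picking one requires
extra information.  Flux balance analysis picks the one maximizing a
biomass objective; `protoflux` instead picks the flux vector best
supported by *quantitative proteomic data*, on the premise that fluxes
and enzyme abundances covary across a population.  It is aimed at
systems-biology researchers with a curated small-to-medium CBM (SBML or a
simple JSON dialect) and a proteins x samples abundance table, who want
per-sample flux estimates for reactions nobody measured.

## The method

1. **Characterize L probabilistically.**  Expectation Propagation (EP)
   approximates the uniform density on L - written as a Boltzmann-like
   density exp(-beta E(v)) with E(v) = 1/2 ||S v||^2 times the box
   indicators - by a multivariate Gaussian, so every point of L gets a
   posterior density under the truncated normal
   v ~ N_T(mu, Sigma | v_inf, v_sup).  EP is orders of magnitude faster
   than exhaustive sampling and supplies the density p_v needed below.
2. **Map proteins to reactions.**  Gene-protein-reaction rules are
   evaluated quantitatively: a complex is limited by its scarcest member
   (P1 AND P2 = min(P1, P2)), isoenzymes add
   ((P1 AND P2) OR P3 = min(P1, P2) + P3).
3. **Select one solution.**  Sample N_s flux vectors from the truncated
   posterior (exactly on the subspace S v = 0) and keep the one
   minimizing the density-weighted distance to the observed abundances

   Z = (1 / p_v) * sum over observed i of (E_i - |v_i|)^2.

   Measured exchange fluxes (say, a CO2 release rate) enter as Gaussian
   observations N(v_obs, sigma^2) that condition the posterior first.

A uniform Hit-and-Run sampler over the same polytope serves as an
independent oracle for the EP moments, a simulation study (invert fluxes
to enzymes through hyperbolic/linear/Hill relations, then predict them
back) quantifies recovery quality, and a null-space decomposition
clusters reactions into pathway modules by the angles between their
kernel row-vectors - useful for checking that proteomic observations
cover all modules.  Synthetic model/proteome generators make the whole
pipeline testable without any external download.

## Worked example

```python
import numpy as np
import protoflux as pf

model = pf.toy_models()["toy_central_carbon"]     # 15-reaction yeast caricature
post = pf.FluxSpaceModel(model).fit()             # EP characterization of L
print(post)
print(post.summary().round(3).head(6))

# synthetic proteome with hidden ground-truth fluxes, then predict back
abund, truth = pf.synthetic_proteome(model, relation="hyperbolic",
                                     noise_sd=0.1, n_samples=3, seed=7,
                                     posterior=post)
fluxes, log = pf.predict_dataset(model, abund, N_s=5000, seed=11)
print(log)
for col in fluxes.columns:
    r = np.corrcoef(truth[col], fluxes[col])[0, 1]
    print(col, "pearson r vs hidden truth:", round(float(r), 3))
```

prints

```
<FluxPosterior: 15 reactions, kernel dim 4, beta=1e+10, converged=True in 29 sweeps>
           mean     sd   lb   ub
reaction
glc_in    0.732  0.152  0.0  1.0
hex       0.732  0.152  0.0  1.0
pgi       0.376  0.199 -1.0  1.0
pfk       0.376  0.199  0.0  1.0
ppp       0.357  0.239  0.0  1.0
gpd       0.438  0.233  0.0  1.0
                 Z  N_obs  sample_index status
sample
sample0   7.432795     10          4266     ok
sample1  33.107936     10          4121     ok
sample2  17.642638     10          2751     ok
sample0 pearson r vs hidden truth: 0.884
sample1 pearson r vs hidden truth: 0.8
sample2 pearson r vs hidden truth: 0.833
```

Reading it: the EP posterior says glucose uptake (`glc_in`) runs at
0.73 +/- 0.15 of its maximum under steady state alone; after seeing each
sample's (noisy, hyperbolically distorted) enzyme abundances for the 10
GPR-bearing reactions, the argmin-Z candidate among 5000 sampled flux
vectors correlates at r ~ 0.8-0.9 with the hidden flux vector that
generated the data - including the 5 reactions with no enzyme
information at all.

The same operations are available from a shell:

```sh
protoflux ep-fit model.json --out posterior/
protoflux predict model.json --proteins proteome.tsv --ns 100000 --seed 7 --out fluxes.tsv
protoflux modules model.json --n-modules 4 --out decomp/
```

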