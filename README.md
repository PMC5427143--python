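# nbacknet

Graph-theoretical analysis of band-specific cortical functional
connectivity in n-back working-memory experiments.

Working-memory load reorganizes the brain's functional network
differently in different EEG frequency bands: under load, theta-band
(4–7 Hz) networks become more globally integrated, while alpha-band
(8–12 Hz) networks lose local segregation.  `nbacknet` implements the
full analysis chain that produces such results from trial-wise regional
band power:

* Pearson correlation of per-epoch power series between 80 cortical
  AAL regions → weighted connectivity matrices;
* proportional thresholding over a sparsity grid (10–50%) → nested
  binary networks with exact edge counts;
* small-world metrics — clustering C, characteristic path length L,
  efficiencies E_global / E_local, betweenness centrality b_i, and the
  surrogate-normalized γ = C/C_rand, λ = L/L_rand, σ = γ/λ against
  Maslov–Sneppen degree-preserving null networks;
* sparsity-integrated (area-under-curve) metrics, paired t-tests
  between the 0-back and 2-back conditions (global α = 0.05; nodal
  α = 0.01 with Benjamini–Hochberg FDR at q = 0.05), and Pearson
  brain–behavior correlations for metrics passing the significance
  gate;
* a synthetic-cohort generator with planted, band-specific integration
  and segregation effects and network-coupled behavior, so the whole
  pipeline is testable without access to raw EEG.

It is intended for cognitive-neuroscience researchers who want a
reproducible, tested reference implementation of this common EEG
connectomics protocol, or a simulation bench for its statistical
behavior.

## Worked example

```python
import nbacknet as nb

# a synthetic cohort under the study conditions:
# 28 subjects, 80 ROIs, ~42 / ~37 correct trials per condition
cohort = nb.generate_cohort(nb.CohortConfig(seed=11))

model = nb.NBackNetworkModel(cohort, profile="fast")
results = model.fit(seed=5)
print(results.summary())
```

The summary starts with the behavioral manipulation check and then the
integrated global metrics per band (abridged output of the run above):

```
Integrated global metrics, theta band (paired t, alpha=0.05)
------------------------------------------------------------------
  C         t= -7.832  p= 0.0000  diff(2b-0b)=-0.0114 *
  L         t= -9.147  p= 0.0000  diff(2b-0b)=-0.0801 *
  ...
  lambda    t= -9.158  p= 0.0000  diff(2b-0b)=-0.0411 *
  ...
  E_global  t=  8.605  p= 0.0000  diff(2b-0b)=+0.0062 *

Integrated global metrics, alpha band (paired t, alpha=0.05)
------------------------------------------------------------------
  C         t= -3.866  p= 0.0006  diff(2b-0b)=-0.0081 *
  ...

Brain-behavior correlations (pooled subject x condition)
------------------------------------------------------------------
  theta  lambda                 ~ rt        r=-0.694  p=0.000  n=56
  ...
  alpha  C                      ~ rt        r=-0.328  p=0.014  n=56
  ...
```

Read: under 2-back load the theta-band integrated normalized path
length λ drops and global efficiency rises (higher integration), the
alpha-band clustering C drops (lower segregation), and subjects whose
theta networks are more integrated respond faster (negative RT–λ
correlation over the 56 pooled subject × condition observations) —
the planted effects, recovered end to end.  `results.save(outdir)`
writes the TSV tables and a JSON report;
`results.plot_metric_curves("lambda", "theta")` and
`results.plot_integrated("alpha")` reproduce the standard figures.

The same pipeline runs from the shell:

```sh
nbacknet simulate --seed 11 -o cohort/
nbacknet analyze -i cohort/ --profile full --seed 5 -o analysis/
nbacknet report -i analysis/
nbacknet metrics --edges network_edges.tsv
```

`profile="full"` uses the reference protocol (41 sparsity points, 100
surrogates per network); `"fast"` (9 points, 20 surrogates) is for
simulation studies.  See `docs/methods.md` for the model, the
generator's assumptions and all numerical conventions.

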