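# dupsel

Molecular-evolution analysis of duplicated genes: codon-model likelihoods,
counting-based dN/dS, rate tests, codon-usage bias, and dS-clock dating.

## The problem

After a gene duplication, the two copies may decay (pseudogenization), gain
a new function under positive selection (neofunctionalization), or partition
the ancestral role (subfunctionalization).  These fates leave different
signatures in the ratio of nonsynonymous to synonymous substitution rates,
ω = dN/dS: ω ≪ 1 indicates purifying selection, ω ≈ 1 neutrality, ω > 1
positive selection.  `dupsel` implements the standard toolkit for reading
those signatures from an in-frame codon alignment of the two paralog clades
plus outgroups:

* **Branch models** on the Goldman–Yang (GY94) codon substitution model,
  with ω partitioned over labeled branch classes — one ratio for all
  branches (M0), pre- vs post-duplication (M2r), one ratio per paralog
  lineage (M3r), separate stems (M4r), all five classes free (M5r), and a
  free-ratio model (Mf).  Fitted by maximum likelihood with Felsenstein
  pruning and compared by likelihood-ratio tests (2ΔL ~ χ²).
* **Site models** (M1 nearly-neutral, M2 positive-selection, M3 discrete,
  M7 beta, M8 beta&ω) and **branch-site models A and B** with naive
  empirical Bayes identification of positively selected sites.
* **Nei–Gojobori (1986) counting**: fractional synonymous/nonsynonymous
  site counts, pathway-averaged differences, Jukes–Cantor correction,
  sliding-window profiles of K, dN and dN/dS.
* **Tajima's relative rate test**, Welch comparisons of per-gene statistics
  (GC3, ENC, dN, dS), and Wright's effective number of codons (ENC).
* **dS-clock dating** of the duplication from ortholog/paralog synonymous
  distances and a calibration split: r = dS_orth / 2T, t = dS_para / 2r.
* A **simulator** that generates duplication-shaped codon alignments with
  known truth (branch-class ω, site mixtures, branch-site regimes,
  GC3-biased codon usage, divergence-calibrated depths) for validating
  every estimator in the package.

The modeling API follows the statsmodels convention: build a `CodonModel`
from data, call `.fit()`, get a `CodonModelResults` with estimates,
convergence diagnostics and a `summary()`.

## Worked example

Simulate a duplicated gene under asymmetric post-duplication selection
(ω = 0.044 before the duplication, 0.118 on the fast paralog lineage, 0.060
on the slow one), then fit the one-ratio and three-ratio models and test
them against each other:

```python
import dupsel as d
from dupsel.simulate import preset_spec, simulate

spec = preset_spec("three_ratio", seed=1, n_codons=500)
aln, truth = simulate(spec)

r0 = d.CodonModel(aln, spec.tree.copy()).fit()
r3 = d.CodonModel(aln, r0.tree, spec=d.BranchModelSpec.M3r()).fit(kappa=r0.kappa)
print(r3.summary())
print(r3.lrt(r0))
```

Output:

```
Codon model fit: M3r
========================================
log-likelihood      -5443.2901
omega-structure p   3
total free params   3
kappa               2.1979
tree length         1.7853
converged           True
----------------------------------------
omega(pre)              0.04414
omega(stem_g1,g1)       0.1176
omega(stem_g5,g5)       0.06305
```

The three fitted ratios recover the generating values (0.044, 0.118,
0.060); the likelihood-ratio test against M0 gives 2ΔL = 23.18 with 2
degrees of freedom (p ≈ 9×10⁻⁶): ω is heterogeneous across the tree, with
roughly twofold faster protein evolution in one paralog.  Counting-based
statistics on the same alignment tell the same story — within-clade NG86
means dN = 0.022 vs 0.011 at comparable dS — and the mean inter-paralog
dS of 0.51 converts, under a 50-MYA calibration with ortholog dS 0.388,
to a duplication age of about 66 MYA.

A full pipeline (composition, divergence, windows, relative-rate tests,
ENC, the model ladder with LRTs, clock dating) runs from one JSON config:

```sh
dupsel simulate --preset three_ratio --seed 1 --n-codons 90 --out demo/
dupsel run config.json        # artifacts under the configured run directory
```

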