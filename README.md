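# rngxe — reaction-norm analysis of genotype-by-environment interaction

`rngxe` implements the two-step reaction-norm pipeline used in dairy and
dual-purpose cattle breeding to quantify genotype-by-environment interaction
(GxE) across heterogeneous farm environments, and to propagate it into
selection decisions.  It is written for quantitative geneticists who want a
self-contained, testable version of the workflow that is usually spread
across BLUPF90-family programs and ad-hoc scripts.

## The model

Herds are described by four environmental categories — geographical area
(plain / hill / mountain), housing (tie-stall / loose), feeding (traditional
/ total mixed ration) and summer pasture (yes / no) — whose combination
defines an environmental group (EG); a herd crossed with its EG is a
herd-environmental group (HEG).

**Step 1** fits a single-trait (repeatability) animal model

y = HEG + htd + fixed + a + Pe + e

by Gibbs sampling and takes the fixed HEG solutions, min–max scaled to
[−1, 1], as a continuous environmental gradient x.

**Step 2** replaces HEG and the animal effect by a fixed Legendre regression
on x and a random regression per sire,

y = htd + fixed + Σₜ φₜ(x) + Σₜ φₜ(x)·sₚ + Pe + e,

with φ₀ = 1, φ₁ = x, an unstructured sire covariance
G₀ = [[σ²_G, σ_G,GxE], [σ_G,GxE, σ²_GxE]] (pedigree-structured across
sires), and five residual-variance classes cut at quantiles of the HEG
solutions.  The intercept variance σ²_G is genetic merit in the average
environment; the slope variance σ²_GxE is environmental sensitivity — the
GxE component.  Phenotypic variance is
σ²_P = σ²_htd (+ σ²_Pe) + σ²_G + σ²_GxE + 2σ_G,GxE + σ̄²_e and sire
heritability h²_sire = 4σ²_G/σ²_P.

Genetic variance at environment x is the quadratic form **z′G₀z** with
z = (1, x) (written ZGZ′ over the gradient); per-environment responses to
index selection follow the multivariate breeder's equation b = P⁻¹Ga,
σ_i = √(b′Pb), R = (i/σ_i)·Gb.

Because real herd-books of this kind are proprietary, the package ships a
first-class synthetic herd-book generator (`rngxe.synthdata`) with a known
reaction-norm architecture, so every stage is testable against truth.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the default
synthetic herd-book (60 herds, 100 sires, ~7,700 test-day records with true
G₀ = [[0.06, 0.01], [0.01, 0.04]]):

```bash
python analysis/01_simulate.py            # herd-book + truth tables
python analysis/02_pedigree_and_editing.py
python analysis/03_estimate_gradient.py   # step 1
python analysis/04_reaction_norm.py       # step 2, with and without GxE
python analysis/05_gxe_summaries.py       # ZGZ' by EC level / EG
python analysis/06_selection_response.py
```

Output of `04_reaction_norm.py`:

```
GxE/P = 0.082 (p = 0.0125); h2_sire = 0.197; Spearman(with, without GxE) = 0.992, top-20 overlap 18
```

Read: the slope (GxE) term explains ~8% of phenotypic variance and is
significant by the posterior z-test; overall sire rankings barely move when
GxE is added (ρ = 0.99) but 2 of the top-20 bulls change — the
re-ranking-at-the-top pattern that matters for sire selection.
`05_gxe_summaries.py` then locates the genetic variance differences across
environmental categories (here housing: F = 8.88, p = 0.005), and
`06_selection_response.py` prints per-EG standardized responses, larger in
the environments with more expressed genetic variance.

The same pipeline is scriptable end-to-end from a YAML config:

```bash
rngxe all --config run.yaml && rngxe report --manifest results/manifest.json
```

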