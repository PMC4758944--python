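# vlbind

Quantitative analysis of small-molecule binding to immunoglobulin
light-chain variable-domain (V_L) dimers, and of the downstream question
that makes such binding interesting: does a dimer-binding ligand suppress
the amyloid-prone monomer pool and hence fibril formation?

In systemic light-chain (AL) amyloidosis, overproduced light chains
equilibrate between folded homo-dimers and less stable monomers; the
monomers can aggregate irreversibly into amyloid fibrils.  A ligand that
binds the hydrophobic cavity at the dimer interface acts as a
thermodynamic clamp: by linkage, dimer-selective binding shifts the
monomer⇌dimer balance toward dimer.  `vlbind` implements the full
measurement-to-mechanism chain used to characterise such ligands:

* **Equilibrium dialysis → binding constants** (`vlbind.dialysis`,
  `vlbind.binding_models`).  Two-chamber measurements give free ligand
  [U] (reference chamber) and bound ligand [B] = sample − reference.
  Two isotherms are fitted by least squares:

  - two positively cooperative sites,
    [B] = ([U]·[R]/K₁)(1 + [U]/K₂) with
    [R] = [R₀]/(1 + [U]/K₁ + [U]²/(K₁K₂)), cooperativity ⇔ K₁ > K₂;
  - two equivalent sites plus nonspecific binding,
    [B] = [R₀][U]/(K₁+[U]) + K_NS·[U].

  Constants from independent experiments are pooled as mean ± SEM.
  Scatchard diagnostics ([B]/[U] vs [B]) label curve shape: concave =
  cooperative, linear = single site class (slope −1/K₁), down-curving to
  a positive asymptote = specific + nonspecific.

* **Sedimentation equilibrium → oligomeric state** (`vlbind.sedimentation`).
  Radial absorbance profiles A(r) = baseline + Σᵢ aᵢ·exp[σᵢ(r²−r_ref²)/2]
  with σᵢ = Mᵢ(1−v̄ρ)ω²/(RT) are fitted with one or two exponential terms,
  yielding apparent molecular weights and monomer / dimer /
  dimer + multimer labels.  A high-speed meniscus-depletion fit with one
  mass pinned at the monomer quantifies any monomeric ligand-bound signal.

* **Monomer–dimer–ligand linkage** (`vlbind.linkage`).  Exact speciation
  of D ⇌ 2M (K_dim = [M]²/[D]) coupled to D + L ⇌ DL + L ⇌ DL₂, giving the
  free-monomer fraction as a function of total ligand — the model's proxy
  for amyloid propensity.

* **ThT inhibition summaries** (`vlbind.tht`).  Thioflavin-T time courses
  are reduced to plateau endpoints, inhibition fractions relative to the
  ligand-free control, lag times, and the smallest tested concentration
  with sustained ≥ 90% endpoint suppression.

* **Synthetic instruments** (`vlbind.synthetic`).  Seeded generators for
  dialysis plates, radial scans and ThT dose grids, with presets for the
  two reference ligands (methylene blue: K₁ = 207 μM, K₂ = 21 μM;
  sulfasalazine: K₁ = 698 μM plus nonspecific binding), so every pipeline
  is testable end to end without instrument files.

## Worked example

Simulate a methylene-blue-style dialysis plate (two protein loads, eight
independent experiments each, 5% measurement noise) and refit the
cooperative model:

```bash
simulate dialysis --preset methylene_blue --seed 11 --noise 0.05 -o mb_dialysis.csv
fit-dialysis mb_dialysis.csv --model cooperative -o mb_fit
```

The JSON report pools the per-experiment constants:

```
k1 mean 228 sem 10.6 ; k2 mean 19.6 sem 1.47 ; N=16
```

i.e. the generating constants (207, 21 μM) are recovered within roughly
two standard errors, with K₁ > K₂ confirming positive cooperativity.

Speciation shows the mechanism: with K_dim = 1 μM and 80 μM protein
(monomer units), raising total ligand from 0 to 500 μM drains the free
monomer pool,

```bash
speciate --kdim 1 --k1 207 --k2 21 --ptotal 80 --lgrid 0:500:6
```

```
l_total  monomer_fraction
    0.0      0.0760
  100.0      0.0516
  300.0      0.0207
  500.0      0.0118
```

a 6.5-fold reduction of the amyloid-prone fraction.  A simulated
sedimentation-equilibrium scan of the ligand-bound complex refits its
generating mass exactly and labels it a dimer:

```bash
simulate auc --preset methylene_blue --seed 3 -o scan.csv
fit-auc scan.csv
# "apparent_mw_Da": 23609.0, "oligomer_state": "dimer"
```

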