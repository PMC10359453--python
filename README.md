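# udgx

Analysis toolkit for **UdgX-type uracil-DNA glycosylases (UDGs)** — the
unusual 4Fe–4S family members that excise uracil from DNA and then trap the
product by forming a covalent His–deoxyribose bond instead of turning over.
The package is aimed at molecular-evolution and enzymology work on this
family: given a protein multiple sequence alignment, kinetic assay data and
crystal structures, it reproduces the three computational analyses that
characterise how UdgX diverged from canonical family-4 UDGs.

## What it computes

**1. Signature-residue evolution analysis of an MSA.**
All coordinates use the numbering of a designated reference sequence
(*Msm*UdgX).  The pipeline:

* profiles every alignment column (counts, frequencies over countable
  residues, consensus, Shannon entropy *H* in bits, percent occurrence with
  gaps counted in the denominator);
* partitions sequences by signature residues — UdgX-type carry **R107/H109**
  (the tip of the catalytic "R-loop" ₁₀₅KRRIH₁₀₉), canonical family-4 UDGs
  carry **P107/N109**; partial matches are reported as *unclassified*, never
  silently lumped;
* lists positions conserved above a threshold (default strictly > 95 %)
  within each subfamily, and the subset whose conserved residue is *unique*
  to the UdgX subfamily (position 53 of motif A — Q in UdgX, A/G in
  family 4 — is the textbook case);
* measures co-occurrence: the fraction of R107/H109 sequences that also
  carry Q53;
* scores pairwise column covariation — mutual information
  MI(i,j) = Σ p(a,b) log₂ [p(a,b)/(p(a)p(b))], chi-square, a
  consensus-indicator phi correlation, joint entropy — and clusters
  positions by average linkage into a Newick tree.

**2. Michaelis–Menten kinetics.**  Initial rates are OLS slopes of product
vs time; (S, v) data are fitted by Lineweaver–Burk double-reciprocal
regression (1/v = (K_m/V_max)(1/S) + 1/V_max, the convention used for the
published mutant table) or by direct nonlinear least squares on
v = V_max·S/(K_m+S).  Results carry delta-method standard errors,
k_cat = V_max/[E_t] (default [E_t] = 200 nM) and k_cat/K_m, with
fold-change comparisons between enzymes.

**3. Structure geometry.**  PDB parsing (via gemmi), named-atom distances
(e.g. E52 OE2 ↔ H109 ND1 of the catalytic dyad), and Cα RMSD between point
mutants by Kabsch least-squares superposition.

A **synthetic-data generator** (`udgx.simulate`) plants ground truth for
every stage — two-subfamily alignments with controlled conservation and
coupled columns, noisy Michaelis–Menten datasets and time courses, toy Cα
traces — so the whole pipeline is testable without downloads.

## Worked example

Fit kinetics simulated at the published H109S parameters
(V_max = 11.57 nM·min⁻¹, K_m = 154.92 nM) with 5 % rate noise on the
assay's 60–3010 nM substrate series:

```python
from udgx import MichaelisMentenModel
from udgx.simulate import KineticsTruth, generate_kinetics

data = generate_kinetics(KineticsTruth(vmax=11.57, km=154.92,
                                       noise_sd_fraction=0.05, seed=4))
res = MichaelisMentenModel(data, et=200.0).fit("lb")
print(res.summary())
```

```
Michaelis-Menten kinetics (Lineweaver-Burk)
===========================================
n observations: 10    [Et]: 200 nM
param           estimate     std err  unit
Vmax             11.5271       0.352  nM min^-1
Km               158.173        8.66  nM
kcat           0.0576353     0.00176  min^-1
kcat/Km      0.000364383    1.12e-05  min^-1 nM^-1
```

The estimates recover the generating parameters within noise (V̂_max 11.53
vs 11.57; K̂_m 158 vs 155 nM), and k_cat = V_max/200 ≈ 0.058 min⁻¹ matches
the published H109S turnover.  `res.plot()` and
`res.plot_double_reciprocal()` draw the Michaelis–Menten and
Lineweaver–Burk views.

The evolution pipeline runs the same way from Python
(`run_evolution_analysis`) or the shell:

```bash
udgx simulate msa --seed 1 --n 2000 --out sim
udgx evolve sim/alignment.fasta --ref-id MsmUdgX --outdir evo
# partition: {'udgx': 1001, 'family4': 975, 'unclassified': 25}
# unique conserved positions: [53, 107, 109]
```

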