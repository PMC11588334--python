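# osmokit

Analyses for the structural and solution biophysics of **WNK kinase
osmosensing**: how conserved water networks and chloride stabilize the
inactive, dimeric state of WNK kinase domains, and how osmolytes and
activating mutations release it.

WNK ("With No Lysine") kinases are chloride-inhibited, osmosensitive
Ser/Thr kinases. The unphosphorylated kinase domain (uWNK) is an inactive
asymmetric dimer carrying networks of conserved crystallographic waters —
the largest (CWN1) in the active site between the Catalytic and Activation
Loops, a second (CWN2) at the dimer interface. Osmolytes such as PEG400
de-dimerize uWNK, disrupt the networks, and activate autophosphorylation;
so do mutations in the charged residue cage around CWN1 (e.g. WNK3/E314A).
`osmokit` packages the computations behind this picture:

| module | what it does |
|---|---|
| `osmokit.structio` | read PDB/mmCIF structures (gemmi-backed), separate polymer chains from waters, write CSV/JSON tables |
| `osmokit.superpose` | Kabsch superposition, cross-isoform residue mapping, r.m.s.d. over selections, per-residue displacement profiles, crystal-symmetry mates |
| `osmokit.watermap` | conserved-water clustering across superposed structures, hydrogen-bond network components, retention counts between states |
| `osmokit.kinetics` | the chloride-inhibited autocatalytic autophosphorylation model: simulation, global progress-curve fitting, phospho-fractions from ion traces |
| `osmokit.equilibria` | monomer–dimer Kd from static-light-scattering mass series; melt temperatures from differential scanning fluorimetry |
| `osmokit.synthdata` | synthetic inputs with recorded ground truth for every stage |
| `osmokit.cli` / `osmokit.pipeline` | the `osmokit` command and versioned JSON reports |

## The models

**Autocatalytic autophosphorylation with chloride inhibition.** Phosphorylated
enzyme phosphorylates unphosphorylated enzyme (uWNK + pWNK → 2 pWNK), so with
total enzyme *T*, phospho-enzyme *p* and rapid-equilibrium chloride scaling

$$\frac{dp}{dt} = k_{app}\,(T-p)\,p,\qquad k_{app} = \frac{k}{1+[\mathrm{Cl}^-]/K_{Cl}}$$

with the logistic closed form
$p(t) = T p_0 e^{k_{app}Tt}/(T - p_0 + p_0 e^{k_{app}Tt})$.
Fitting shares (*k*, *K*<sub>Cl</sub>, *p*<sub>0</sub>) across a chloride
series (differential evolution + least-squares polish); *T* is fixed at the
experimental 4 μM.

**Monomer–dimer equilibrium.** For 2M ⇌ D with
*K*<sub>d</sub> = [M]²/[D], 90° SLS reports the weight-average mass
(1−*f*)*m*<sub>mono</sub> + *f*·*m*<sub>dimer</sub> with *f* the dimer mass
fraction: a ~60 kD reading for a 40 kD monomer means a 50/50 mixture by mass.

**Conserved waters.** Structures are anchored onto a reference by Kabsch
superposition of chosen residues; water oxygens are clustered greedily
(≤ 1 water per structure per cluster, 2.2 Å default match cutoff) and
clusters linked at O–O ≤ 3.4 Å into hydrogen-bond network components.

## Worked example

```
$ osmokit synth kinetics --seed 11 --out demo     # truth: k=0.10, K_Cl=120, p0=0.15
$ osmokit fit-kinetics demo/curves.csv --seed 1
S308: k=0.0985 uM^-1 min^-1  K_Cl=93.81 mM  p0=0.212 uM  ssr=4.602e-03  converged=True

$ osmokit synth sls --seed 11 --noise 0 --out demo
$ osmokit fit-sls demo/sls.csv
Kd = 20 uM
  0.80 mg/ml: 60.0 kD, dimer mass fraction 0.500
  1.80 mg/ml: 65.1 kD, dimer mass fraction 0.627
...
$ osmokit fit-dsf demo/dsf.csv
synthetic: Tm = 55.19 C (slope 2.10 C)
```

The kinetic fit recovers the generating parameters within the scatter a
σ = 0.03 noise level allows on a single 15-point series; the SLS fit
returns the Kd (20 μM) that makes the 0.8 mg/ml point an exact 50/50
monomer–dimer mixture (60 kD), with the series becoming predominantly
dimeric at higher concentration; the melt fit recovers the 55 °C transition
to within ~0.2 °C at 3% noise.

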