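# allokit

Analysis toolkit for the allosteric activation of antithrombin (and serpins
generally): from a pair of conformer crystal structures to the residues that
move, and from raw kinetic, thermodynamic and simulation readouts to the
numbers that say whether a mutant is activated.

Native antithrombin is almost entirely locked in a repressed conformation
(R); heparin-pentasaccharide binding flips it to an activated conformation
whose second-order association rate constant k₂ toward factor Xa is ~10³-fold
higher. The residues enforcing the lock form an allosteric communication
network between the heparin-binding site and the reactive center loop. The
package implements every desk-side stage used to find and characterize that
network:

| module | what it does |
|---|---|
| `structio` | PDB reading/writing, altloc resolution, the "most distal side-chain carbon" convention (bond-graph BFS from CA, carbons only) |
| `confdiff` | iterative trimmed Kabsch superposition, per-residue distal-carbon displacement scans, intra-structure pair distances, per-atom/residue deviation maps |
| `kinfit` | pseudo-first-order progress-curve fits A(t)=A₀e^(−k·t), stoichiometry-of-inhibition titrations, k₂ = k_obs·SI/[I], fold / percent activation, two-state R⇄A partition f_A = (k_obs−k_R)/(k_A−k_R) |
| `mutcycle` | double/triple-mutant thermodynamic coupling, CI = (k_a·k_b)/(k₀·k_ab), ΔG_int = RT·ln CI |
| `thermflr` | two-state van't Hoff melting fits with linear baselines (variable projection), baseline-fluorescence slopes, pentasaccharide fluorescence gain |
| `trajdyn` | Cα trajectory alignment and windowing, PCA / explained variance, PC-plane drift, DCCM residue-correlation maps, Δ-correlation ranking |
| `synthgen` | seeded generators with exact ground truth for every stage above |

## Worked example

Generate a synthetic conformer pair in which one residue's distal carbon is
shifted by (3, 4, 0) Å underneath a random rigid motion of the whole mobile
copy, then recover it:

```bash
$ allokit synth conformers --seed 21 --out fx
$ allokit confdiff --ref fx/conformer_a.pdb --mobile fx/conformer_b.pdb \
      --chain-ref A --chain-mob A --top 3 --out scan.tsv
overlay rmsd 0.00 A over 60/60 backbone pairs (1 cycles); wrote 3 rows to scan.tsv
$ head -2 scan.tsv
chain  resnum  resname  distal_atom_a  distal_atom_b  displacement_A  rank  fallback
A      5       ALA      CB             CB             5.000223        1     False
```

The backbone overlay is exact (the two copies differ only by a rigid motion
plus the injected shift), and the scan ranks residue 5 first with the
Pythagorean 5 Å displacement.

The activation arithmetic on the printed rate constants:

```python
>>> from allokit.kinfit import equilibrium_partition, activation_metrics
>>> part = equilibrium_partition(k_obs_native=4e3, k_R=7.5e2, k_A=1e6)
>>> print(f"f_R = {100*part.f_R:.2f}%  f_A = {100*part.f_A:.2f}%")
f_R = 99.67%  f_A = 0.33%
>>> act = activation_metrics(236*4e3, 4e3, 360*4e3)
>>> print(f"fold = {act.fold:.0f}  percent_activation = {act.percent_activation:.1f}%")
fold = 236  percent_activation = 65.5%
```

The first block says the native equilibrium mixture is ~99.7% repressed —
the observed native rate of 4×10³ M⁻¹s⁻¹ is explained by a ~0.3% admixture
of the 10⁶ M⁻¹s⁻¹ activated form. The second says a variant reacting
236-fold faster than native wild type has covered 65.5% of the 360-fold
native→activated window.

Other entry points: `allokit kinfit` (progress-curve → k₂), `allokit couple`
(rate table → coupling indices), `allokit melt` (melting curve → Tm, ΔH_vH),
`allokit trajdyn pca` / `allokit trajdyn dccm` (trajectory → variance ratios
/ Δ-correlation ranking), `allokit synth <stage>` (fixtures with truth.json).

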