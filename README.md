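# tetraswap

Quantitative analysis of an antibody light chain that lives in a reversible
**monomer ⇌ tetramer equilibrium** mediated by 3D domain swapping of its
variable domain.  The package is aimed at structural biologists and protein
biophysicists who measure such equilibria by size-exclusion chromatography
(SEC) and want to go from raw observations to dissociation constants,
thermodynamic parameters, dissociation kinetics and coordinate-level
swap/interface analysis in one tested toolchain.

## The model

For the dissociation of a homotetramer into four monomers, T ⇌ 4 M,

```
K_D = [M]^4 / [T]          (units M^3, 1 M standard state)
ΔG° = −RT ln K_D           (per mole of tetramer)
```

SEC peak areas give the monomer **mass** fraction *f*, so at a total
monomer-equivalent concentration *c*: `[M] = f·c` and `[T] = (1−f)·c/4`.
The temperature dependence of ΔG° is modelled with a temperature-independent
heat-capacity change ΔC°p and the two characteristic temperatures *T*<sub>h</sub>
(where ΔH° = 0) and *T*<sub>s</sub> (where ΔS° = 0):

```
ΔH°(T) = ΔC°p (T − T_h)
ΔS°(T) = ΔC°p ln(T / T_s)
ΔG°(T) = ΔC°p (1 + ln T_s) T − ΔC°p T ln T − ΔC°p T_h
```

Dissociation kinetics after a dilution jump follow mass action,
`d[T]/dt = k_on[M]⁴ − k_off[T]`, observed through an exponential fit of the
tetramer fraction with relaxation time τ; near equilibrium
`1/τ = k_off (1 + 16 [M]_eq³ / K_D)`.

On the structural side the package enumerates interprotomer and dimer–dimer
hydrogen bonds (N/O/S heavy atoms under a distance cutoff), finds hydrophobic
interface clusters, computes Cα RMSD per framework region (Kabat numbering,
insertion codes honored) after proper Kabsch superposition, and detects the
swapped segment and hinge from per-residue interchain contact fractions.

## Worked example

```python
from tetraswap.equilibrium import kd_from_ratio, solve_speciation, celsius_to_kelvin
from tetraswap.thermo import delta_g_from_k, ThermoParams, delta_h, delta_s

# SEC of a 300 uM solution shows 4% monomer / 96% tetramer at 25 C
k = kd_from_ratio(f_mono=0.04, c_total=300e-6, temperature=celsius_to_kelvin(25))
print(f"K_D at 25 C          : {k.value:.2e} M^3")
print(f"dG(dissociation)     : {delta_g_from_k(k):.1f} kcal/mol")

# what the same K_D predicts after dilution to 6 uM
state = solve_speciation(k, 6e-6)
print(f"monomer % at 6 uM    : {100*state.f_mono:.0f}%")

# enthalpy/entropy from fitted model parameters
p = ThermoParams(delta_cp=0.78, t_h=celsius_to_kelvin(1), t_s=celsius_to_kelvin(29))
print(f"dH at 45 C           : {float(delta_h(p, celsius_to_kelvin(45))):.1f} kcal/mol")
print(f"dS at 45 C           : {float(delta_s(p, celsius_to_kelvin(45))):+.3f} kcal/mol/K")
```

prints

```
K_D at 25 C          : 2.88e-16 M^3
dG(dissociation)     : 21.2 kcal/mol
monomer % at 6 uM    : 60%
dH at 45 C           : 34.3 kcal/mol
dS at 45 C           : +0.040 kcal/mol/K
```

The tiny K_D (10⁻¹⁶ M³) quantifies a tight tetramer: at 300 µM almost all
chains are tetrameric, yet a 50-fold dilution releases the majority as
monomers.  The positive, temperature-increasing ΔH° is the thermodynamic
signature of hydrophobically driven association.

The command line offers the same pipeline end to end; with no inputs it runs
on internally generated synthetic data with known ground truth:

```sh
tetraswap run --output-dir out --seed 7     # thermo + kinetics + peaks + structure
tetraswap simulate --out data_synth         # write the synthetic dataset itself
tetraswap analyze-structure data_synth/swapped_dimer.pdb
```

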