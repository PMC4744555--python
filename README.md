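# dbp5kinetics

Kinetic and thermodynamic analysis of the ATPase cycle of the DEAD-box
protein Dbp5 (DDX19), the RNA-stimulated ATPase that powers nuclear mRNA
export. The package is for enzymologists and quantitative biologists who
want to simulate the hydrolysis cycle, fit transient and steady-state
data to its standard models, analyse intermediate ¹⁸O isotope exchange,
and run constrained global fits and parameter-recovery studies against
synthetic data with known ground truth.

## The model

The intrinsic cycle is the minimal four-state scheme

```
        k+T        k+H         k−Pi          k−D
H + T  ⇌   HT    ⇌    HD·Pi   ⇌    HD + Pi  ⇌   H + D + Pi
        k−T        k−H         k+Pi          k+D
```

where H is the enzyme, T is ATP, D is ADP and Pi is phosphate, with
phosphate released before ADP. With no assumption about the speed or
reversibility of any step the steady-state cycling parameters are

```
kcat   = k+H k−Pi k−D / [(k+H + k−H)(k+Pi[Pi] + k−D) + k+H k−Pi + k−Pi k−D]
KM,ATP = [k−T (k−H (k+Pi[Pi] + k−D) + k−Pi k−D) + k+H k−Pi k−D] / (k+T · denom)
```

Pre-steady-state phosphate release shows a lag phase,
`[Pi](t) = β((e^−λt − 1)/λ + t) + Pi₀`, whose saturating rate
`λ∞ = k+H + k−H + k−Pi` and zero-substrate intercept `λ₀ ≈ k−H + k−Pi`
separate hydrolysis from product release. Intermediate ¹⁸O exchange
partitions the bound ADP·Pi state between resynthesis and release with
coefficient `Pc = k−H/(k−H + k−Pi)`, read out from the ¹⁸O₂:¹⁸O₁
isotopologue ratio of released phosphate in ¹⁸O-enriched water. An
RNA-extended scheme adds saturable RNA engagement of the ATP state
followed by an accelerated hydrolysis/release branch, with RNA released
together with ADP.

## Worked example

```python
import numpy as np
import dbp5kinetics as dk

# steady-state parameters implied by the global-fit rate constants
rates = dk.preset_rates("table2_nadh")
print(f"kcat   = {dk.kcat_closed_form(rates):.4f} /s")
print(f"KM,ATP = {dk.km_closed_form(rates)/1000:.2f} mM")

# transient phosphate release: 0.5 uM enzyme, 5 mM ATP, 5 uM sensor
t1 = dk.preset_rates("table1")
trace = dk.simulate(dk.MixState(H=0.5, T=5000.0, PiBiP=5.0), t1,
                    np.linspace(0.1, 60.0, 300), "pibip_pi")
fit = dk.fit_lag_linear(trace)
print(f"lag rate = {fit.lam:.3f} /s, steady-state slope = {fit.beta:.4f} uM/s")

# isotope exchange: forward-model a partition coefficient and invert it
ratio = dk.ratio_O2_O1(0.042, enrichment=0.485)
print(f"18O2:18O1 ratio = {ratio:.4f} -> Pc = {dk.estimate_pc_from_ratio(ratio, 0.485):.3f}")
```

prints

```
kcat   = 0.0445 /s
KM,ATP = 1.12 mM
lag rate = 0.985 /s, steady-state slope = 0.0098 uM/s
18O2:18O1 ratio = 0.0156 -> Pc = 0.042
```

The closed-form turnover (0.0445 s⁻¹) rounds to the reported 0.04 s⁻¹
and the Michaelis constant to 1.1 mM. At 5 mM ATP the fitted lag rate
(0.99 s⁻¹) sits below its saturating value of 2.2 s⁻¹ because ATP
binding is weak (K_T = 6.4 mM); the steady-state slope corresponds to
0.020 s⁻¹ per enzyme, the phosphate-release-limited turnover at that
ATP concentration.

A command-line interface mirrors the library:

```
dbp5kinetics simulate --params table1 --atp 5000 --pibip 5 \
    --observable pibip_pi --out trace.csv
dbp5kinetics fit --model lag_linear --input trace.csv
dbp5kinetics isotope --ratio 0.0156 --enrichment 0.485
dbp5kinetics thermo --kd 0.0064 --burial-area 511
dbp5kinetics recover --noise 0.02 --seed 7
```

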