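# raftquant

Analysis pipeline for three classic model-membrane measurements on large
unilamellar vesicles (LUVs), aimed at membrane biophysicists studying lipid
order, raft-like liquid-ordered (L_o) domains and vesicle size — e.g. when
probing how a membrane-active small molecule (such as the polyphenol
resveratrol) reorganizes PC/sphingomyelin/cholesterol bilayers.

## What it computes

**Laurdan generalized polarization (GP).**  From emission spectra
(390–600 nm, 355 nm excitation),

    GP = (I440 − I490) / (I440 + I490),

where I440 and I490 are the intensities at the characteristic wavelengths
of the ordered and disordered lipid phases.  GP versus temperature curves
quantify thermotropic behavior; the dose-response statistic
ΔGP/GP = 100·(GP_dose − GP_0)/|GP_0| (%) classifies an additive as ordering
(positive) or fluidizing (negative), and its zero-crossing dose is located
by linear interpolation.

**Phase-transition extraction.**  A four-parameter Boltzmann sigmoid
GP(T) = A2 + (A1 − A2)/(1 + exp((T − Tm)/dT)) is fitted to the thermal
curve; the analytic first derivative of the fitted sigmoid is then fitted
with a Lorentzian whose center gives a second Tm estimate and whose FWHM
measures transition width (cooperativity).

**L_o domain sizing by TEMPO quenching of DPH.**  From the residual
fluorescence ratio Q = F/F_o (with/without the quencher TEMPO), the linear
quenching ruler

    R = Ro · (Q − Q_PC) / (Q_SM/Chol − Q_PC)

maps Q between the liquid-disordered baseline (pure PC) and the
liquid-ordered ceiling (SM/Chol 50/50) onto a mean domain radius, with
sensing range Ro = 47.5 Å (calibratable from control pairs).

**DLS vesicle sizing.**  A second-order cumulant fit of the intensity
autocorrelation, g2(τ) − 1 = β·exp(−2Γτ)·(1 + (μ2/2)τ²)², yields the mean
decay rate Γ and PDI = μ2/Γ²; Stokes–Einstein inversion gives the
hydrodynamic diameter D_h = k_B·T/(3πη·D) with D = Γ/q².

A seeded synthetic-data generator emulates all three raw data types for
~70 named composition/dose presets, so every stage is verifiable by
parameter recovery.

## Worked example

Generate a noisy synthetic thermal scan of pure sphingomyelin vesicles
(two replicates, GP noise 0.005), compute its GP curve and extract the
transition:

```bash
raftquant synth --preset SM_control --kind spectra --seed 1 --replicates 2 --out sm.csv
raftquant gp --spectra sm.csv --out sm_gp.csv
raftquant tm --gp-table sm_gp.csv --out sm_tm.csv
```

which prints

```
wrote 14 spectra to sm.csv
wrote 7 GP points to sm_gp.csv
Tm(sigmoid) = 38.54 C, Tm(Lorentzian) = 38.55 C, width = 11.61 C
```

The SM control preset encodes a gel-to-fluid transition at 38.5 °C; with
replicate noise the sigmoid midpoint is recovered to 0.04 °C, the
Lorentzian center agrees with it to 0.01 °C, and the fitted width (11.6 °C
FWHM) sits on the encoded cooperativity scale.  The same chain in Python:

```python
import raftquant as rq

series = rq.synth_thermal_scan(rq.get_preset("SM_control"), seed=1, n_replicates=2)
result = rq.transition_summary(rq.gp_thermal_series(series))
print(result.sigmoid.tm_C, result.lorentzian.width_C)
```

Domain radii from quenching ratios use the per-matrix calibrations:

```python
rq.domain_radius(0.769, rq.POPC_CALIBRATION).radius_A   # 24.3 Å
rq.domain_radius(0.896, rq.PDPC_CALIBRATION).radius_A   # 42.9 Å
```

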