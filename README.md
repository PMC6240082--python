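# qstorm

Simulation and analysis of **graphene-oxide-quenched single-molecule
localization microscopy (qSTORM)**.

Graphene oxide (GO) is a broadband fluorescence quencher: a fluorophore
sitting within ~15 nm of a GO sheet hands its excitation energy to the
sheet by resonance energy transfer (RET) instead of emitting a photon.  A
GO-coated cover slip therefore extinguishes the non-specifically adsorbed
dye that normally floods STORM images with background, while leaving labels
on structures further from the surface untouched.  This package is for
microscopists and method developers who want to simulate such experiments
end to end, fit the quenching law to measured efficiencies, and quantify
reconstructions with the field's standard metrics — with no experimental
data required.

## The model and the estimators

For a point dipole a distance *z* above a graphene-like sheet the energy
transfer efficiency follows

&nbsp;&nbsp;&nbsp;&nbsp;ε(z) = 1 − [1 + A(λ/z)⁴]⁻¹,

with emission wavelength λ and a single dimensionless coupling/orientation
coefficient *A*.  The efficiency is estimated **self-referenced** from one
image as ε = 1 − I₍GO₎/I₍NGO₎, the ratio of emitted photon densities over
and off a GO region, so laser power and buffer condition cancel.  Around
this core the package provides:

* a synthetic-scene generator (GO sheets and films, 11-nm-wide fibres,
  200–400 nm capsule shells; specific labels, uniform non-specific
  background, and bright multi-fluorophore aggregates);
* quenched blinking photophysics with localization uncertainty
  σ_PSF/√N, plus an optional camera-frame renderer and a 2-D Gaussian
  localizer (Poisson maximum-likelihood spot fits);
* the weighted single-parameter fit of ε(z) across polymer-spacer
  thicknesses;
* super-resolution rendering (histogram / per-localization Gaussian) and a
  wide-PSF diffraction-limited renderer;
* metrics: Fourier Ring Correlation resolution at the 1/7 threshold, the
  feature-of-interest (FOI) effective PSF (modal fibre cross-section FWHM
  minus fibre width minus fluorophore size), contrast C = (I − I_b)/I_b,
  and improvement factors;
* an aggregate study showing how bright fluorophore aggregates bias the
  FRC resolution while the FOI metric stays put.

## Worked example

```python
from qstorm import QuenchModel, quench_efficiency, invert_quench
from qstorm.experiments import spacer_sweep

model = QuenchModel(a=2.6e-8, wavelength_nm=570.0)
print(f"eps(2 nm)  = {quench_efficiency(2.0, model):.4f}")
print(f"eps(15 nm) = {quench_efficiency(15.0, model):.4f}")
print(f"z(eps=1/2) = {invert_quench(0.5, model):.2f} nm")

points, fit = spacer_sweep(seed=3)   # 8 spacers x 5 replicate images
print(f"A_hat = {fit.a_hat:.3e} +- {fit.a_se:.1e}")
```

prints

```
eps(2 nm)  = 0.9942
eps(15 nm) = 0.0514
z(eps=1/2) = 7.24 nm
A_hat = 2.632e-08 +- 5.7e-10
```

Quenching is nearly complete at a 2 nm gap, drops to ~5 % at 15 nm (the
edge of the useful quenching range), and the half-efficiency gap sits near
7 nm.  The sweep simulates the full efficiency-vs-gap experiment at spacer
thicknesses 2–15 nm and recovers the coupling coefficient used to generate
it (truth 2.6 × 10⁻⁸) within its standard error.

A command-line surface wraps the same stages:

```bash
qstorm simulate-scene --template fibres_over_flake --seed 4 --out scene.json
qstorm run --config run.json --seed 7
qstorm frc --locs run/localizations.csv --out frc.json
qstorm quench-fit --points efficiency_vs_gap.csv --wavelength-nm 570 --out fit.json
```

Localization tables are read and written in a ThunderSTORM-compatible CSV
dialect (`"frame","x [nm]","y [nm]","sigma [nm]","intensity [photon]",
"uncertainty [nm]"`).

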