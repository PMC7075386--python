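# skyshine

Photon skyshine dosimetry for medical linear-accelerator vaults.

Skyshine is the radiation scattered by the air above a facility's roof back
down to ground level outside the building. For a linac vault with the gantry
pointed up and a lightly shielded roof, it can be the dominant dose pathway
at points tens of meters beyond the sidewall — exactly where parking lots and
outdoor seating tend to be. This package is for medical physicists and
radiation-safety staff doing shielding design and survey planning: it
predicts instantaneous and weekly skyshine dose equivalents, locates the
characteristic off-wall dose maximum, checks roof-shielding compliance, and
calibrates the model to measured dose-rate profiles.

## The model

A single-Compton-scatter sightline model. Photons transmitted through the
roof (transmission factor `B_xs`) scatter off air electrons in the beam;
because the sidewall is opaque to the low-energy scattered photons
(0.25–0.51 MeV), only scattering angles above

    θ_m = π/2 + arctan(x),      x = h / (d_s − d_w)

reach an observer at isocenter height, where `h` is the isocenter-to-rooftop
height, `d_w` the isocenter-to-outer-sidewall distance and `d_s` the
observation distance from the isocenter (all meters). Integrating the
large-angle Compton cross section dσ/dΩ ≈ [α(1 − cos θ)]⁻¹ along the beam
gives the instantaneous dose-equivalent rate (nSv/s)

    Ḣ = k · (F0 / 400 cm²) · B_xs · (Ḋ0 / 400 cGy·min⁻¹) · S(x) / d_s
    S(x) = 2(1 + x²)^{3/2} − x(2x² + 3)

with `F0` the field area and `Ḋ0` the dose rate at isocenter, and `k` an
energy-dependent empirical constant (nSv/s) absorbing all physical
prefactors; fitted defaults are k = 312 (6 MV), 200 (10 MV), 160 (18 MV).
The model is linear in field area, falls off as 1/d_s at intermediate
distances, and peaks at d_s − d_w ≈ 2h — three features measured profiles
show and the widely used empirical formula

    Ḣ_NCRP = 2.5×10⁷ · B_xs · Ḋ0[Gy/h] · Ω^1.3 / (d_i · d_s)²

does not predict. Both predictors are implemented so they can be compared
point by point. A weekly wrapper folds in workload W (Gy/week), use factor U
and occupancy T:

    H_w = 1.5×10⁻² · k · (W·U·T) · (F0/400) · B_xs · S(x) / d_s   [μSv/week]

plus sidewall-leakage inverse-square terms and roof-top compliance checks
("high radiation area": 100 mrem in any one hour).

## Worked example

Audit the worst-case no-roof scenario — 6 MV, B_xs = 1, W = 500 Gy/week,
U = 0.25, T = 1/20, F0 = 1600 cm², nominal vault d_w = 5 m, h = 4 m, with
the sidewall (a primary barrier) shielded to P = 10 μSv/week:

```sh
cat > worst_case.json <<'EOF'
{
  "geometry": {"d_w": 5.0, "h": 4.0},
  "beam": {"mv": 6, "f0": 1600.0, "d0": 400.0},
  "roof": {"b_xs": 1.0},
  "scenario": {"w": 500.0, "u": 0.25, "t": 0.05, "wall_type": "primary"}
}
EOF
skyshine scenario-audit --config worst_case.json
```

```
quantity            value   units
skyshine_peak_weekly 9.441  uSv/week
skyshine_dmax       12.15   m
total_peak_weekly   12.52   uSv/week
total_peak_distance 8.61    m
total_at_dmax       11.74   uSv/week
roof_hourly_dose    5556    mrem/h
required_b_xs       0.018   dimensionless
```

Reading: even with no roof at all, the weekly skyshine peaks at ~9.4 μSv at
12.15 m from the isocenter (≈ 1.8 roof heights beyond the wall); adding the
wall-leakage dose the weekly total never exceeds ~12.5 μSv — under the
20 μSv/week uncontrolled-area goal at every distance. The unshielded rooftop,
however, would see ~5600 mrem in a busy hour, so the roof needs a
transmission below 0.018 to avoid "high radiation area" designation — and
with that much roof shielding, ground-level skyshine (scaling linearly with
B_xs, to a peak of ~0.17 μSv/week) becomes negligible.

The same scenario runs through the library API (`skyshine.weekly_skyshine`,
`skyshine.total_weekly`, `skyshine.find_dmax`, ...), and
`skyshine simulate` / `skyshine calibrate` generate synthetic dose-rate
profiles and fit `k` back from them. See `skyshine --help` for all seven
subcommands.

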