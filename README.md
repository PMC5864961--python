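# tensioncoat

Physics of **surface-tension-assisted coating** of fenestrated 3D-printed
scaffolds — for biomaterials researchers who dip reticulated (window-bearing)
supports into hydrogel precursors and rely on capillarity to suspend liquid
films across the windows before crosslinking them into solid panes.

The package answers three practical questions:

1. **Will the liquid coat the mesh?** (`tensioncoat.wetting`)
   A reduced Gibbs-energy analysis of a two-dimensional square-cell mesh.
   At low saturation α_L the liquid wets the cell corners as circular-arc
   fillets (phase I); the hypothetical alternative is a cell filled except
   for a shrinking circular hole (phase II):

       F_I /(γ_L l) = 4 (1 + γ_SL/γ_L) − (8 − 2π) √(α_L/(4 − π))   (θ = 0)
       F_II/(γ_L l) = 4 γ_SL/γ_L + 2√π √(1 − α_L)

   with γ_S = γ_SL + γ_L cos θ (Young's equation).  Fillets touch at the
   critical saturation α_Lc (≈ 0.215 for θ = 0); past the inflection of the
   composite curve the liquid phase-separates — some cells fill completely
   while others keep only fillets — and complete coating is energetically
   favorable exactly for wetting liquids, θ < 90°.

2. **Is the suspended film stable on this frame?** (`tensioncoat.film`)
   A minimal-surface simulator: triangulated film pinned to the window
   boundary, relaxed by gradient descent on surface area (Barzilai–Borwein
   steps, Armijo backtracking, optional enclosed-volume constraint via
   Newton projection).  Stability = convergence to energetic equilibrium
   with no vertex escape; sweeps cover window length × pipe diameter grids.

3. **What does the scaffold's compression test say?** (`tensioncoat.mechanics`)
   σ = F/SA and ε = ΔL/L₀ conversion, effective compressive modulus K as
   the OLS slope over the first 0.5 mm of displacement, and buckling
   detection (first local stress maximum followed by a >5% drop).

`tensioncoat.synthetic` generates every input with known ground truth
(wetting systems, the printed 3×3 window/pipe grid, noisy compression
records), so the whole pipeline is testable offline.

## Worked example

```python
import math
import tensioncoat as tc

# --- wetting: a perfectly wetting liquid on a square-cell mesh
system = tc.make_system(theta=0.0, gamma_sl_ratio=0.0)
curve = tc.energy_curve(system, n_points=2001)
sep = tc.detect_phase_separation(curve)
print(f"critical saturation:  {curve.alpha_lc:.4f}")
print(f"phase separation:     {sep.is_separating}, "
      f"window = ({sep.coexist_lo:.4f}, {sep.coexist_hi:.4f})")
print(f"coatability at 60 deg: {tc.coatability(tc.make_system(math.radians(60))).value}")

# --- film: relax a perturbed film on a 5.5 mm window
frame = tc.build_frame(tc.FrameSpec(l=5.5, h=0.5))
mesh = tc.init_film(frame, subdivisions=8, perturb_amplitude=0.55, seed=7)
res = tc.relax(mesh)
print(f"film: converged={res.converged} stable={res.stable} "
      f"area={res.final_area:.4f} mm^2 in {res.iterations} iterations")

# --- mechanics: recover a preset modulus from a noisy synthetic record
profile = tc.paper_device_presets()[0]            # stiff rectangular design
record = tc.gen_compression(profile, tc.GeneratorConfig(seed=11, noise_rel=0.01))
est = tc.effective_modulus(record)
buck = tc.detect_buckling(tc.to_stress_strain(record))
print(f"K_hat = {est.K:.2f} MPa (truth {profile.K_true}), "
      f"r^2 = {est.r_squared:.5f}, buckling at eps = {buck.buckling_strain:.4f}")
```

prints

```
critical saturation:  0.2146
phase separation:     True, window = (0.2150, 1.0000)
coatability at 60 deg: favorable
film: converged=True stable=True area=30.2500 mm^2 in 76 iterations
K_hat = 76.45 MPa (truth 77.0), r^2 = 0.99964, buckling at eps = 0.0251
```

Reading: fillets of a θ = 0 liquid touch at 21.5% saturation, beyond which
completely filled cells coexist with fillet-only cells all the way to full
coverage (the coatable regime); a perturbed film on a 5.5 mm window relaxes
back to the flat 30.25 mm² minimal surface; and the modulus estimator
recovers the 77 MPa ground truth within 1% at 1% force noise, placing the
programmed buckling strain at ε ≈ 0.025 (grid-limited, truth 0.026).

The same functionality is scriptable via the `coat` CLI:

```bash
coat critical-saturation --theta-deg 0
# {"theta_deg": 0.0, "alpha_lc": 0.21460183660255167}
coat coatability --theta-deg 105
# {"theta_deg": 105.0, "verdict": "unfavorable"}
coat energy-curve --theta-deg 0 --n-points 501 --out results/curve0
coat stability-sweep --l 2.25,5.5,8.75 --h 0.25,0.5,1.0 --out results/table.csv
coat repro all --seed 42 --out results/repro    # full table regeneration
```

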