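# bandwave

Single-cell statistics and multiscale models of chemotactic bacterial
band migration.

A dense band of *E. coli* consumes its attractant and chases the gradient
it creates, migrating at a constant group speed `V_G` even though every
cell inside it is an erratic run-and-tumble walker.  `bandwave` is for
quantitative microbiologists and biophysicists who want to go from raw
particle-tracking tables to the mean-reversion picture of such a band:

* **measure** — group velocity `V_G = ⟨dx/dt⟩`, the co-moving band
  coordinate `z = x − V_G t − x_peak(0)`, density / instantaneous-velocity
  profiles, run-tumble segmentation, and the expected drift velocity
  `V_D(z) = ⟨l_R cos θ_R⟩/⟨τ_R + τ_T⟩` with its linear fit
  `V_D(z) ≈ −r z + V_D0`;
* **infer** — the attractant profile from the density profile via the
  travelling-wave balance `−V_G dS/dz = D_s S″ − kρ` and the perceived
  MWC gradient `g(z) = d/dz ln[(1+S/K_off)/(1+S/K_on)] ≈ g0 + g1 z`;
* **predict** — the Ornstein–Uhlenbeck consequences of
  `dz = [χ(g0 + g1 z) − V_G]dt + ε dW`: reversion rate `r = χ|g1|`,
  balanced position `z* = (V_G − χg0)/(χg1)`, stationary width
  `σ = ε/√(2r)`, pushed/diffusive/pulled classification by the sign of
  `g1`, and χ-ordered phenotype arrangements;
* **simulate** — seeded synthetic tracking data with known ground truth,
  Langevin ensembles (rigid moving gradients, consumption-coupled bands,
  trail-following groups), and a 3D pathway-level agent model (MWC
  receptors with gain N, adaptation, CheY-P → multi-flagella motors).

Everything lives in `src/bandwave/`; the numbered scripts under
`analysis/` are thin narrative drivers that run the study end to end and
write their tables under `results/`.  `docs/methods.md` documents the
models, defaults, and numerical choices.

## Worked example

```python
from bandwave import synthetic_tracks as st, trackstats as ts

params = st.RunTumbleGenParams()          # V_D(z) = -0.05 z + 0.17, V_G = 0.18
run = st.generate_run_tumble_tracks(params, n_cells=500, duration=10.0, seed=2024)

v_g, sem = ts.estimate_group_velocity(run.tracks)
moving = ts.to_moving_frame(run.tracks, v_g)
events, _ = ts.segment_runs_tumbles(moving)
v_d = ts.drift_velocity_profile(events, bin_width=0.24, seed=0)
z = moving.positions("z_mm")
fit = ts.fit_linear_drift(v_d, z_range=(z.mean() - 1.65 * z.std(),
                                        z.mean() + 1.65 * z.std()))
print(f"V_G = {v_g:.4f} mm/min")
print(f"r = {fit.r:.4f} +- {fit.r_se:.4f} /min, "
      f"V_D0 = {fit.v_d0:.4f} +- {fit.v_d0_se:.4f} mm/min")
```

prints

```
V_G = 0.1725 mm/min
r = 0.0590 +- 0.0058 /min, V_D0 = 0.1742 +- 0.0017 mm/min
```

i.e. the measurement chain recovers the generator's drift profile
(`r = 0.05 /min`, `V_D0 = 0.17 mm/min`) from the sampled tracks alone:
the drift velocity decreases from the back of the band to the front and
crosses `V_G` inside it, the signature of mean-reverting motion.  (The
⟨dx/dt⟩ estimate sits slightly below the generating `V_G = 0.18` because
the band mean still relaxes toward its balanced position over the 10 min
window; see `docs/methods.md`.)

Running the numbered analyses in order reproduces the whole study:

```bash
python analysis/01_simulate_tracks.py     # synthetic tracking ensembles
python analysis/02_track_statistics.py    # V_G, profiles, (r, V_D0) fit
python analysis/03_infer_gradient.py      # S(z), g(z), pushed classification
python analysis/04_ou_predictions.py      # z*, sigma, ordered chi ladder
python analysis/05_langevin_ensembles.py  # width laws, consumption, trail
python analysis/06_agent_based.py         # pathway-level chi ladder
```

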