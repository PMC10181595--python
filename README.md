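# gaitwrench

Estimating knee joint loading outside the gait laboratory is a long-standing
goal in osteoarthritis care: inertial sensors can capture a patient's walking
kinematics anywhere, but the force plates that anchor a conventional
musculoskeletal analysis cannot leave the lab. `gaitwrench` implements the
missing middle of that workflow. From gait-cycle kinematics alone it

1. **predicts ground reaction forces and moments (GRFM)** with a probabilistic
   principal component analysis (PPCA) model trained on cycles where force
   plates *were* available,
2. **estimates the centre of pressure (COP)** from the predicted GRFM with the
   zero-moment-point (ZMP) method, repairing the heel-strike/toe-off
   singularities with an anchored 10th-order polynomial,
3. **computes external knee moments** (flexion, adduction, rotation) by
   bottom-up link-segment inverse dynamics, and
4. **evaluates agreement** between workflows with RMSE, R², mean absolute
   differences of the first/second peak and stance impulse, exact Wilcoxon
   signed-rank tests and Benjamini–Hochberg FDR control.

Because clinical gait recordings are not redistributable, the package ships a
first-class synthetic cohort generator that emulates a slow-walking knee-OA
population (body mass 80.5 ± 15.3 kg, speed 0.75 ± 0.23 m/s, ~100 cycles per
subject) with an explicit low-rank coupling between kinematic and force
channels — the exact structural assumption the PPCA estimator relies on — so
every stage is testable end to end.

## The model

Each gait cycle is time-normalized to 101 points and stacked into a feature
vector `x` containing the joint-angle waveforms, the stance fraction (the
timing feature that resolves the double-support indeterminacy), and the
per-foot GRFM waveforms. PPCA assumes

```
x = W z + μ + ε,    z ~ N(0, I_q),    ε ~ N(0, σ² I)
```

fitted in closed form: `μ` is the feature mean, `σ²` the mean of the discarded
sample-covariance eigenvalues, and `W = U_q (Λ_q − σ² I)^{1/2}`. At inference
time the kinematic block `x_o` is observed and the GRFM block `x_t` is the
Gaussian conditional

```
E[x_t | x_o] = μ_t + W_t (W_oᵀ W_o + σ² I)⁻¹ W_oᵀ (x_o − μ_o)
```

computed through the q-dimensional latent posterior (no D×D matrices), with a
per-sample posterior standard deviation. The COP follows from the ZMP
identities `x_ap = M_z / F_y`, `z_ml = −M_x / F_y` (lab frame: X anterior,
Y up, Z right), valid only while the vertical force is well above zero; the
first and last 15 % of stance are replaced by a degree-10 Chebyshev
least-squares fit constrained through the calcaneus origin at 0 % and 100 %
of stance. Knee moments come from a foot+shank Newton–Euler recursion,
resolved in the shank anatomical frame and normalized to Nm/kg. An optional,
clearly-labelled *frontal-plane proxy* splits an axial knee load into
medial/lateral compartment forces from the adduction moment; it is not a
musculoskeletal contact simulation.

## Worked example

```python
from gaitwrench.synth import GeneratorConfig, generate_dataset, normalized_cycles, ANGLE_CHANNELS
from gaitwrench.ppca import FeatureLayout, loso_cv

cfg = GeneratorConfig(n_subjects=6, cycles_per_subject=30, seed=42)
dataset = generate_dataset(cfg)
cycles = normalized_cycles(dataset)

layout = FeatureLayout.default(list(ANGLE_CHANNELS))
result = loso_cv(cycles, layout, q="auto")

for channel, label in [("grf_r_y", "vertical GRF  [BW]   "),
                       ("grf_r_x", "ant-post GRF  [BW]   "),
                       ("grm_r_z", "sagittal GRM  [Nm/kg]")]:
    p = result.pooled[channel]
    print(f"{label} RMSE {p['rmse_mean']:.3f} +/- {p['rmse_sd']:.3f}   R^2 {p['r2_mean']:.3f}")
```

prints

```
vertical GRF  [BW]    RMSE 0.018 +/- 0.008   R^2 0.998
ant-post GRF  [BW]    RMSE 0.018 +/- 0.006   R^2 0.924
sagittal GRM  [Nm/kg] RMSE 0.131 +/- 0.069   R^2 0.989
```

i.e. when a model trained on five subjects predicts the sixth, the vertical
ground reaction force is recovered to about 0.02 body weight with near-unity
R² — the synthetic cohort is, by construction, an easier target than patient
recordings, so these figures bound what the architecture can do when its
low-rank assumption holds exactly.

The same workflow is available from the shell:

```sh
gaitwrench simulate --seed 1 --subjects 6 --cycles 30 --out trials/
gaitwrench train    --trials trials/ --q auto --out model.json
gaitwrench pipeline --model model.json --trial trials/S000_cycle000.csv --out results/
```

`results/` then holds per-cycle `grfm_*.sto`, `cop_*.sto`,
`knee_moments_*.sto` and `kcf_*_proxy.sto` files (OpenSim ASCII tables) plus
a `report.csv` of per-cycle loading features.

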