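# rosetteroll

Analysis pipeline for the motility of *Caulobacter crescentus* rosettes —
spherical aggregates of sessile stalked cells that are propelled by the
flagellar motor of a single predivisional member. Near a solid surface a
rosette does not swim: it **rolls**, translating perpendicular to its
rotation axis, and it reorients by sharp back-tracking turns whenever the
flagellar motor reverses. `rosetteroll` implements the full quantitative
chain needed to characterize this behaviour from tracking data, together
with the physical models that interpret it, and a synthetic-data module
that generates every input with known ground truth.

## What it computes

**Kinematics.** The 2D mean-squared displacement
MSD(Δt) = ⟨|**r**(t+Δt) − **r**(t)|²⟩ₜ of an ensemble of tracks, and the
ballistic–diffusive crossover lag Δt_c from the intersection of a
quadratic fit a·Δt² at short lags and a linear fit b·Δt at long lags
(Δt_c = b/a). For a self-propelled particle whose direction reverses as a
telegraph process with mean state duration τ, the velocity
autocorrelation is u²e^(−2t/τ), so Δt_c ≈ τ: the crossover reads out the
motor-reversal timescale.

**3D rotation from 2D images.** A minimal PIV front end (normalized
cross-correlation, 3-point Gaussian sub-pixel peak, peak-ratio
validation) and a weighted linear least-squares fit of the rigid-body
field **v** = **U** + **ω** × (**r** − **c**) evaluated on the visible
spherical surface, z(ρ) = z_c − √(R² − ρ²). The depth variation of the
surface across the projected disk is what makes the in-plane components
(ω_x, ω_y) identifiable from a single 2D field.

**Motor statistics.** Switch detection from sharp heading changes,
motor-state assignment from trajectory chirality (CCW circulation ⇔ CW
motor), turning angles θ ∈ [0, π], per-state duration distributions and
restoring times (a CW duration plus the consecutive CCW duration), with
Gaussian/exponential mixture fits.

**Rolling statistics.** The angle β between the in-plane rotation axis
ω_{x−y} and the translation u_{x−y} (ideal rolling: β = 3π/2), the
polarity P = 2(ρ_max − ρ_min)/(ρ_max + ρ_min) of its circular density,
and the slipping ratio Q = u_⊥/(ω_{x−y}R) against the scaled wall gap
d/R, with exponential fits, bootstrap confidence bounds, one-way ANOVA
and OLS slope tests.

**Hydrodynamics.** Closed-form spheroid rotational drag
σ = 16e³/(3ξ(e))·πηR³ with ξ(e) = e/(1−e²) − ½log((1+e)/(1−e)) and the
torque-scaling argument (L = σω) comparing rosettes to solitary cells; a
first-kind boundary-integral solver for the grand mobility of a rigid
sphere above a no-slip wall (wall handled exactly by the image-system
Green's function) predicting the purely hydrodynamic slip Q(d/R) of a
torque-driven sphere; a resistive-force-theory simulator of a sphere
propelled by a rotating helical filament near the wall; and an exact
binomial model for the probability that a rosette carries two or more
simultaneously active flagella.

## Worked example

Simulate nine rolling rosettes (120 s at 20 Hz, speed 3.6 μm/s,
exponential 1-s motor reversals) plus swarmer tracks, then analyze:

```bash
rosetteroll simulate --seed 7 --out data/
rosetteroll analyze --seed 7 --dataset data/ --out analysis/
```

The analyze step prints, per stage (a run at seed 7 with 3 × 70-s tracks
shown):

```
[kinematics] {'crossover_s': 1.26, 'ballistic_coeff': 11.2, 'diffusive_coeff': 14.1,
              'exponents': [1.78, 1.31], 'mean_speed': 3.20, 'speed_sd': 0.01}
[motor] {'n_switches': 147, 'mean_duration_cw': 1.45, 'mean_duration_ccw': 1.37,
         'mean_restoring': 2.78, ...}
[rolling] {'n_intervals': 209, 'mean_Q': 0.92, 'polarity': 2.0}
[hydro] {'sigma_ratio': 732.5, 'p_multi_flagellum': 0.0258}
```

Reading the numbers: the MSD crossover (≈1 s) matches the generator's
mean motor-state duration; measured durations are slightly longer than
the true 1 s because switches closer together than the detection window
merge; the mean slipping ratio recovers the generator's Q_true = 0.9; the
polarity of β is maximal because near-wall rolling locks the translation
perpendicular to the rotation axis; and with 25 member cells each
flagellated for ~1% of its division cycle, two simultaneously active
flagella occur with probability only 2.6% — the statistical basis for
treating the rosette as a single-motor machine.

The purely hydrodynamic slip prediction:

```bash
rosetteroll hydro --out q_curve.csv --gaps "0.1,0.5,2"
# Q_max = 0.0515 over d/R in [0.1, 2.0]
```

Q decays with the gap and vanishes in free space, where a torque-driven
sphere spins without translating.

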