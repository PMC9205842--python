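# offsetspect

Simulation toolkit for **undersampled SPECT**: can a dual-head gamma camera acquire
8–60 projections instead of the usual 120 — cutting acquisition time proportionally —
without losing image quality or quantification?  The package combines two ideas from
sparse-view brain SPECT (dopamine-transporter imaging with striatal phantoms):

* **offset acquisition** — shifting the second detector head by half the angular step,
  so opposed views stop being conjugate and the number of distinct view directions
  doubles for the same number of projections;
* **compressed-sensing iterative reconstruction (CS-IR)** — Poisson ML-EM with an
  edge-preserving total-variation prior applied one-step-late (OSL):

  ```
               f_i                    p_j
  f_i ← ─────────────────── · Σ_j C_ij ─────────── ,   U_TV = Σ √(Δx² + Δy² + ε²)
        Σ_j C_ij (1 + β ∂U_TV/∂f_i)   Σ_k C_kj f_k
  ```

  with β = 0.001, ε = 1e−6, 100 iterations and a Butterworth pre-filter
  (order 8, cutoff 0.5 cycles/cm).  β = 0 gives plain ML-EM; ramp-filtered FBP of 120
  conventional views is the reference.

It is a library for people studying tomographic sampling and regularization: everything
is importable Python (no CLI), with `examples/` scripts as the guided tour.  The
package generates three digital phantoms (point-source resolution, multi-cylinder
linearity, striatal brain), simulates noisy projections with an analytic parallel-beam
projector and LEHR-like collimator blur (≈10.9 mm FWHM at the 150 mm rotation radius,
~75 kcounts per view, Poisson noise), reconstructs with FBP / ML-EM / CS-IR /
CS-IR-with-offset, and measures FWHM, aspect ratio (ASR), count-density linearity,
%CV and the specific binding ratio (SBR).  Model details and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

`python examples/resolution_point_sources.py` reconstructs the resolution phantom from
8 and 120 views with CS-IR on both sampling schemes and prints:

```
collimator blur at 150 mm: 10.85 mm FWHM

views sampling  FWHM@100mm  ASR@100mm
    8    onset      15.8 mm       1.12
    8   offset      16.2 mm       1.06
  120    onset      15.6 mm       1.03
  120   offset      15.6 mm       1.00
```

The FWHM (≈15–16 mm: collimator blur ⊕ Butterworth roll-off ⊕ pixel footprint) barely
moves with the number of views, but the aspect ratio — radial over tangential FWHM at
the 100 mm off-center source, 1.0 for an isotropic point response — stays at ≈1.0 for
offset sampling down to 8 views while conventional (onset) sampling distorts.  The
other examples tell the rest of the story with the numbers they print:

* `examples/angles_and_sampling.py` — angle sets, doubled view directions, the 1/15
  acquisition-time factor for 120 → 8 views;
* `examples/count_linearity.py` — linearity r = 0.9996 from 8 offset views vs
  r = 0.9781 from 8 onset views (streaks distort the low-count cylinders);
* `examples/brain_noise_and_sbr.py` — at 60 views the TV prior cuts background %CV
  roughly in half relative to ML-EM at identical SBR;
* `examples/full_sweep.py` — the config-driven sweep + summary: at 8 onset views the
  brain %CV explodes to ≈30% and SBR collapses to 2.35, while 8 offset views hold
  ≈5.2% and 4.12.

A full-size sweep (`SweepConfig()` defaults: 3 phantoms × 6 projection numbers ×
3 arms × 10 seeds, plus the FBP reference) writes a tidy `metrics.csv` and normalized
PNG galleries via `run_sweep(config, out_dir=...)`.

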