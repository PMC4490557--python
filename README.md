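# ribofret

Simulation and analysis of two-color single-molecule FRET trajectories
of tRNA translocation on the bacterial ribosome.

During translocation, elongation factor EF-G moves the tRNAs through a
series of conformational states that a donor/acceptor dye pair (Cy3 on
ribosomal protein L11, Cy5 on the A-site tRNA) reports as discrete FRET
efficiency levels: E = I_A/(I_D + I_A) ≈ 0.8 (classical PRE), 0.6
(hybrid PRE), 0.4 (a chimeric intermediate stalled by EF-G variants)
and 0.2 (POST). The package is for single-molecule biophysicists who
need the full trajectory-analysis chain as tested, scriptable code:

- a **synthetic trace generator** — continuous-time Markov dynamics,
  camera-frame integration, donor→acceptor bleed-through (β = 0.13),
  detector noise, single-step photobleaching — with a ground-truth
  sidecar for every trace;
- **quality control** — bleed-through correction, bleach-step detection
  and truncation, lifetime and anti-correlation screens, three-point
  smoothing, FRET calculation;
- **idealization** — per-trace Gaussian hidden Markov models fitted by
  Baum–Welch EM with BIC state-number selection and Viterbi decoding,
  mapped onto the canonical FRET classes;
- **transition analysis** — amplitude (ΔE ≥ 0.05) and duration
  (≥ 2 frames) filters, static/dynamic classification,
  post-synchronization at the first transition to E ≤ 0.5;
- **populations and energetics** — state occupancies P, contour
  histograms, Gaussian-mixture fits, K_eq = P_S2/P_S1 and
  ΔG = −ln K_eq in units of k_BT;
- **dwell-time kinetics** — exponential fits y = y0 + A·e^(−t/τ),
  rates k = 1/τ, photobleaching-rate estimation, and bias correction
  up to full simulation-based calibration.

## Worked example

Simulate 200 molecules of the EF-G(XL)-stalled complex — which
fluctuates between the hybrid state (E = 0.56 ± 0.08) and the chimeric
intermediate (E = 0.40 ± 0.09) with forward/back rates 7.9 and
1.2 s⁻¹ — and run the full pipeline:

```python
import ribofret as rf

ds = rf.generate_dataset("XL", 200, seed=11)
res = rf.analyze(ds.raw_traces(), rf.PipelineConfig(k_max=3, seed=5),
                 condition="XL")
print(res.rate_table)
```

which prints (abridged):

```
accepted 176 of 200 | synced 99 | k_bleach 0.095
state_high state_low  P_high  P_low   Keq  dG_kBT  k_down  n_down  k_up  n_up
       0.6       0.4   0.158  0.842 5.348  -1.677   6.835     829 1.627   778
```

Reading the row: over the 1.5 s window after post-synchronization the
intermediate holds 84% of the occupancy (ground truth for this window
is 0.851), giving K_eq ≈ 5.3 and a free-energy drop of ≈ 1.7 k_BT —
the intermediate is reachable by thermal fluctuations. The dwell-fit
rates k_obs (6.8 and 1.6 s⁻¹, from 829 and 778 filtered transitions)
carry the finite-frame-rate detection bias discussed in
`docs/methods.md`; `ribofret.calibrate_rates(res)` removes it by
iterative re-simulation when the observation model is known.

The same stages are available from the shell:

```sh
ribofret simulate --preset XL --n-traces 200 --seed 11 --out sim/
ribofret analyze --traces sim/traces.tsv --condition XL --out analysis/
ribofret report --analysis analysis/ --out report/
```

Presets cover the factor-free PRE and POST complexes, active
translocation (EFG_wt), the stalled intermediates (XL, wt_GTPgS, D45,
H91A, H583K, wt_Fus) and the tRNA–tRNA FRET pair (ttPRE, ttFus).

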