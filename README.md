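# evacpanic

Psycho- and physiological indicators of panic during simulated fire
evacuation.

Virtual-reality evacuation experiments probe how people react to fire cues
— an alarm with no visible cause, spreading smoke, open flame — by
recording eye movement (60 Hz binocular tracker) and prefrontal
haemodynamics (10 Hz, 8-channel fNIRS) while participants experience a
roaming baseline followed by three stimulus–evacuation rounds, then rate
their emotions on 9-point basic-emotion and Self-Assessment-Manikin (SAM)
scales. `evacpanic` implements the full indicator pipeline for such
sessions, plus a synthetic-cohort generator so every stage is testable
without access to human-subject recordings.

## Indicators

For each stimulus–evacuation round (and, where meaningful, the roaming
baseline):

* **Pupil dilation amplitude** — blink gaps are linearly interpolated, the
  binocular mean area \(A_t\) is normalized by the round's first 10
  samples, \(M_t = A_t / \tfrac1{10}\sum_{i=1}^{10} A_i\), and the round's
  maximum \(M_t\) is the amplitude.
* **Fixation / saccade time ratios** — \(r_{\text{fix}} = \sum_t F_t / N\)
  and \(r_{\text{sac}} = \sum_t S_t / N\) per eye, averaged over eyes;
  blink samples stay in \(N\), so the two ratios sum to slightly less
  than 1.
* **Binned gaze entropy** — Shannon entropy (nats) of gaze positions over
  a 10×10-pixel grid,
  \(S = \log N - \tfrac1N \sum_i n_i \log n_i\).
* **Brain activation coefficients** — each ΔHbO channel is band-passed at
  0.01–0.1 Hz (zero-phase Butterworth), each stimulus is modelled as a
  Kronecker impulse convolved with the unit-peak canonical HRF
  (double-gamma: peak ≈ 5 s, undershoot minimum ≈ 16 s, gone by 30 s),
  and the per-stimulus, per-channel coefficient follows the least-squares
  projection \(\hat\beta_{ij} = f_i^\top y_j / f_i^\top f_i\). Stimuli
  80 s apart with a 30 s response are separable; the session-level fit
  solves the three coefficients jointly, which coincides with the scalar
  projection for disjoint supports and stays exact under filtering.
* **Emotion shifts** — \(\Delta x = x_{\text{scenario}} - x_{\text{roaming}}\)
  per term (6 basic emotions + valence/arousal/dominance).

Scenario contrasts use paired (within-participant) t-tests with
per-contrast significance at α = 0.05, reported as mean/SD/p-value tables
per indicator family.

## Worked example

```python
import evacpanic as ep

cfg = ep.PipelineConfig(seed=1, n_participants=56)
ep.run_simulate(cfg, "demo/cohort")                      # write synthetic cohort
ep.run_analyze("demo/cohort", cfg, "demo/analysis")      # all indicators
res = ep.run_report("demo/analysis/metrics.csv", cfg, "demo/report")

t = res["pupil"]
print(t.summary.round(3).to_string(index=False))
print(t.contrasts[["scenario_a", "scenario_b", "t", "p", "significant"]]
      .round(4).to_string(index=False))
```

```
            metric scenario  n  mean    sd
dilation_amplitude    Alarm 56 1.500 0.234
dilation_amplitude    Smoke 56 1.357 0.146
dilation_amplitude    Flame 56 1.333 0.154
scenario_a scenario_b      t      p  significant
     Alarm      Smoke 4.2139 0.0001         True
     Alarm      Flame 4.6793 0.0000         True
     Smoke      Flame 0.8878 0.3785        False
```

The synthetic cohort is generated around per-scenario population
amplitudes 1.46 / 1.31 / 1.32 (Alarm / Smoke / Flame) with
between-subject spread, so the recovered sample means land near those
values and the contrasts show the characteristic pattern: the ambiguous
alarm drives significantly larger pupil dilation than either visible fire
cue, which do not differ from each other. `demo/report/report.md`
collects the same mean/SD/p tables for all six indicator families, with
significant contrasts in bold.

The same pipeline is available from the shell:

```sh
evacpanic simulate --seed 1 --n 56 --out demo/cohort
evacpanic analyze  --cohort demo/cohort --out demo/analysis
evacpanic report   --metrics demo/analysis/metrics.csv --out demo/report
```

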