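# effortnirs

Analysis toolkit for prefrontal fNIRS studies of listening effort in
hearing-aid users. It implements the full analysis chain for a
within-subjects comparison of two hearing-aid programs (a standard
quiet-listening program vs. a DNN-based noise-management program) during a
speech-in-noise repetition task:

- **Signal pipeline** for dual-wavelength (760/850 nm) continuous-wave
  recordings at 10 Hz from 6 long (~3.5 cm) + 2 short-separation prefrontal
  channels: step-artifact removal → scalp-coupling-index (SCI) channel QC →
  optical density → wavelet motion correction → modified Beer–Lambert
  conversion → 0.01–1.5 Hz band-pass → short-separation regression →
  0.01–0.09 Hz band-pass.
- **Event-related averaging**: the response to a sentence sequence is the
  mean of HbDiff = HbO − HbR over [onset + 10 s, offset) minus the 5-s
  pre-onset baseline, aggregated into left-lateral, lower-medial and
  right-lateral subregions.
- **Adaptive SNR-50 staircase** (modified HINT rules: 8 dB start, ±4 dB for
  the first five sentences, ±2 dB after; estimate = mean SNR of trials 12–20
  plus the would-be trial-21 SNR; test SNR = mean of the last two of three
  runs + 2 dB) with a simulated logistic listener.
- **Behavioural statistics**: rationalized arcsine (RAU) transform of
  accuracy, paired t-tests with 95% CIs, paired Cohen's *d* = |t|/√n.
- **Multilevel inference**: trial × subregion HbDiff modelled with a
  participant random intercept by full maximum likelihood
  (`HbDiffModel(...).fit() → HbDiffResults` with `summary()`), nested model
  comparison by likelihood-ratio test and AIC, simple-slopes probing of the
  program × subregion interaction, and a correct-trials-only
  brain–behaviour model (HbDiff ~ effort rating).
- **Synthetic-data generator** reproducing the session structure (blocks of
  six ≥18-s low-context sequences plus two short decoys, 30-s baselines, one
  practice + four test blocks) with double-gamma hemodynamic responses,
  cardiac/respiratory/Mayer/drift noise, step and spike artifacts, and known
  ground truth — so every stage can be validated against programmed truth.

## Worked example

```bash
effortnirs run-all --seed 5 --outdir demo
```

simulates eight participants with a programmed −19 µM left-lateral program
effect, preprocesses every session, and fits the model hierarchy. It prints:

```
programmed left-lateral program effect 19.0 µM; recovered 12.9 µM (DNN coefficient -12.95)
```

and writes `trial_table.csv`, `qc.json`, `behavioural_tests.csv`,
`simple_slopes.csv`, `mlm_results.json` and figures into `demo/`. The
simple-slopes table localises the effect to the left lateral subregion:

```
     subregion  estimate   se       t      p
  left_lateral   -12.946  0.2 -64.654  0.000
  lower_medial    -0.205  0.2  -1.026  0.305
 right_lateral    -0.110  0.2  -0.550  0.583
```

The recovered magnitude sits below the programmed 19 µM because the
published pipeline parameters (0.1-IQR wavelet shrinkage, 0.01–0.09 Hz final
band) attenuate event amplitudes by roughly 20–30%; see `docs/methods.md`.
The behavioural table reproduces the expected direction: higher effort
ratings (+0.9 points) and lower RAU accuracy (−8.7) under the standard
program for this seed.

Library use mirrors the CLI:

```python
import effortnirs as en

rec, true_hb, truth = en.simulate_session("P00", seed=3)
hb, qc = en.run_pipeline(rec, en.PipelineParams())
table = en.build_trial_table(hb, rec.events, rec.montage, qc)
res = en.HbDiffModel(table, en.ModelSpec(program=True, subregion=True, interaction=True)).fit()
print(res.summary())
```

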