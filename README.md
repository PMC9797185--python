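# gammashift

Task-locked prefrontal gamma analysis and trial-outcome decoding for
attentional set-shifting experiments.

During set-shifting tasks, medial prefrontal local field potentials (LFPs)
show a transient elevation of gamma-band power (62–67 Hz, the "65-Hz
range") in the seconds before a correct choice — but not before an
incorrect one. `gammashift` implements the full analysis chain that
establishes and exploits this effect, for electrophysiologists who want to
run it on their own recordings or probe its statistical behavior on
synthetic data with known ground truth:

1. **Preprocessing** — zero-phase 60-Hz notch filtering, artifact masking
   of samples with |V − ⟨V⟩| > 3σ over the whole recording, and RMS
   normalization of the unmasked trace.
2. **Spectral analysis** — analytic Morlet continuous wavelet transform
   (L1-normalized, so a unit sinusoid at f₀ has unit peak power at f₀);
   per-frequency power normalized by the session-wide mean baseline power
   (arbitrary units, A.U.); band power averaged in half-open task windows:
   baseline = [t_start, t_start+3), choice = [t_dig−3, t_dig),
   post-choice = [t_dig, t_dig+3). Trials with start-to-dig latency ≤ 6 s
   are excluded from window comparisons (their baseline and choice windows
   would overlap).
3. **Band discovery** — for each correct trial, the frequency in the
   30–120 Hz gamma span (excluding 58–62 Hz around the power line) where
   choice-window power most exceeds the mean incorrect-trial spectrum;
   the 6-Hz window capturing the most per-trial peaks (ties broken by the
   integrated mean difference) is the discriminative band.
4. **Decoding** — a threshold rule on choice-window band power, trained on
   a class-balanced random draw (5 correct + 5 incorrect trials) and
   tested on all remaining trials. Significance is the one-sided exact
   binomial tail P(X ≥ k), X ~ Bin(n, ½), for k successes on n tested
   trials.
5. **Behavioral scoring** — trials to the 8-of-10-consecutive-correct
   criterion, error counts, perseverative vs random error taxonomy, and
   the 10-minute timeout rule for the set-shifting task.
6. **Group statistics** — pooled-variance unpaired t-tests (from raw data
   or published mean ± SEM summaries), a random-intercept linear mixed
   model for trial-level band power (power ~ trial type + (1 | animal),
   REML, Wald z contrasts), and two-sample t-test power analysis.
7. **Synthetic sessions** — 1/f pink-noise LFP with 60-Hz line
   contamination, sparse biphasic artifacts, and outcome-dependent
   gamma bursts confined to the 3 s before the dig; plus a parameterized
   agent playing the set-shifting task.

## Worked example

```python
import pandas as pd
from gammashift import synth, session, spectral, banddiscovery, decoder, stats

# one recorded session: discover the band and decode trial outcome
cfg = synth.SynthConfig(n_trials=40, trial_duration=(8.0, 15.0), p_correct=0.7, seed=42)
raw, events = synth.generate_lfp_session(cfg)
clean = session.preprocess(raw)
print(f"masked {clean.artifact_mask.mean():.3%} of samples as artifacts")

search = banddiscovery.BandSearchConfig()
freqs = spectral.linear_grid(*search.span)
grid, spectra = spectral.trial_window_spectra(clean, events, freqs, windows=("choice",))
outcome = events.table["outcome"].to_numpy()
report = banddiscovery.discover_band(
    spectra["choice"][outcome == "correct"],
    spectra["choice"][outcome == "incorrect"],
    grid, search)
print(f"discriminative band: {report.band.lo:g}-{report.band.hi:g} Hz")

table = spectral.build_trial_table(clean, events)
res = decoder.decode(table, spectral.CANONICAL_BANDS[0], seed=42)
print(f"decoder accuracy {res.accuracy:.2%} ({res.n_correct_pred}/{res.n_test}), "
      f"binomial p = {res.p_value:.2e}")

# a 4-animal cohort for the trial-level mixed model
tables = []
for i in range(4):
    cfg_i = synth.SynthConfig(n_trials=25, trial_duration=(8.0, 15.0), seed=100 + i)
    raw_i, ev_i = synth.generate_lfp_session(cfg_i)
    tables.append(spectral.build_trial_table(session.preprocess(raw_i), ev_i,
                                             animal_id=f"M{i + 1}"))
rows = stats.lmm_table(pd.concat(tables, ignore_index=True))
for name, r in stats.fit_power_lmm(rows).items():
    print(f"{name}: estimate {r.estimate:+.3f}, p = {r.p:.3g}")
```

Output:

```
masked 0.317% of samples as artifacts
discriminative band: 62-67 Hz
decoder accuracy 100.00% (30/30), binomial p = 9.31e-10
correct_vs_baseline: estimate +9.783, p = 0
incorrect_vs_baseline: estimate -0.004, p = 0.98
correct_vs_incorrect: estimate +9.788, p = 0
```

The generator injected a 62–67 Hz burst (SNR ≈ 5 in-band) before correct
digs only; the search recovers exactly that band, the decoder separates
the outcomes perfectly on this clean simulation, and the mixed model
localizes the power elevation to correct-trial choice windows (the
+9.8 A.U. estimate is the simulated burst's normalized power over the
baseline reference of 1).

## Command line

`gammashift` exposes each stage as a subcommand over the CSV/JSON
interfaces (`simulate`, `preprocess`, `power`, `discover-band`, `decode`,
`score-behavior`, `stats`), plus `run` for the whole pipeline from a YAML
or JSON config:

```sh
gammashift simulate --seed 7 --n-trials 40 --out-lfp lfp.csv --out-events events.csv
gammashift run --config pipeline.yaml --outdir out/
```

`run` writes `trial_power.csv`, `band_report.json`, and a self-describing
`report.json` (config echo, seed, version); reruns with the same config
and seed are byte-identical.

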