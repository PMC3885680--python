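# fingerdecode

Pairwise decoding of individual finger movements from multichannel scalp
recordings, built around spectral principal-component features.

The pipeline:

1. **synth** — synthetic recordings with the statistical structure the
   analysis assumes: blank/fixation/cue trial layout, `1/f` background,
   alpha/beta rhythms that desynchronize during movement, a finger-specific
   broadband power increase on a planted channel subset, and ~1 Hz bipolar
   kinematic flexion peaks. Ground-truth events, spectral templates and
   spatial weights are returned for end-to-end scoring.
2. **kinematics** — movement-peak detection from bipolar traces
   (0.5–2 Hz band-pass, 200 µV threshold, 400 ms post-cue latency, 500 ms
   tail exclusion, 200 ms separation, strongest-in-400 ms merge) and a
   data-glove position variant.
3. **preprocess** — zero-phase 0.3 Hz high-pass, 60 Hz notch (plus
   harmonics for intracranial mode), common average reference, and 1 s
   epoch extraction around movement peaks and mid-fixation rest centers.
4. **spectral** — 1 s Hanning-window PSDs on an integer-Hz grid,
   log-normalization to the grouped ensemble mean, per-channel PCA of the
   frequency-by-frequency covariance, projection weights, and band-power
   baseline features.
5. **decode** — r²-based channel selection, repeated stratified five-fold
   cross-validation with an RBF max-margin classifier (grid-searched penalty
   and kernel width), rest-epoch control decoding. All fitted state
   (normalizer, basis, selection, scaling, hyperparameters) comes from
   training folds only.
6. **stats** — permutation-based empirical guessing level, the
   normal-approximation binomial chance interval
   `0.5 ± z_{1−α/2}·√(0.25/m)`, one-sample/paired t-tests, and report-table
   column statistics.

## CLI

```sh
fingerdecode simulate --config cfg.json --out data/
fingerdecode detect --config cfg.json --data data/ --out events.tsv
fingerdecode all --config cfg.json --seed 1 --out run/
fingerdecode report --report run/report.json
```

`cfg.json` is a `PipelineConfig` document (unknown keys rejected), e.g.:

```json
{
  "seed": 1,
  "synth": {"n_channels": 24, "trials_per_finger": 60,
            "signal_channels": [7, 8, 9, 10, 11, 12, 13, 14, 15, 16]},
  "decode": {"reps": 20, "pc_set": [0, 1, 2], "channel_strategy": "top_k",
             "top_k": 10}
}
```

Signals are exchanged as tab-delimited matrices with a JSON header
(fs, channel labels, units); trials and events as TSV; reports as CSV + JSON
carrying the config digest.

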