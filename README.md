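# seegdecode

Decoding self-related stimuli — a subject's **own name** versus a
**stranger's name** — from stereo-electroencephalography (SEEG)
band-power features, with permutation-based feature selection,
leave-one-out classification, significance testing, brain-region
analysis, and response-latency estimation.  Because raw patient SEEG is
not publicly available, the package ships a synthetic-session generator
that emulates the statistical structure of such recordings, so every
stage of the pipeline is testable against known ground truth.

## Who this is for

Researchers analysing event-related intracranial recordings (SEEG/ECoG)
who need a tested reference implementation of the
high-gamma-band-power decoding workflow: multi-contact depth-electrode
recordings, two balanced stimulus classes, and questions about *where*
and *when* the neural responses differ.

## The method

For one session (continuous signals `contacts × samples` at 1–2 kHz,
stimulus onsets, contact metadata):

1. **Preprocessing** — remove contacts whose 50 Hz line power exceeds
   `median + 10·MAD` across contacts; comb-notch 50 Hz and harmonics
   (zero phase); shaft-Laplacian re-reference (each contact minus the
   mean of its adjacent kept neighbors); 6th-order Butterworth band-pass
   into high-gamma (60–145 Hz), beta (13–30 Hz) or alpha (8–12 Hz);
   instantaneous power `|analytic(x)|²` via the Hilbert transform;
   epoch 0–1000 ms post-onset; z-score each trial against its own
   200 ms pre-onset baseline; smooth with an 80 ms Gaussian; reject
   contacts whose across-trial standard error exceeds the mean response.
2. **Feature extraction** — average z-power in 100 non-overlapping
   10 ms bins per contact (`v`), concatenate over contacts into the
   trial feature vector `V`.
3. **Selection** — per feature, Spearman correlation `r` between the
   feature values and the binary class labels; 1000 label shuffles give
   a surrogate `r` distribution; a Gaussian fit to the surrogates
   yields the two-sided tail p-value; the Bonferroni level is
   `0.05 / dim(V)`; keep the 20 smallest-p features (`V20`).
4. **Classification** — PCA to >90 % explained variance (typically 2–6
   components) + linear discriminant analysis, or a 200-tree random
   forest; leave-one-out cross-validation with selection re-run inside
   every training fold (no test-set leakage).
5. **Significance** — keep predictions fixed, shuffle the true labels
   1000 times; the significance level is the 95th percentile of the
   permuted accuracies.
6. **Regions** — count selected-feature provenance per anatomical
   region; re-run the pipeline on single regions; a region is
   *cross-modal* when its accuracy exceeds the significance level in
   both the auditory and the visual session; a least-squares regression
   of accuracy on physical stimulus similarity (normalized zero-lag
   cross-correlation of auditory envelopes / binary name images) checks
   that decoding is not explained by low-level stimulus differences.
7. **Latency** — per contact, the first 10 ms bin whose power differs
   significantly from baseline (activation) or between classes
   (difference), by studentized permutation tests; plus the density of
   selected-feature generation times.
8. **Three-class control** — the 1000 ms pre-onset interval becomes a
   "rest" class; pairwise selection of 10 features per class pair (30
   total); sensitivity `100·TP/(TP+FN)`, precision `100·TP/(TP+FP)`,
   confusion matrix and one-vs-rest ROC/AUC.

## Worked example

```python
import seegdecode as sd

# a synthetic session: 16 contacts on 2 shafts, 60+60 trials,
# one contact responding to the own name (gain 3, 60-145 Hz, 300 ms)
cfg = sd.SimConfig(seed=1, n_trials_per_class=60,
                   effects=[sd.EffectSpec(contact_id="S1-3", onset_ms=300.0)])
session, ground_truth = sd.generate_session(cfg)

ep = sd.preprocess_session(session, band="high_gamma")
features = sd.bin_features(ep)                      # 120 trials x 1600 features
result = sd.loo_decode(features, classifier="lda", k=20, seed=3)
print(f"accuracy {result.accuracy:.1f}% "
      f"(threshold {result.significance_threshold:.1f}%, "
      f"p={result.permutation_p:.3g})")

selected = sd.select_top_features(features, k=20, seed=2)
print("selected features per contact:",
      {c: int((selected.contact_ids == c).sum())
       for c in set(selected.contact_ids)})
print("own-vs-other latency:",
      sd.difference_latency(ep, "S1-3", seed=5, min_consecutive=2), "ms")
```

prints

```
accuracy 90.0% (threshold 58.3%, p=0)
selected features per contact: {'S1-3': 20}
own-vs-other latency: 310.0 ms
```

All 120 trials are decoded leave-one-out; 90 % accuracy is far above
the 58.3 % chance-level threshold (p < 1/1000).  All 20 selected
features trace to the simulated effect contact, and the estimated
own-vs-other difference latency (310 ms, bin start) recovers the
simulated 300 ms onset to within one 10 ms bin.

The same pipeline is scriptable from the shell:

```bash
seegdecode simulate --config sim.yaml --out session/ --seed 1
seegdecode run2 --in session/ --seed 1 --out report.json
seegdecode run3 --in session/ --seed 1 --out report3.json
```

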