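# spaten

Sex detection from clinical-style EEG with a deliberately shallow,
explainable spatio-temporal CNN — plus the tooling needed to ask *where* the
information lives: closed-form relevance attribution, ICA-based cardiac
artifact rejection, and perturbation experiments that dissociate
topographies, waveforms/spectra, and heart-artifact leakage.

## Who this is for

Researchers studying demographic confounds in machine-learning EEG analysis.
Deep disease classifiers can silently exploit sex-related signal content
(neural or artifactual); this package provides a minimal, fully inspectable
classifier and a synthetic EEG cohort generator with controllable
sex-dependent structure, so every claim about "what the network uses" can be
tested against planted ground truth.

## The model

A two-trainable-layer CNN over normalized 21-channel, 4-s (1000-sample,
250 Hz) EEG segments:

    segment X (21 x 1000)
      -> cross-correlation with 16 spatio-temporal kernels K_k (21 x 19), ReLU
      -> 16 correlation curves (982 samples each)
      -> temporal max pooling (window 75, stride 25) -> 16 x 40 window maxima
      -> global average -> 16 features
      -> sigmoid unit (logistic regression) -> P(male)

6400 trainable weights (16·21·19 kernel weights + 16 dense weights; the
convolution is bias-free). Kernels span all channels and slide only along
time, so each kernel is a short spatio-temporal EEG pattern and the sign of
its dense weight says which sex it argues for. Per-subject predictions are
majority votes over 50 segments.

Because only each pooling window's maximum reaches the output, relevance is
closed-form: with `C_{i,k} = X_i * K_k` the cross-correlation in window `i`,

    R'_{i,k} = X_[argmax C_{i,k}] ⊙ K_k · max C_{i,k},   R_{i,k} = R'_{i,k} · w_k

summed over windows and kernels gives a signed 21 x 1000 relevance map
(negative = female, positive = male). QRS-locked averages of |R| quantify how
much of the decision rides on electrocardiac artifacts.

The synthetic cohort generator plants sex effects at three loci —
instantaneous scalp topographies (variance-matched, covariance-different),
alpha-band power, or scalp-projected QRS artifacts — on top of band-limited
neural sources, 1/f noise, and an annotated ECG channel. Perturbations
(joint time-point shuffling, per-channel ±200 ms shifts, channel subsets)
then dissociate the loci exactly as on real data. See `docs/methods.md`.

## Worked example

A small end-to-end run — simulate a topographic-effect cohort, preprocess,
train, evaluate on unseen subjects, and export a relevance map:

    spaten demo --out demo_run --seed 7 --n-train 20 --n-eval 10 \
        --n-segments 20 --epochs 6

prints

    {
      "seed": 7,
      "n_train_segments": 400,
      "n_eval_segments": 200,
      "balanced_accuracy": 1.0,
      "imbalanced_accuracy": 1.0,
      "best_epoch": 1,
      "abs_relevance_sum": 2774.67
    }

Reading: 20 training subjects (10 female / 10 male, 20 segments each) carry a
strong planted topographic sex difference (effect size 2.0); the trained
model labels all 10 unseen evaluation subjects correctly by majority vote
(`balanced_accuracy` 1.0 — expected at this planted effect size, and
meaningless as a real-world estimate). `best_epoch` is the epoch whose
held-out balanced accuracy won model selection. `demo_run/` contains the
model (`model.msn.npz`), per-condition results (`results.tsv`), a 21x1000
relevance map (`relevance.tsv`), and a JSON run log.

The same stages are available as a library:

```python
from spaten.pipeline import CohortSpec, build_split_datasets
from spaten.synthetic_cohort import SimConfig
from spaten.minispaten import ModelSpec, TrainConfig, train
from spaten.evaluate import evaluate_model

cohort = CohortSpec(n_subjects=20, n_segments=20,
                    sim=SimConfig(effect_mode="topographic",
                                  effect_size=2.0, seed=1))
train_ds, eval_ds = build_split_datasets(cohort, n_eval_subjects=10)
model = train(train_ds, ModelSpec(), TrainConfig(epochs=6, seed=0))
balanced, imbalanced, confusion = evaluate_model(model, eval_ds)
```

Other CLI subcommands: `simulate` (EDF cohort + manifest), `preprocess`,
`train`, `predict`, `relevance`, `perturb`, `channels` (single-channel /
greedy forward selection), `suite` (a Table-style experiment grid from YAML).

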