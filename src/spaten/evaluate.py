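"""Metrics, statistics, and the per-condition experiment suite.

Balanced accuracy is the arithmetic mean of true positive rate and true
negative rate with male (label 1) as the positive class; the balanced metric
itself is invariant to that convention.  Significance of subject-level
accuracies is assessed with an exact one-sided binomial test against the
baseline of always predicting the majority class (p0 = majority fraction of
the evaluation cohort), Bonferroni-corrected over the number of experimental
conditions.  Paired t-tests compare per-network accuracies between
conditions, paired by training seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sp_stats

from .errors import (
    DegenerateStatisticError,
    InvalidInputError,
    UndefinedMetricError,
)
from .minispaten import (
    ModelSpec,
    SegmentDataset,
    TrainConfig,
    ensemble_predict,
    predict_subject,
    train,
)
from .pipeline import CohortSpec, build_split_datasets
from .perturb import PerturbationSpec, restrict_channels

__all__ = [
    "ConfusionMatrix",
    "ExperimentResult",
    "ConditionSpec",
    "SuiteConfig",
    "balanced_accuracy",
    "imbalanced_accuracy",
    "binomial_test_onesided",
    "binomial_test_twosided",
    "bonferroni_adjust",
    "paired_ttest",
    "predict_cohort",
    "confusion_from_predictions",
    "run_suite",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Subject counts; 'positive' class is male (label 1)."""

    female_predicted_female: int
    female_predicted_male: int
    male_predicted_female: int
    male_predicted_male: int

    def __post_init__(self) -> None:
        if min(
            self.female_predicted_female, self.female_predicted_male,
            self.male_predicted_female, self.male_predicted_male,
        ) < 0:
            raise InvalidInputError("confusion counts must be >= 0")

    @property
    def n_female(self) -> int:
        return self.female_predicted_female + self.female_predicted_male

    @property
    def n_male(self) -> int:
        return self.male_predicted_female + self.male_predicted_male

    @property
    def n_total(self) -> int:
        return self.n_female + self.n_male

    @property
    def n_correct(self) -> int:
        return self.female_predicted_female + self.male_predicted_male


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """(TPR + TNR) / 2 with male recall as TPR and female recall as TNR."""
    if cm.n_male == 0 or cm.n_female == 0:
        raise UndefinedMetricError("both classes must be present")
    tpr = cm.male_predicted_male / cm.n_male
    tnr = cm.female_predicted_female / cm.n_female
    return (tpr + tnr) / 2.0


def imbalanced_accuracy(cm: ConfusionMatrix) -> float:
    """Plain fraction of correct predictions."""
    if cm.n_total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return cm.n_correct / cm.n_total


def binomial_test_onesided(k: int, n: int, p0: float) -> float:
    """Exact upper-tail probability P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise InvalidInputError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise InvalidInputError("need 0 < p0 < 1")
    return float(sp_stats.binomtest(k, n, p0, alternative="greater").pvalue)


def binomial_test_twosided(k: int, n: int, p0: float) -> float:
    """Exact two-sided test (used for the prediction-bias check)."""
    if not 0 <= k <= n:
        raise InvalidInputError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise InvalidInputError("need 0 < p0 < 1")
    return float(sp_stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def bonferroni_adjust(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests."""
    if n_tests < 1:
        raise InvalidInputError("n_tests must be >= 1")
    return alpha / n_tests


def paired_ttest(acc_a, acc_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Paired t-test on per-network accuracies (paired by training seed).

    ``alternative``: 'two-sided', 'greater' (a > b) or 'less'.
    Returns (t statistic, p-value).
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InvalidInputError("need two equal-length vectors with n >= 2")
    if np.var(a - b) == 0.0:
        raise DegenerateStatisticError("zero variance of paired differences")
    res = sp_stats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort-level prediction

def predict_cohort(model, dataset: SegmentDataset) -> dict[str, int]:
    """Per-subject majority-vote labels for every subject in the dataset."""
    out = {}
    for sid in dataset.subjects():
        mask = dataset.subject_ids == sid
        out[sid] = predict_subject(model, dataset.X[mask]).label
    return out


def confusion_from_predictions(
    dataset: SegmentDataset, predictions: dict[str, int]
) -> ConfusionMatrix:
    counts = [[0, 0], [0, 0]]  # [true][pred]
    for sid, pred in predictions.items():
        counts[dataset.subject_label(sid)][pred] += 1
    return ConfusionMatrix(
        female_predicted_female=counts[0][0],
        female_predicted_male=counts[0][1],
        male_predicted_female=counts[1][0],
        male_predicted_male=counts[1][1],
    )


def evaluate_model(model, eval_ds: SegmentDataset) -> tuple[float, float, ConfusionMatrix]:
    """(balanced accuracy, imbalanced accuracy, confusion) at subject level."""
    preds = predict_cohort(model, eval_ds)
    cm = confusion_from_predictions(eval_ds, preds)
    return balanced_accuracy(cm), imbalanced_accuracy(cm), cm


# ---------------------------------------------------------------------------
# experiment suite

@dataclass(frozen=True)
class ConditionSpec:
    """One row of the experiment grid."""

    name: str
    band: str = "broadband"
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    ica: bool = False
    n_kernels: int = 16
    kernel_len: int = 19
    channels: tuple[str, ...] = ()  # empty -> all EEG channels


@dataclass(frozen=True)
class SuiteConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    n_eval_subjects: int = 30
    conditions: tuple[ConditionSpec, ...] = (ConditionSpec(name="broadband"),)
    n_repeats: int = 30
    train_config: TrainConfig = field(default_factory=TrainConfig)
    alpha: float = 0.05
    n_tests: int | None = None  # None -> number of conditions
    seed: int = 0


@dataclass
class ExperimentResult:
    condition: str
    per_network: list[tuple[int, float, float]]  # (seed, balanced, imbalanced)
    mean_balanced: float
    sd_balanced: float
    mean_imbalanced: float
    sd_imbalanced: float
    p_binomial: float           # ensemble majority-vote correct count vs p0
    ensemble_balanced: float
    adjusted_alpha: float
    significant: bool
    error: str | None = None


def _condition_datasets(suite: SuiteConfig, cond: ConditionSpec):
    cohort = replace(
        suite.cohort,
        band=cond.band,
        ica=cond.ica,
        perturbation=cond.perturbation,
    )
    train_ds, eval_ds = build_split_datasets(cohort, suite.n_eval_subjects)
    spec = ModelSpec(
        n_channels=train_ds.X.shape[1],
        input_len=train_ds.X.shape[2],
        n_kernels=cond.n_kernels,
        kernel_len=cond.kernel_len,
    )
    if cond.channels:
        train_ds, spec = restrict_channels(train_ds, cond.channels, spec)
        eval_ds, _ = restrict_channels(eval_ds, cond.channels, spec)
    return train_ds, eval_ds, spec


def run_suite(suite: SuiteConfig, progress=None) -> list[ExperimentResult]:
    """Train ``n_repeats`` independently seeded networks per condition.

    Per network, subject-level balanced and imbalanced accuracies on the
    evaluation cohort are recorded; the binomial test is run on the correct
    count of the across-network majority-vote (ensemble) prediction against
    p0 = the evaluation cohort's majority-class fraction.  A failed training
    aborts its condition with a diagnostic; other conditions proceed.
    """
    n_tests = suite.n_tests or len(suite.conditions)
    adj_alpha = bonferroni_adjust(suite.alpha, n_tests)
    results: list[ExperimentResult] = []
    for cond in suite.conditions:
        if progress:
            progress(f"condition {cond.name}")
        try:
            train_ds, eval_ds, spec = _condition_datasets(suite, cond)
            per_network = []
            models = []
            for r in range(suite.n_repeats):
                seed = suite.seed + 7919 * r + 13
                cfg = replace(suite.train_config, seed=seed)
                model = train(train_ds, spec, cfg)
                bal, imb, _ = evaluate_model(model, eval_ds)
                per_network.append((seed, bal, imb))
                models.append(model)
            # ensemble majority vote across networks, per subject
            correct = 0
            ens_preds = {}
            for sid in eval_ds.subjects():
                mask = eval_ds.subject_ids == sid
                pred = ensemble_predict(models, eval_ds.X[mask])
                ens_preds[sid] = pred.label
                correct += int(pred.label == eval_ds.subject_label(sid))
            cm = confusion_from_predictions(eval_ds, ens_preds)
            n_subj = cm.n_total
            p0 = max(cm.n_female, cm.n_male) / n_subj
            p_binom = binomial_test_onesided(correct, n_subj, p0)
            bals = np.array([x[1] for x in per_network])
            imbs = np.array([x[2] for x in per_network])
            results.append(
                ExperimentResult(
                    condition=cond.name,
                    per_network=per_network,
                    mean_balanced=float(bals.mean()),
                    sd_balanced=float(bals.std(ddof=1)) if len(bals) > 1 else 0.0,
                    mean_imbalanced=float(imbs.mean()),
                    sd_imbalanced=float(imbs.std(ddof=1)) if len(imbs) > 1 else 0.0,
                    p_binomial=p_binom,
                    ensemble_balanced=balanced_accuracy(cm),
                    adjusted_alpha=adj_alpha,
                    significant=p_binom < adj_alpha,
                )
            )
        except Exception as exc:  # noqa: BLE001 - condition-scoped diagnostics
            results.append(
                ExperimentResult(
                    condition=cond.name, per_network=[],
                    mean_balanced=float("nan"), sd_balanced=float("nan"),
                    mean_imbalanced=float("nan"), sd_imbalanced=float("nan"),
                    p_binomial=float("nan"), ensemble_balanced=float("nan"),
                    adjusted_alpha=adj_alpha, significant=False,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return results
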