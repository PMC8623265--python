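"""Cross-condition evaluation designs.

The study crosses three nuisance factors — muscle fatigue (MF),
forearm angle (FA) and acquisition time/day (AT) — against gesture
decoding accuracy:

* **MF**: at fixed day and angle, train on one fatigue class and test
  on each class (4 pairings: a->a, a->b, b->a, b->b).
* **FA**: rested trials only, same-day train/test, all 3x3
  train-angle x test-angle pairings.
* **AT**: rested trials only, fixed angle, all 3x3 train-day x
  test-day pairings.
* **COMBINED**: 18 fixed three-key models in three categories (AB_C,
  BC_A, CA_B) mixing all factors; two days train, the third tests.

Protocol: train and test sets are strictly separated at the recording
group level (no cross-validation); each pairing is repeated with
reshuffled group assignments and the mean accuracy over repetitions is
the headline number. Accuracy is per analysis window over the 11
analyzed gestures; the rest gesture is excluded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import classifiers
from .core import ANGLES, DAYS, REST_GESTURE, ConditionKey, DatasetRegistry
from .features import MinMaxNormalizer, extract
from .preprocessing import FilterSpec, WindowSpec, preprocess

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "design",
    "model_type",
    "subject",
    "train_keys",
    "test_key",
    "train_level",
    "test_level",
    "repetition",
    "accuracy",
]


@dataclass
class ExperimentResult:
    """Per-pairing, per-repetition accuracies plus aggregation helpers."""

    records: pd.DataFrame

    @property
    def mean_accuracy(self) -> float:
        return float(self.records["accuracy"].mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.records["accuracy"].std(ddof=1))

    def summary(self, by: Sequence[str] = ("train_keys", "test_key")) -> pd.DataFrame:
        g = self.records.groupby(list(by))["accuracy"]
        return g.agg(["mean", "std", "count"]).reset_index()

    def matrix(self) -> pd.DataFrame:
        """Mean accuracy pivot: train_level rows x test_level columns."""
        return self.records.pivot_table(
            index="train_level", columns="test_level", values="accuracy", aggfunc="mean"
        )

    def degradation(self) -> float:
        """Matched-condition mean accuracy minus mismatched mean accuracy."""
        same = self.records["train_level"] == self.records["test_level"]
        return float(
            self.records.loc[same, "accuracy"].mean()
            - self.records.loc[~same, "accuracy"].mean()
        )

    def per_subject_vectors(self) -> pd.DataFrame:
        """Subjects x pairings table of repetition-mean accuracies."""
        return self.records.pivot_table(
            index="subject",
            columns=["train_keys", "test_key"],
            values="accuracy",
            aggfunc="mean",
        )

    @staticmethod
    def concat(results: Sequence["ExperimentResult"]) -> "ExperimentResult":
        return ExperimentResult(
            pd.concat([r.records for r in results], ignore_index=True)
        )


@dataclass(frozen=True)
class CombinedModelSpec:
    """One row of the 18-model combined design."""

    category: str  # AB_C, BC_A or CA_B (train-days _ test-day)
    model_index: int  # 1..6 within the category
    train_keys: Tuple[ConditionKey, ConditionKey]
    test_key: ConditionKey
    irregular: bool = False  # deviates from the category's rotation pattern

    @property
    def label(self) -> str:
        return f"{self.category}:{self.model_index}"


# The fixed combined design: per category, six rows of
# (train key, train key, test key). The final CA_B row repeats A_b_30
# where the rotation pattern would give A_a_30; the published design is
# reproduced as printed and the row is flagged `irregular`.
_COMBINED_ROWS: List[Tuple[str, int, str, str, str, bool]] = [
    ("AB_C", 1, "A_b_30", "B_a_45", "C_a_75", False),
    ("AB_C", 2, "A_a_30", "B_b_45", "C_b_75", False),
    ("AB_C", 3, "A_a_45", "B_b_75", "C_a_30", False),
    ("AB_C", 4, "A_b_45", "B_a_75", "C_b_30", False),
    ("AB_C", 5, "A_a_75", "B_a_30", "C_b_45", False),
    ("AB_C", 6, "A_b_75", "B_b_30", "C_a_45", False),
    ("BC_A", 1, "B_b_30", "C_a_45", "A_a_75", False),
    ("BC_A", 2, "B_a_30", "C_b_45", "A_b_75", False),
    ("BC_A", 3, "B_a_45", "C_b_75", "A_a_30", False),
    ("BC_A", 4, "B_b_45", "C_a_75", "A_b_30", False),
    ("BC_A", 5, "B_a_75", "C_a_30", "A_b_45", False),
    ("BC_A", 6, "B_b_75", "C_b_30", "A_a_45", False),
    ("CA_B", 1, "C_b_30", "A_a_45", "B_a_75", False),
    ("CA_B", 2, "C_a_30", "A_b_45", "B_b_75", False),
    ("CA_B", 3, "C_a_45", "A_b_75", "B_a_30", False),
    ("CA_B", 4, "C_b_45", "A_a_75", "B_b_30", False),
    ("CA_B", 5, "C_a_75", "A_b_30", "B_b_45", False),
    ("CA_B", 6, "C_b_75", "A_b_30", "B_a_45", True),
]


def enumerate_combined_models() -> List[CombinedModelSpec]:
    """The 18 combined-design model specs, 6 per category, in order."""
    return [
        CombinedModelSpec(
            category=cat,
            model_index=idx,
            train_keys=(ConditionKey.from_label(k1), ConditionKey.from_label(k2)),
            test_key=ConditionKey.from_label(k3),
            irregular=irregular,
        )
        for cat, idx, k1, k2, k3, irregular in _COMBINED_ROWS
    ]


def build_registry(manifest, base_dir=None) -> DatasetRegistry:
    """Load a registry from a manifest table (path or DataFrame).

    Delegates to :func:`semgbench.io.build_registry`; kept here because
    the registry is the evaluation module's input surface.
    """
    from . import io as _io

    return _io.build_registry(manifest, base_dir=base_dir)


def featurize_registry(
    registry: DatasetRegistry,
    filter_spec: FilterSpec | None = None,
    window_spec: WindowSpec | None = None,
    eps: float = 20.0,
    class_b_window: Tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Run every recording through bandpass -> trim -> segment -> extract.

    Returns the study-wide feature table (16 feature columns + label +
    condition metadata + a ``key`` column with the dataset-class name).
    """
    kw = {} if class_b_window is None else {"class_b_window": class_b_window}
    frames = []
    for rec in registry.recordings():
        windows = preprocess(rec, filter_spec, window_spec, **kw)
        if windows:
            frames.append(extract(windows, eps))
    if not frames:
        raise ValueError("registry produced no analysis windows")
    table = pd.concat(frames, ignore_index=True)
    table["key"] = (
        table["day"] + "_" + table["fatigue"] + "_" + table["angle"].astype(str)
    )
    return table


def _check_separation(
    train: pd.DataFrame, test: pd.DataFrame
) -> None:
    """Structural guard: no (subject, key, group) triple in both sets."""
    tr = set(map(tuple, train[["subject", "key", "group"]].drop_duplicates().to_numpy()))
    te = set(map(tuple, test[["subject", "key", "group"]].drop_duplicates().to_numpy()))
    overlap = tr & te
    if overlap:
        raise ValueError(f"train/test overlap at group level: {sorted(overlap)[:3]} ...")


def _evaluate_split(
    train: pd.DataFrame,
    test: pd.DataFrame,
    model_type: str,
    sigma: float,
    rng: np.random.Generator | None = None,
    shuffle_labels: bool = False,
) -> float:
    _check_separation(train, test)
    if shuffle_labels:
        train = train.copy()
        train["gesture"] = rng.permutation(train["gesture"].to_numpy())
    norm = MinMaxNormalizer().fit(train)
    model = classifiers.fit(model_type, norm.transform(train), sigma=sigma)
    preds = classifiers.predict(model, norm.transform(test))
    return classifiers.accuracy(preds, test["gesture"].to_numpy())


def run_pairing(
    features: pd.DataFrame,
    train_keys: Sequence[ConditionKey | str],
    test_key: ConditionKey | str,
    model_type: str = "lda",
    n_rep: int = 10,
    seed: int = 0,
    sigma: float = 0.3,
    subjects: Sequence[str] | None = None,
    shuffle_labels: bool = False,
    design: str = "PAIRING",
    train_level: str | None = None,
    test_level: str | None = None,
) -> ExperimentResult:
    """One train-keys -> test-key pairing, repeated with reshuffled groups.

    Each repetition permutes the group indices, trains on the first
    ceil(n/2) groups of the training keys and tests on the remaining
    groups of the test key — train and test never share a group index,
    which enforces the group-level separation invariant even when a key
    appears on both sides. Accuracy is per window over the 11 analyzed
    gestures.
    """
    train_labels = [
        k.label if isinstance(k, ConditionKey) else str(k) for k in train_keys
    ]
    test_label = test_key.label if isinstance(test_key, ConditionKey) else str(test_key)
    df = features[features["gesture"] != REST_GESTURE]
    subjects = list(subjects) if subjects is not None else sorted(df["subject"].unique())
    rows = []
    for si, subject in enumerate(subjects):
        sub = df[df["subject"] == subject]
        groups = np.sort(
            sub.loc[sub["key"].isin(train_labels + [test_label]), "group"].unique()
        )
        if len(groups) < 2:
            raise ValueError(
                f"subject {subject}: need >= 2 groups for a separated split, "
                f"have {len(groups)}"
            )
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(si,)))
        n_train = (len(groups) + 1) // 2
        for rep in range(n_rep):
            perm = rng.permutation(groups)
            tr_groups, te_groups = perm[:n_train], perm[n_train:]
            train = sub[sub["key"].isin(train_labels) & sub["group"].isin(tr_groups)]
            test = sub[(sub["key"] == test_label) & sub["group"].isin(te_groups)]
            if train.empty or test.empty:
                raise ValueError(
                    f"empty split for subject {subject}: keys {train_labels} -> {test_label}"
                )
            acc = _evaluate_split(train, test, model_type, sigma, rng, shuffle_labels)
            rows.append(
                {
                    "design": design,
                    "model_type": model_type,
                    "subject": subject,
                    "train_keys": "+".join(train_labels),
                    "test_key": test_label,
                    "train_level": train_level if train_level is not None else "+".join(train_labels),
                    "test_level": test_level if test_level is not None else test_label,
                    "repetition": rep,
                    "accuracy": acc,
                }
            )
    return ExperimentResult(pd.DataFrame(rows, columns=RESULT_COLUMNS))


def influence_of_fatigue(
    features: pd.DataFrame,
    model_type: str = "lda",
    day: str = "A",
    angle: int = 45,
    n_rep: int = 10,
    seed: int = 0,
    sigma: float = 0.3,
) -> ExperimentResult:
    """MF design: the four fatigue pairings a->a, a->b, b->a, b->b
    at fixed day and angle. ``degradation()`` on the result gives the
    matched-minus-mismatched accuracy delta."""
    parts = []
    for i, (ftr, fte) in enumerate([("a", "a"), ("a", "b"), ("b", "a"), ("b", "b")]):
        parts.append(
            run_pairing(
                features,
                [ConditionKey(day, ftr, angle)],
                ConditionKey(day, fte, angle),
                model_type=model_type,
                n_rep=n_rep,
                seed=seed * 101 + i,
                sigma=sigma,
                design="MF",
                train_level=ftr,
                test_level=fte,
            )
        )
    return ExperimentResult.concat(parts)


def influence_of_angle(
    features: pd.DataFrame,
    model_type: str = "lda",
    fatigue: str = "a",
    days: Sequence[str] | None = None,
    angles: Sequence[int] = ANGLES,
    n_rep: int = 10,
    seed: int = 0,
    sigma: float = 0.3,
) -> ExperimentResult:
    """FA design: same-day 3x3 train-angle x test-angle matrix, rested
    trials only, aggregated over days."""
    days = list(days) if days is not None else sorted(features["day"].unique())
    parts = []
    i = 0
    for day in days:
        for ta in angles:
            for va in angles:
                parts.append(
                    run_pairing(
                        features,
                        [ConditionKey(day, fatigue, ta)],
                        ConditionKey(day, fatigue, va),
                        model_type=model_type,
                        n_rep=n_rep,
                        seed=seed * 101 + i,
                        sigma=sigma,
                        design="FA",
                        train_level=str(ta),
                        test_level=str(va),
                    )
                )
                i += 1
    return ExperimentResult.concat(parts)


def influence_of_time(
    features: pd.DataFrame,
    model_type: str = "lda",
    fatigue: str = "a",
    angle: int = 45,
    days: Sequence[str] = DAYS,
    n_rep: int = 10,
    seed: int = 0,
    sigma: float = 0.3,
) -> ExperimentResult:
    """AT design: 3x3 train-day x test-day matrix at fixed angle,
    rested trials only."""
    parts = []
    i = 0
    for td in days:
        for vd in days:
            parts.append(
                run_pairing(
                    features,
                    [ConditionKey(td, fatigue, angle)],
                    ConditionKey(vd, fatigue, angle),
                    model_type=model_type,
                    n_rep=n_rep,
                    seed=seed * 101 + i,
                    sigma=sigma,
                    design="AT",
                    train_level=td,
                    test_level=vd,
                )
            )
            i += 1
    return ExperimentResult.concat(parts)


def run_combined(
    features: pd.DataFrame,
    model_type: str = "lda",
    seed: int = 0,
    sigma: float = 0.3,
    points_per_subject: int = 10,
    train_groups_per_key: int = 2,
) -> ExperimentResult:
    """COMBINED design: the 18 fixed three-key models.

    Per model and subject: repeatedly draw ``train_groups_per_key``
    groups at random from each of the two training keys, then test on
    each group of the test key in turn — one accuracy point per test
    group — until ``points_per_subject`` points are collected. With at
    least five subjects, the best- and worst-performing subjects (by
    mean accuracy over all models) are dropped, leaving the middle
    three: 30 points per model at the full design. With fewer subjects
    all are kept and a deviation notice is logged.
    """
    df = features[features["gesture"] != REST_GESTURE]
    subjects = sorted(df["subject"].unique())
    models = enumerate_combined_models()
    rows = []
    for si, subject in enumerate(subjects):
        sub = df[df["subject"] == subject]
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(si, 7)))
        for spec in models:
            groups = np.sort(sub.loc[sub["key"] == spec.test_key.label, "group"].unique())
            if len(groups) == 0:
                raise ValueError(
                    f"subject {subject}: no groups for test key {spec.test_key.label}"
                )
            point = 0
            while point < points_per_subject:
                train_parts = []
                for key in spec.train_keys:
                    kg = np.sort(sub.loc[sub["key"] == key.label, "group"].unique())
                    take = min(train_groups_per_key, len(kg))
                    chosen = rng.choice(kg, size=take, replace=False)
                    train_parts.append(
                        sub[(sub["key"] == key.label) & sub["group"].isin(chosen)]
                    )
                train = pd.concat(train_parts, ignore_index=True)
                for g in groups:
                    if point >= points_per_subject:
                        break
                    test = sub[(sub["key"] == spec.test_key.label) & (sub["group"] == g)]
                    acc = _evaluate_split(train, test, model_type, sigma)
                    rows.append(
                        {
                            "design": "COMBINED",
                            "model_type": model_type,
                            "subject": subject,
                            "train_keys": "+".join(k.label for k in spec.train_keys),
                            "test_key": spec.test_key.label,
                            "train_level": spec.category,
                            "test_level": spec.label,
                            "repetition": point,
                            "accuracy": acc,
                        }
                    )
                    point += 1
    records = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(subjects) >= 5:
        by_subject = records.groupby("subject")["accuracy"].mean().sort_values()
        dropped = [by_subject.index[0], by_subject.index[-1]]
        records = records[~records["subject"].isin(dropped)].reset_index(drop=True)
        logger.info("combined design: dropped best/worst subjects %s", dropped)
    else:
        logger.warning(
            "combined design: only %d subjects, best/worst trimming skipped "
            "(needs >= 5); keeping all",
            len(subjects),
        )
    return ExperimentResult(records)


def pearson_trend(result: ExperimentResult) -> pd.DataFrame:
    """Per-subject Pearson R against the mean accuracy profile of the rest.

    Each subject's accuracy vector over the design's pairings (mean
    over repetitions) is correlated with the element-wise mean vector
    of the remaining subjects. A zero-variance vector yields NaN.
    """
    table = result.per_subject_vectors()
    if table.shape[1] < 3:
        raise ValueError("pearson_trend needs >= 3 pairings per subject")
    rows = []
    for subject in table.index:
        own = table.loc[subject].to_numpy(dtype=float)
        others = table.drop(index=subject).mean(axis=0).to_numpy(dtype=float)
        if len(table.index) < 2 or np.std(own) == 0 or np.std(others) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(own, others).statistic)
        rows.append({"subject": subject, "r": r, "n_points": own.size})
    return pd.DataFrame(rows)


def degradation_summary(
    mf: ExperimentResult, fa: ExperimentResult, at: ExperimentResult
) -> pd.DataFrame:
    """Mean matched-minus-mismatched degradation per design (MF/FA/AT)."""
    return pd.DataFrame(
        [
            {"design": name, "degradation": res.degradation()}
            for name, res in (("MF", mf), ("FA", fa), ("AT", at))
        ]
    )
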