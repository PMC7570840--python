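"""Evaluation protocol: split plan, per-type accuracy tables, case experiment.

The study design trains one binary weed/rice network per feature group
on 1200 signals (300 per contact type) and evaluates it on three
testing sets of 200 signals whose per-type allocations deliberately
differ (the second and third sets swap 7 signals between types A and B).
Reports mirror the published tables: per-type correct counts, weed
accuracy (type A) and rice accuracy (types B, C, D pooled), to one
decimal.  The contact-position experiment is reproduced as a simulated
analogue: batches of rice-contact signals of one type (end / middle /
root of the gasbag) are classified and the percentage recognised as
rice is the case's recognition rate, to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import mlp
from .features import FEATURE_COLUMNS, FEATURE_GROUPS, FEATURE_LETTERS, extract_feature_table
from .mlp import MLPConfig, MLPModel
from .signals import (
    CLASS_LABELS,
    ClassPreset,
    LabeledDataset,
    binary_label,
    generate_dataset,
)

__all__ = [
    "SplitPlan",
    "SplitDatasets",
    "EvaluationReport",
    "GroupModel",
    "table4_plan",
    "confusion_by_type",
    "class_accuracies",
    "make_split_datasets",
    "run_group_experiment",
    "run_case_experiment",
    "average_rate",
    "CASE_CONTACT_TYPE",
]

#: Contact-position cases of the recognition experiment mapped to the
#: rice signal type they produce: end (I), middle (II), root (III).
CASE_CONTACT_TYPE = {"I": "B", "II": "C", "III": "D"}


@dataclass(frozen=True)
class SplitPlan:
    """Per-class allocations of the training set and the testing sets."""

    training: Dict[str, int]
    testing: Tuple[Dict[str, int], ...]

    def __post_init__(self) -> None:
        for alloc in (self.training, *self.testing):
            if any(v < 0 for v in alloc.values()):
                raise ValueError("allocations must be non-negative")


def table4_plan() -> SplitPlan:
    """The study's split: 300 signals per type for training and three
    200-signal testing sets with allocations (50/50/50/50), (57/43/50/50)
    and (43/57/50/50) for types A–D."""
    return SplitPlan(
        training={c: 300 for c in CLASS_LABELS},
        testing=(
            {"A": 50, "B": 50, "C": 50, "D": 50},
            {"A": 57, "B": 43, "C": 50, "D": 50},
            {"A": 43, "B": 57, "C": 50, "D": 50},
        ),
    )


def uniform_plan(train_per_class: int, test_per_class: int, n_sets: int = 3) -> SplitPlan:
    return SplitPlan(
        training={c: train_per_class for c in CLASS_LABELS},
        testing=tuple({c: test_per_class for c in CLASS_LABELS} for _ in range(n_sets)),
    )


@dataclass
class SplitDatasets:
    """Generated signals for a split plan."""

    training: LabeledDataset
    testing: List[LabeledDataset]


@dataclass
class EvaluationReport:
    """Per-testing-set correct counts and weed/rice accuracies."""

    group_id: str
    feature_letters: str
    correct_counts: List[Dict[str, int]]
    allocations: List[Dict[str, int]]
    weed_accuracy: List[float]
    rice_accuracy: List[float]

    def as_table(self):
        """Rows: correct counts per type then accuracies; columns: testing sets."""
        import pandas as pd

        rows = {
            f"Correct number of type {c}": [cc[c] for cc in self.correct_counts]
            for c in CLASS_LABELS
        }
        rows["Accuracy of weeds"] = self.weed_accuracy
        rows["Accuracy of rice"] = self.rice_accuracy
        return pd.DataFrame(
            rows, index=[f"Testing set {i + 1}" for i in range(len(self.correct_counts))]
        ).T


def confusion_by_type(
    predicted: Sequence[str], true_types: Sequence[str]
) -> Dict[str, int]:
    """Count, per contact type A–D, the correctly classified samples.

    ``predicted`` holds binary labels ("weed"/"rice"); a type-A sample is
    correct when predicted weed, a B/C/D sample when predicted rice.
    """
    if len(predicted) != len(true_types):
        raise ValueError("prediction and truth lengths differ")
    counts = {c: 0 for c in CLASS_LABELS}
    for pred, true_type in zip(predicted, true_types):
        if true_type not in counts:
            raise ValueError(f"unknown contact type {true_type!r}")
        if pred == binary_label(true_type):
            counts[true_type] += 1
    return counts


def class_accuracies(
    correct_counts: Mapping[str, int], allocation: Mapping[str, int]
) -> Tuple[float, float]:
    """Weed and rice accuracies in percent, rounded to one decimal."""
    for c in CLASS_LABELS:
        if correct_counts.get(c, 0) > allocation.get(c, 0):
            raise ValueError(f"more correct type-{c} samples than allocated")
    n_weed = allocation.get("A", 0)
    n_rice = sum(allocation.get(c, 0) for c in "BCD")
    if n_weed == 0 or n_rice == 0:
        raise ValueError("allocation must include weed and rice samples")
    weed = 100.0 * correct_counts.get("A", 0) / n_weed
    rice = 100.0 * sum(correct_counts.get(c, 0) for c in "BCD") / n_rice
    return round(weed, 1), round(rice, 1)


# ---------------------------------------------------------------------------
# Group experiments
# ---------------------------------------------------------------------------

def make_split_datasets(
    presets: Mapping[str, ClassPreset],
    plan: Optional[SplitPlan] = None,
    n: int = 1024,
    seed: int = 0,
) -> SplitDatasets:
    """Generate training and testing datasets from independent seed streams."""
    plan = plan or table4_plan()
    training = generate_dataset(plan.training, presets, n=n, seed=seed)
    testing = [
        generate_dataset(alloc, presets, n=n, seed=int(seed) + 1 + i)
        for i, alloc in enumerate(plan.testing)
    ]
    return SplitDatasets(training=training, testing=testing)


def _letters_to_columns(letters: str) -> List[str]:
    if not letters:
        raise ValueError("feature group must name at least one feature")
    cols = []
    for letter in letters:
        if letter not in FEATURE_LETTERS:
            raise ValueError(f"unknown feature letter {letter!r}")
        cols.append(FEATURE_COLUMNS[FEATURE_LETTERS.index(letter)])
    return cols


@dataclass
class GroupModel:
    """A trained network together with the feature letters it consumes."""

    model: MLPModel
    feature_letters: str


def train_group_model(
    feature_table,
    letters: str,
    config: Optional[MLPConfig] = None,
    seed: int = 0,
) -> GroupModel:
    """Train the binary classifier on one feature subset of a feature table."""
    cols = _letters_to_columns(letters)
    if config is None:
        # Default width 12 admits up to five inputs; wider groups get the
        # minimum admissible hidden layer under the 2M+1 sizing rule.
        config = MLPConfig(hidden_size=max(12, 2 * len(cols) + 1))
    X = feature_table[cols].to_numpy(dtype=float)
    y = [binary_label(c) for c in feature_table["class_label"]]
    model = mlp.train(X, y, config, seed=seed, feature_names=cols)
    return GroupModel(model=model, feature_letters=letters)


def classify_table(group_model: GroupModel, feature_table) -> np.ndarray:
    cols = _letters_to_columns(group_model.feature_letters)
    labels, _ = mlp.predict(group_model.model, feature_table[cols].to_numpy(float))
    return labels


def run_group_experiment(
    split: SplitDatasets,
    feature_letters: str,
    config: Optional[MLPConfig] = None,
    seed: int = 0,
    group_id: Optional[str] = None,
    feature_tables: Optional[Tuple] = None,
) -> EvaluationReport:
    """Train on the split's training set and evaluate the three testing sets.

    ``feature_tables`` may carry pre-extracted (train, [test...]) tables
    to avoid re-extracting features when several groups share one split.
    """
    if feature_tables is None:
        train_table = extract_feature_table(split.training)
        test_tables = [extract_feature_table(ds) for ds in split.testing]
    else:
        train_table, test_tables = feature_tables
    gm = train_group_model(train_table, feature_letters, config, seed=seed)
    correct_counts, allocations, weed_acc, rice_acc = [], [], [], []
    for ds, table in zip(split.testing, test_tables):
        predicted = classify_table(gm, table)
        counts = confusion_by_type(predicted, list(table["class_label"]))
        weed, rice = class_accuracies(counts, ds.allocation)
        correct_counts.append(counts)
        allocations.append(dict(ds.allocation))
        weed_acc.append(weed)
        rice_acc.append(rice)
    if group_id is None:
        group_id = next(
            (g for g, ls in FEATURE_GROUPS.items() if ls == feature_letters), "custom"
        )
    return EvaluationReport(
        group_id=group_id,
        feature_letters=feature_letters,
        correct_counts=correct_counts,
        allocations=allocations,
        weed_accuracy=weed_acc,
        rice_accuracy=rice_acc,
    )


# ---------------------------------------------------------------------------
# Simulated contact-position experiment
# ---------------------------------------------------------------------------

def run_case_experiment(
    case: str,
    n_rice: int,
    presets: Mapping[str, ClassPreset],
    group_model: GroupModel,
    seed: int = 0,
    n: int = 1024,
) -> float:
    """Recognition rate (%) for one contact-position case.

    Simulates ``n_rice`` rice-contact signals of the case's type
    (I → B, II → C, III → D), classifies them with the trained model and
    returns the percentage recognised as rice, rounded to two decimals.
    """
    if case not in CASE_CONTACT_TYPE:
        raise ValueError("case must be one of 'I', 'II', 'III'")
    if n_rice < 1:
        raise ValueError("n_rice must be positive")
    contact_type = CASE_CONTACT_TYPE[case]
    ds = generate_dataset({contact_type: n_rice}, presets, n=n, seed=seed)
    table = extract_feature_table(ds)
    predicted = classify_table(group_model, table)
    return round(100.0 * float(np.mean(predicted == "rice")), 2)


def average_rate(rates: Sequence[float]) -> float:
    """Arithmetic mean of recognition rates, to two decimals."""
    if len(rates) == 0:
        raise ValueError("need at least one rate")
    return round(float(np.mean(rates)), 2)
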