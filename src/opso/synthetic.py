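"""Synthetic eye-tracking-style tabular datasets.

Generates datasets with the structure of per-subject reading-task feature
tables (one row per child, real-valued fixation/saccade summary statistics,
a balanced dyslexic/control label): a handful of informative features whose
class means differ by a controlled standardized effect size — mimicking the
longer fixations, shorter saccades and extra regressions of dyslexic
readers — plus noisy linear copies of them (redundant features) and pure
noise columns.  The ground-truth informative mask ships with each dataset,
which is what makes feature-selection recovery testable at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .selection import FeatureDataset

__all__ = ["SynthSpec", "generate_etdd_like", "generate_task_suite",
           "write_dataset_csv", "read_dataset_csv"]


@dataclass
class SynthSpec:
    """Recipe for one synthetic per-subject feature table.

    Defaults follow the 70-subject, 50 % positive, 34-feature tabular task
    layout.  ``effect_size`` is the standardized mean difference of each
    informative feature between classes (features have unit within-class
    standard deviation); ``noise_sd`` is the sd of the noise added to the
    redundant copies.
    """

    n_subjects: int = 70
    positive_fraction: float = 0.5
    n_features: int = 34
    n_informative: int = 6
    n_redundant: int = 4
    effect_size: float = 1.2
    noise_sd: float = 0.5
    seed: int = 0
    task_name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ConfigurationError("need at least 4 subjects")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ConfigurationError("positive_fraction must be in (0, 1)")
        if self.n_informative < 0 or self.n_redundant < 0:
            raise ConfigurationError("feature counts must be non-negative")
        if self.n_informative + self.n_redundant > self.n_features:
            raise ConfigurationError(
                "n_informative + n_redundant exceeds n_features"
            )
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ConfigurationError("redundant features require informative ones")
        n_pos = round(self.n_subjects * self.positive_fraction)
        if n_pos == 0 or n_pos == self.n_subjects:
            raise ConfigurationError("both classes must be non-empty")


def generate_etdd_like(spec: SynthSpec) -> FeatureDataset:
    """Generate one dataset following the planted-signal model.

    Class counts are exact (``round(n_subjects · positive_fraction)``
    positives), informative features are unit-variance Gaussians whose class
    means differ by ``effect_size``, redundant features are informative
    columns plus N(0, noise_sd²), and the rest is pure N(0, 1) noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_features
    n_pos = round(n * spec.positive_fraction)
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    X = rng.standard_normal((n, p))
    k_inf, k_red = spec.n_informative, spec.n_redundant
    # class-mean shift on the informative block
    X[:, :k_inf] += spec.effect_size * y[:, None]
    if k_red:
        src = np.arange(k_red) % k_inf
        X[:, k_inf:k_inf + k_red] = (
            X[:, src] + spec.noise_sd * rng.standard_normal((n, k_red))
        )
    truth = np.zeros(p, dtype=int)
    truth[:k_inf + k_red] = 1
    subject_id = np.array([f"S{i + 1:03d}" for i in range(n)])
    # shuffle rows so label order carries no information
    order = rng.permutation(n)
    return FeatureDataset(
        X=X[order],
        y=y[order],
        subject_id=subject_id,          # ids assigned after shuffling rows
        task_name=spec.task_name,
        truth_mask=truth,
        feature_names=[f"f{j:03d}" for j in range(p)],
    )


# feature counts of the six emulated reading-task datasets and a documented
# difficulty gradient (larger effect size = easier task)
_SUITE_LAYOUT = [
    ("D1", 450, 1.5),
    ("D2", 34, 1.2),
    ("D3", 34, 0.9),
    ("D4", 450, 1.5),
    ("D5", 34, 1.2),
    ("D6", 34, 0.9),
]


def generate_task_suite(seed: int) -> list[FeatureDataset]:
    """Six datasets emulating the task layout (450/34/34 features, twice).

    Per-dataset seeds are derived deterministically from the master seed and
    differ pairwise.
    """
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31, size=len(_SUITE_LAYOUT))
    out = []
    for (name, p, eff), s in zip(_SUITE_LAYOUT, sub_seeds):
        k_inf = max(3, p // 20) if p <= 50 else 20
        spec = SynthSpec(
            n_subjects=70,
            positive_fraction=0.5,
            n_features=p,
            n_informative=k_inf,
            n_redundant=k_inf // 2,
            effect_size=eff,
            noise_sd=0.5,
            seed=int(s),
            task_name=name,
        )
        out.append(generate_etdd_like(spec))
    return out


def write_dataset_csv(dataset: FeatureDataset, path: str | Path) -> None:
    """Write a dataset as delimited text (12 significant digits, so that a
    write/read round trip is bit-identical)."""
    from .io_utils import atomic_write_text

    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    df.insert(0, "subject_id", dataset.subject_id)
    df["label"] = dataset.y
    atomic_write_text(path, df.to_csv(index=False, float_format="%.12g"))


def read_dataset_csv(path: str | Path, task_name: str = "") -> FeatureDataset:
    """Read a delimited-text dataset (reserved columns subject_id, label)."""
    from .selection import dataset_from_dataframe

    df = pd.read_csv(path)
    return dataset_from_dataframe(df, task_name=task_name or Path(path).stem)
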