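"""Exhaustive feature-subset sweep with best-per-size reporting.

Every non-empty subset of the configured features trains its own freshly
initialized model on the chromosome-held-out split; the held-out Pearson r
per subset is recorded and the best combination per subset size reported
(e.g. 255 subsets for 8 features, 63 for 5). Per-subset seeds derive
deterministically from a master seed; the on-disk record table makes an
interrupted sweep resumable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import BinnedStore
from .evaluation import SplitSpec, pearson, split_bins
from .model import ModelSpec, predict, train

__all__ = ["SweepRecord", "SweepResult", "enumerate_subsets", "run_sweep"]

_MAX_FEATURES = 16


@dataclass
class SweepRecord:
    subset: tuple[str, ...]
    n_features: int
    pearson_r: float | None
    n_train_bins: int
    n_test_bins: int
    seed: int
    epochs_run: int


@dataclass
class SweepResult:
    """All per-subset records plus the derived best-per-size table."""

    records: list[SweepRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset": [";".join(r.subset) for r in self.records],
                "n_features": [r.n_features for r in self.records],
                "pearson_r": [r.pearson_r for r in self.records],
                "n_train_bins": [r.n_train_bins for r in self.records],
                "n_test_bins": [r.n_test_bins for r in self.records],
                "seed": [r.seed for r in self.records],
                "epochs_run": [r.epochs_run for r in self.records],
            }
        )

    def best_per_n(self) -> dict[int, SweepRecord]:
        """Max-r record per subset size; ties break to the lexicographically
        first subset (records are enumerated in that order)."""
        best: dict[int, SweepRecord] = {}
        for rec in self.records:
            if rec.pearson_r is None:
                continue
            cur = best.get(rec.n_features)
            if cur is None or rec.pearson_r > cur.pearson_r:
                best[rec.n_features] = rec
        return best

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "SweepResult":
        frame = pd.read_csv(path, sep="\t")
        result = cls()
        for _, row in frame.iterrows():
            result.records.append(
                SweepRecord(
                    subset=tuple(str(row["subset"]).split(";")),
                    n_features=int(row["n_features"]),
                    pearson_r=None if pd.isna(row["pearson_r"]) else float(row["pearson_r"]),
                    n_train_bins=int(row["n_train_bins"]),
                    n_test_bins=int(row["n_test_bins"]),
                    seed=int(row["seed"]),
                    epochs_run=int(row["epochs_run"]),
                )
            )
        return result


def enumerate_subsets(feature_names: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically.

    Guarded at 16 features (65535 subsets); beyond that pass an explicit
    subset list to :func:`run_sweep`.
    """
    names = list(feature_names)
    if not 1 <= len(names) <= _MAX_FEATURES:
        raise ValueError(
            f"{len(names)} features; exhaustive enumeration supports 1-"
            f"{_MAX_FEATURES} — pass an explicit subset list instead"
        )
    if len(names) != len(set(names)):
        raise ValueError("duplicate feature names")
    out: list[tuple[str, ...]] = []
    for size in range(1, len(names) + 1):
        out.extend(sorted(combinations(sorted(names), size)))
    return out


def _subset_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    store: BinnedStore,
    subsets: Sequence[Sequence[str]],
    split: SplitSpec,
    spec_template: ModelSpec,
    master_seed: int = 0,
    resume_path: str | Path | None = None,
) -> SweepResult:
    """Train one model per feature subset and record held-out Pearson r.

    ``spec_template.n_features`` and ``spec_template.seed`` are overridden
    per subset. With ``resume_path``, completed subsets found in an existing
    record table are skipped and new records appended after each training.
    """
    for subset in subsets:
        unknown = [n for n in subset if n not in store.features]
        if unknown:
            raise KeyError(f"unknown features in subset {tuple(subset)}: {unknown}")
    result = SweepResult()
    done: set[tuple[str, ...]] = set()
    if resume_path is not None and Path(resume_path).exists():
        result = SweepResult.load(resume_path)
        done = {rec.subset for rec in result.records}

    train_idx, val_idx, test_idx = split_bins(store.bins, split)
    for index, subset in enumerate(subsets):
        subset = tuple(subset)
        if subset in done:
            continue
        matrix, targets, _ = store.prepare(subset)
        valid = matrix.valid
        tr = train_idx[valid[train_idx]]
        va = val_idx[valid[val_idx]]
        te = test_idx[valid[test_idx]]
        seed = _subset_seed(master_seed, index)
        spec = ModelSpec(
            n_features=len(subset),
            n_filters=spec_template.n_filters,
            kernel_width=spec_template.kernel_width,
            hidden_dim=spec_template.hidden_dim,
            batch_size=spec_template.batch_size,
            patience_epochs=spec_template.patience_epochs,
            max_epochs=spec_template.max_epochs,
            learning_rate=spec_template.learning_rate,
            seed=seed,
        )
        state, log = train(
            spec, matrix.data[tr], targets[tr], matrix.data[va], targets[va],
            feature_names=subset,
        )
        preds = predict(state, matrix.data[te])
        r = pearson(targets[te], preds) if len(te) >= 2 else None
        result.records.append(
            SweepRecord(
                subset=subset,
                n_features=len(subset),
                pearson_r=r,
                n_train_bins=len(tr),
                n_test_bins=len(te),
                seed=seed,
                epochs_run=log.epochs_run,
            )
        )
        if resume_path is not None:
            result.save(resume_path)
    return result
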