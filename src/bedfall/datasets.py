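"""Class-balanced dataset assembly, splits, and CSV persistence.

A dataset is a pandas DataFrame with the frozen schema

    mode, c, y, u_00..u_25, v_00..v_12, episode_seed

(`mode` is the posture-mode name or ``"none"``; ``c`` the binary fall
label; ``y`` the continuous discounted risk label).  Files are UTF-8 CSV
with ``#``-prefixed JSON metadata lines (discount, frame rate, window, bed
bounds, engine version) before the header, written at full float precision
so round-trips are lossless.

Class balancing follows the simulate-until-quota protocol: episodes are
generated until exactly ceil(N/2) falls and floor(N/2) non-falls are
collected; surplus episodes of a filled class are discarded and all
rejections (drop timeouts, instability) are tallied, never silently
dropped.  Pose-balanced test sets instead pin the posture mode and collect
exactly n/4 accepted episodes per mode.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .episodes import EpisodeBatch
from .sampling import MODES
from .skeleton import FEATURE_COLUMNS, VALIDITY_COLUMNS

SCHEMA_COLUMNS = ["mode", "c", "y"] + FEATURE_COLUMNS + VALIDITY_COLUMNS + ["episode_seed"]

MODE_NONE = "none"

#: pipeline signature: (seeds, forced_modes) -> EpisodeBatch
Pipeline = Callable[..., EpisodeBatch]


class BudgetExhaustedError(RuntimeError):
    """Per-class quota unreachable within the episode budget."""


class CsvSchemaError(ValueError):
    """CSV file does not match the dataset schema."""


@dataclass(frozen=True)
class DatasetSpec:
    """Target size and construction settings of a labeled dataset."""

    n_total: int
    balance: bool = True
    sampling_strategy: str = "pose_stratified"
    split_ratio: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be at least 2")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")


@dataclass
class BuildStats:
    """Generation accounting: episodes run, rejections, surplus discards."""

    episodes_run: int = 0
    rejections: dict = field(default_factory=dict)
    surplus_discarded: dict = field(default_factory=dict)

    def add_rejection(self, reason: str, k: int = 1) -> None:
        if k:
            self.rejections[reason] = self.rejections.get(reason, 0) + k

    def add_surplus(self, label: str, k: int = 1) -> None:
        if k:
            self.surplus_discarded[label] = self.surplus_discarded.get(label, 0) + k


def batch_to_frame(batch: EpisodeBatch, which: np.ndarray) -> pd.DataFrame:
    """Schema DataFrame from the selected rows of an episode batch."""
    idx = np.flatnonzero(which)
    mode = np.where(batch.mode[idx] == "", MODE_NONE, batch.mode[idx])
    data = {"mode": mode, "c": batch.c[idx], "y": batch.y[idx]}
    for j, col in enumerate(FEATURE_COLUMNS):
        data[col] = batch.u[idx, j]
    for j, col in enumerate(VALIDITY_COLUMNS):
        data[col] = batch.validity[idx, j]
    data["episode_seed"] = batch.seeds[idx]
    return pd.DataFrame(data, columns=SCHEMA_COLUMNS)


def build_balanced_dataset(
    rng: np.random.Generator,
    spec: DatasetSpec,
    pipeline: Pipeline,
    batch_size: int = 4096,
    max_episodes: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, BuildStats]:
    """Simulate until exact class quotas are reached.

    Returns ``(df, frames, stats)`` where ``frames`` is the aligned
    (n, 5, 26) sequence array for sequence models.  Raises
    :class:`BudgetExhaustedError` if a class quota cannot be filled within
    ``max_episodes`` (default ``200 * n_total + 20000``).
    """
    spec.validate()
    need = {1: math.ceil(spec.n_total / 2), 0: spec.n_total // 2}
    if not spec.balance:
        need = {1: 0, 0: 0}
    budget = max_episodes if max_episodes is not None else 200 * spec.n_total + 20000
    stats = BuildStats()
    parts: list[pd.DataFrame] = []
    frame_parts: list[np.ndarray] = []
    n_unbalanced = 0
    while True:
        if spec.balance:
            if need[0] == 0 and need[1] == 0:
                break
        elif n_unbalanced >= spec.n_total:
            break
        if stats.episodes_run >= budget:
            raise BudgetExhaustedError(
                f"class quotas unreachable: still need {need} after {stats.episodes_run} episodes"
            )
        n_batch = min(batch_size, budget - stats.episodes_run)
        seeds = rng.integers(0, 2**31 - 1, size=n_batch)
        batch = pipeline(seeds)
        stats.episodes_run += n_batch
        for reason in (set(batch.reject_reason) - {""}):
            stats.add_rejection(reason, int(np.sum(batch.reject_reason == reason)))
        if spec.balance:
            take = np.zeros(len(batch), bool)
            for label in (1, 0):
                cls = np.flatnonzero(batch.accepted & (batch.c == label))
                keep = cls[: need[label]]
                take[keep] = True
                need[label] -= len(keep)
                stats.add_surplus("fall" if label else "non_fall", len(cls) - len(keep))
        else:
            take = batch.accepted.copy()
            extra = int(take.sum()) - (spec.n_total - n_unbalanced)
            if extra > 0:
                drop = np.flatnonzero(take)[-extra:]
                take[drop] = False
            n_unbalanced += int(take.sum())
        if take.any():
            parts.append(batch_to_frame(batch, take))
            frame_parts.append(batch.frames[np.flatnonzero(take)])
    df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=SCHEMA_COLUMNS)
    frames = np.concatenate(frame_parts) if frame_parts else np.zeros((0, 5, 26))
    return df, frames, stats


def build_pose_balanced_test_set(
    rng: np.random.Generator,
    n_test: int,
    pipeline: Pipeline,
    batch_size: int = 4096,
    max_episodes: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, BuildStats]:
    """Collect exactly n_test/4 accepted episodes per posture mode."""
    if n_test % 4 != 0:
        raise ValueError("pose-balanced test size must be divisible by 4")
    quota = n_test // 4
    budget = max_episodes if max_episodes is not None else 200 * n_test + 20000
    stats = BuildStats()
    parts: list[pd.DataFrame] = []
    frame_parts: list[np.ndarray] = []
    for mode in MODES:
        got = 0
        while got < quota:
            if stats.episodes_run >= budget:
                raise BudgetExhaustedError(f"pose quota unreachable for {mode.value}")
            n_batch = min(batch_size, budget - stats.episodes_run)
            seeds = rng.integers(0, 2**31 - 1, size=n_batch)
            batch = pipeline(seeds, forced_modes=[mode] * n_batch)
            stats.episodes_run += n_batch
            for reason in (set(batch.reject_reason) - {""}):
                stats.add_rejection(reason, int(np.sum(batch.reject_reason == reason)))
            acc = np.flatnonzero(batch.accepted)
            keep = acc[: quota - got]
            got += len(keep)
            take = np.zeros(len(batch), bool)
            take[keep] = True
            if take.any():
                parts.append(batch_to_frame(batch, take))
                frame_parts.append(batch.frames[np.flatnonzero(take)])
    df = pd.concat(parts, ignore_index=True)
    frames = np.concatenate(frame_parts)
    return df, frames, stats


def split_train_val(
    dataset: pd.DataFrame, ratio: float = 0.9, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded shuffle-split into disjoint, exhaustive train/validation parts.

    The returned frames keep the original integer index so aligned arrays
    (e.g., sequence frames) can be sliced with ``df.index``.
    """
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    perm = np.random.default_rng(seed).permutation(len(dataset))
    n_train = int(round(ratio * len(dataset)))
    return dataset.iloc[perm[:n_train]], dataset.iloc[perm[n_train:]]


def write_csv(dataset: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write the dataset with '#'-prefixed JSON metadata lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# bedfall dataset\n")
        fh.write("# " + json.dumps(metadata or {}, sort_keys=True) + "\n")
        dataset.to_csv(fh, index=False)


def read_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read a dataset CSV, validating the schema; returns (df, metadata).

    Raises :class:`CsvSchemaError` naming the offending line for malformed
    files.
    """
    path = Path(path)
    metadata: dict = {}
    header_line = None
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines: list[tuple[int, str]] = []  # (1-based line number, text)
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("{"):
                metadata = json.loads(stripped)
            continue
        if not line.strip():
            continue
        if header_line is None:
            header_line = (lineno, line)
        else:
            data_lines.append((lineno, line))
    if header_line is None:
        raise CsvSchemaError(f"{path}: no header line found")
    columns = [c.strip() for c in header_line[1].rstrip("\n").split(",")]
    if columns != SCHEMA_COLUMNS:
        raise CsvSchemaError(
            f"{path}: line {header_line[0]}: header does not match the dataset "
            f"schema ({len(columns)} columns, expected {len(SCHEMA_COLUMNS)})"
        )
    rows = []
    for lineno, line in data_lines:
        fields = line.rstrip("\n").split(",")
        if len(fields) != len(SCHEMA_COLUMNS):
            raise CsvSchemaError(
                f"{path}: line {lineno}: expected {len(SCHEMA_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        rows.append(fields)
    df = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    try:
        df["c"] = df["c"].astype(int)
        df["episode_seed"] = df["episode_seed"].astype(np.int64)
        df["y"] = df["y"].astype(float)
        for col in FEATURE_COLUMNS:
            df[col] = df[col].astype(float)
        for col in VALIDITY_COLUMNS:
            df[col] = df[col].astype(int)
    except ValueError as exc:
        raise CsvSchemaError(f"{path}: non-numeric value in data rows: {exc}") from exc
    return df, metadata


def features(df: pd.DataFrame) -> np.ndarray:
    """The (n, 26) feature matrix u of a dataset frame."""
    return df[FEATURE_COLUMNS].to_numpy(float)


def labels_continuous(df: pd.DataFrame) -> np.ndarray:
    return df["y"].to_numpy(float)


def labels_binary(df: pd.DataFrame) -> np.ndarray:
    return df["c"].to_numpy(int)
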