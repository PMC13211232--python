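"""End-to-end experiment orchestration.

Ties the pipeline together at configurable scale: generate a class-balanced
training set and a pose-balanced test set with the physics engine, train
the regression families over the five-seed protocol, calibrate the decision
threshold on validation, and report overall and per-posture metrics.  Also
provides seeded, nested subsetting used by the training-set-size scaling
experiment.

Seed handling: one integer seed drives everything through spawned
``SeedSequence`` streams — training-set episodes, test-set episodes (a
disjoint stream, so no episode leaks across), and subset shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets as ds
from .episodes import EpisodeConfig, generate_batch
from .evaluate import calibrate_threshold, per_posture_report
from .labels import LabelConfig
from .models import DEFAULT_SEEDS, TrainConfig, fit_family
from .sampling import SamplerConfig
from .world import World, WorldConfig, build_world


def make_pipeline(
    world: World,
    sampler_config: SamplerConfig,
    episode_config: EpisodeConfig,
    label_config: LabelConfig,
):
    """Episode pipeline closure with the :mod:`bedfall.datasets` signature."""

    def pipeline(seeds, forced_modes=None):
        return generate_batch(
            world, sampler_config, episode_config, label_config, seeds, forced_modes
        )

    return pipeline


@dataclass
class GenerationResult:
    train: pd.DataFrame
    train_frames: np.ndarray
    test: pd.DataFrame
    test_frames: np.ndarray
    train_stats: ds.BuildStats
    test_stats: ds.BuildStats
    manifest: dict = field(default_factory=dict)


def generate_datasets(
    seed: int,
    n_train: int,
    n_test: int,
    strategy: str = "pose_stratified",
    world_config: WorldConfig | None = None,
    sampler_config: SamplerConfig | None = None,
    episode_config: EpisodeConfig | None = None,
    label_config: LabelConfig | None = None,
) -> GenerationResult:
    """Physics-generate a balanced train set and a pose-balanced test set.

    The training set uses the requested sampling strategy; the test set is
    always pose-balanced (modes pinned uniformly), drawn from a seed stream
    disjoint from training.
    """
    world = build_world(world_config)
    sampler = sampler_config or SamplerConfig(strategy=strategy)
    if sampler.strategy != strategy:
        sampler = SamplerConfig(
            strategy=strategy,
            sigma_deg=sampler.sigma_deg,
            edge_margin=sampler.edge_margin,
            joint_range_default=sampler.joint_range_default,
            seed=sampler.seed,
        )
    episode = episode_config or EpisodeConfig()
    label = label_config or LabelConfig(sim_timestep=world.sim_timestep)
    ss_train, ss_test = np.random.SeedSequence(seed).spawn(2)
    pipeline = make_pipeline(world, sampler, episode, label)
    spec = ds.DatasetSpec(n_total=n_train, sampling_strategy=sampler.strategy, seed=seed)
    train, train_frames, train_stats = ds.build_balanced_dataset(
        np.random.default_rng(ss_train), spec, pipeline
    )
    # the test set pins posture modes, so it always uses stratified sampling
    test_sampler = SamplerConfig(
        strategy="pose_stratified",
        sigma_deg=sampler.sigma_deg,
        edge_margin=sampler.edge_margin,
        joint_range_default=sampler.joint_range_default,
        seed=sampler.seed,
    )
    test_pipeline = make_pipeline(world, test_sampler, episode, label)
    if n_test > 0:
        test, test_frames, test_stats = ds.build_pose_balanced_test_set(
            np.random.default_rng(ss_test), n_test, test_pipeline
        )
    else:
        test = pd.DataFrame(columns=ds.SCHEMA_COLUMNS)
        test_frames = np.zeros((0, 5, 26))
        test_stats = ds.BuildStats()
    manifest = {
        "seed": seed,
        "n_train": n_train,
        "n_test": n_test,
        "strategy": sampler.strategy,
        "world": world.manifest(),
        "sampler": {
            "strategy": sampler.strategy,
            "sigma_deg": sampler.sigma_deg,
            "edge_margin_m": sampler.edge_margin,
            "joint_range_default_rad": sampler.joint_range_default,
            "euler_convention": "extrinsic-xyz",
        },
        "episode": {
            "drop_height_m": episode.drop_height,
            "pre_pose_duration_s": episode.pre_pose_duration,
            "contact_timeout_s": episode.contact_timeout,
            "rollout_window_s": episode.rollout_window,
        },
        "label": {"fps": label.fps, "gamma": label.gamma, "window_s": label.window},
        "train_rejections": train_stats.rejections,
        "test_rejections": test_stats.rejections,
    }
    return GenerationResult(
        train, train_frames, test, test_frames, train_stats, test_stats, manifest
    )


def balanced_subset(
    df: pd.DataFrame, frames: np.ndarray | None, n: int, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Class-balanced subset of n samples (prefixes of one seeded shuffle).

    Subsets for increasing n are nested: the n1-subset is contained in the
    n2-subset for n1 <= n2 under the same seed.
    """
    order = np.random.default_rng(seed).permutation(len(df))
    c = df["c"].to_numpy()[order]
    take = np.concatenate([order[c == 1][: n // 2], order[c == 0][: n - n // 2]])
    if len(take) < n:
        raise ValueError(f"pool too small for a balanced subset of {n}")
    return df.iloc[take].reset_index(drop=True), None if frames is None else frames[take]


def pose_subset(
    df: pd.DataFrame, frames: np.ndarray, n: int, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pose-balanced subset (n/4 per mode) of a pose-balanced set."""
    if n % 4:
        raise ValueError("pose-balanced subset size must be divisible by 4")
    order = np.random.default_rng(seed).permutation(len(df))
    modes = df["mode"].to_numpy()[order]
    parts = [order[modes == m][: n // 4] for m in np.unique(modes)]
    take = np.concatenate(parts)
    if len(take) < n:
        raise ValueError(f"pool too small for a pose-balanced subset of {n}")
    return df.iloc[take].reset_index(drop=True), frames[take]


def _family_inputs(family: str, df: pd.DataFrame, frames: np.ndarray | None):
    if family == "lstm":
        if frames is None:
            raise ValueError("lstm requires sequence frames")
        return frames
    return ds.features(df)


def train_and_evaluate(
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    families: tuple[str, ...] = ("mlp",),
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    split_ratio: float = 0.9,
    split_seed: int = 0,
    train_frames: np.ndarray | None = None,
    test_frames: np.ndarray | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """The fixed evaluation protocol for one train/test pair.

    Splits train 9:1 into train/validation (one split shared by all seeds),
    fits each family at each seed, calibrates the F1-maximizing threshold
    on validation scores, and evaluates on the test set overall and per
    posture mode at that global threshold.  Returns the long-format report
    (one row per family/seed/subgroup) and a dict of fitted models keyed by
    (family, seed).
    """
    tr, val = ds.split_train_val(train_df.reset_index(drop=True), split_ratio, split_seed)
    rows: list[dict] = []
    fitted: dict = {}
    y_test_c = ds.labels_binary(test_df)
    y_test = ds.labels_continuous(test_df)
    modes_test = test_df["mode"].to_numpy()
    for family in families:
        for seed in seeds:
            X_tr = _family_inputs(family, tr, None if train_frames is None else train_frames[tr.index])
            X_val = _family_inputs(family, val, None if train_frames is None else train_frames[val.index])
            model = fit_family(
                family,
                X_tr,
                ds.labels_continuous(tr),
                X_val,
                ds.labels_continuous(val),
                seed,
                train_config,
            )
            tau = calibrate_threshold(model.predict(X_val), ds.labels_binary(val))
            X_te = _family_inputs(family, test_df, test_frames)
            scores = model.predict(X_te)
            for report in per_posture_report(scores, y_test_c, y_test, modes_test, tau):
                row = report.to_dict()
                row.update({"family": family, "seed": seed, "n_train": len(train_df)})
                rows.append(row)
            fitted[(family, seed)] = model
    return pd.DataFrame(rows), fitted


def summarize(report: pd.DataFrame) -> pd.DataFrame:
    """Mean +- std over seeds for each (family, subgroup)."""
    metric_cols = ["auroc", "auprc", "accuracy", "precision", "recall", "f1", "mse"]
    agg = report.groupby(["family", "subgroup"])[metric_cols].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def scaling_experiment(
    pool_df: pd.DataFrame,
    test_df: pd.DataFrame,
    sizes: tuple[int, ...],
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
    subset_seed: int = 0,
    families: tuple[str, ...] = ("mlp",),
    train_config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Train at each size on nested balanced subsets of one pool.

    ``sizes`` must be ascending and within the pool.  Returns one overall
    report row per (size, family, seed).
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    if sizes[-1] > len(pool_df):
        raise ValueError("pool smaller than the largest requested size")
    rows = []
    for n in sizes:
        sub, _ = balanced_subset(pool_df, None, n, subset_seed)
        report, _ = train_and_evaluate(
            sub, test_df, families=families, seeds=seeds, train_config=train_config
        )
        overall = report[report.subgroup == "overall"]
        rows.append(overall)
    return pd.concat(rows, ignore_index=True)
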