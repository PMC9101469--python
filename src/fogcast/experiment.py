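"""Study orchestration: MAS/LAS/bilateral dataset views, leave-one-freezer-out
cross-validation, the 3 × 6 model grid, and report generation.

The grid crosses the three dataset views (most-affected side, least-affected
side, bilateral) with six feature-subset sizes (top 5, 10, 15, 20, 25, 30 by
Relief-F weight). One cross-validation fold is run per freezer; non-freezers
always stay in the training set. Relief-F is re-ranked per fold on training
windows only, so no held-out window ever influences feature selection or
model fitting. Each grid cell reports metrics averaged over held-out
freezers with equal participant weight, and the best model per view is the
one with the smallest rank sum across the five evaluation metrics.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    EvalConfig,
    EpisodeScorecard,
    METRIC_ORIENTATION,
    build_target_zones,
    detect_mtds,
    rank_sum_select,
    score_episodes,
    window_metrics,
)
from .features import BandSpec, FeatureCatalog, build_catalog, extract_feature_matrix
from .preprocessing import WindowSpec, build_signal_bundle, make_windows
from .relieff import FeatureRanking, ReliefFConfig, relieff_rank, top_n
from .rusboost import RUSBoostConfig, fit_rusboost, predict

__all__ = [
    "FEATURE_COUNTS",
    "SIDES",
    "WindowDataset",
    "SideDatasetView",
    "GridResult",
    "build_window_dataset",
    "build_side_datasets",
    "leave_one_freezer_out_cv",
    "run_grid",
    "scorecard_frame",
    "write_report",
]

FEATURE_COUNTS = (5, 10, 15, 20, 25, 30)
SIDES = ("MAS", "LAS", "bilateral")


@dataclass
class WindowDataset:
    """Per-window feature matrix with provenance for a whole cohort."""

    features: np.ndarray  # (n_windows, 333), bilateral catalog order
    meta: pd.DataFrame  # participant_id, trial_id, window_index, start_s, end_s, target
    catalog: FeatureCatalog
    trials: dict  # trial_id -> TrialRecording (annotations for episode scoring)

    @property
    def target(self) -> np.ndarray:
        return self.meta["target"].to_numpy(dtype=bool)


@dataclass
class SideDatasetView:
    """One modelling dataset: per-participant column selection of the
    bilateral matrix. MAS/LAS views have 166 side-neutral columns (the
    bilateral weight-shift feature needs both feet and is bilateral-only)."""

    side: str
    X: np.ndarray
    feature_names: list
    meta: pd.DataFrame


def build_window_dataset(
    recordings: list,
    wspec: WindowSpec = WindowSpec(),
    bands: BandSpec = BandSpec(),
) -> WindowDataset:
    """Preprocess, window and featurize every trial of a cohort."""
    catalog = build_catalog()
    blocks, rows = [], []
    trials = {}
    for rec in recordings:
        trials[rec.trial_id] = rec
        bundle = build_signal_bundle(rec)
        windows = make_windows(rec, wspec)
        if not windows:
            continue
        matrix, _ = extract_feature_matrix(bundle, windows, catalog, bands)
        blocks.append(matrix)
        for w in windows:
            rows.append(
                (rec.participant_id, rec.trial_id, w.index, w.start, w.end,
                 w.is_target)
            )
    features = np.vstack(blocks) if blocks else np.empty((0, len(catalog)))
    meta = pd.DataFrame(
        rows,
        columns=["participant_id", "trial_id", "window_index", "start_s",
                 "end_s", "target"],
    )
    return WindowDataset(features=features, meta=meta, catalog=catalog, trials=trials)


def build_side_datasets(dataset: WindowDataset, profiles: list) -> dict:
    """The three modelling views of the bilateral window matrix.

    Per participant the MAS view picks that participant's more-affected
    foot's 166 features (LAS the other foot); the bilateral view passes all
    333 columns through.
    """
    mas_by_participant = {p.participant_id: p.mas_side for p in profiles}
    participants = dataset.meta["participant_id"]
    missing = sorted(set(participants) - set(mas_by_participant))
    if missing:
        raise ValueError(f"profiles missing mas_side for participants: {missing}")
    left_idx = dataset.catalog.side_indices("left")
    right_idx = dataset.catalog.side_indices("right")
    unilateral_names = [
        dataset.catalog.names[i].split("_", 1)[1] for i in left_idx
    ]
    mas_is_left = participants.map(
        lambda p: mas_by_participant[p] == "left"
    ).to_numpy(dtype=bool)

    F = dataset.features
    X_mas = np.where(mas_is_left[:, None], F[:, left_idx], F[:, right_idx])
    X_las = np.where(mas_is_left[:, None], F[:, right_idx], F[:, left_idx])
    return {
        "MAS": SideDatasetView("MAS", X_mas, unilateral_names, dataset.meta),
        "LAS": SideDatasetView("LAS", X_las, unilateral_names, dataset.meta),
        "bilateral": SideDatasetView(
            "bilateral", F, list(dataset.catalog.names), dataset.meta
        ),
    }


def _model_seed(master_seed: int, side: str, held_out: str, n_features: int) -> int:
    entropy = np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32(side.encode()),
         zlib.crc32(held_out.encode()), int(n_features)]
    )
    return int(entropy.generate_state(1)[0] & 0x7FFFFFFF)


def _score_fold(
    view: SideDatasetView,
    dataset: WindowDataset,
    held_out: str,
    subset: np.ndarray,
    model_cfg: RUSBoostConfig,
    eval_cfg: EvalConfig,
) -> EpisodeScorecard:
    """Fit on everyone but ``held_out``, evaluate that participant's windows
    and episodes."""
    participants = view.meta["participant_id"].to_numpy()
    train = participants != held_out
    test = ~train
    if not (train.any() and test.any()):
        raise ValueError(f"degenerate fold for participant {held_out!r}")
    y = view.meta["target"].to_numpy(dtype=bool)
    if y[train].all() or not y[train].any():
        raise ValueError(
            f"fold training set for {held_out!r} lost a class; cannot fit"
        )
    ensemble = fit_rusboost(view.X[np.ix_(train, subset)], y[train], model_cfg)
    pred, _scores = predict(ensemble, view.X[np.ix_(test, subset)])
    sens, spec = window_metrics(pred, y[test])

    test_meta = view.meta.loc[test].copy()
    test_meta["pred"] = pred
    mtds, zones, segments = [], [], {}
    trial_ids = sorted(test_meta["trial_id"].unique())
    for tid in trial_ids:
        tw = test_meta[test_meta["trial_id"] == tid].sort_values("window_index")
        mtds.extend(detect_mtds(tw["end_s"].to_numpy(), tw["pred"].to_numpy(),
                                eval_cfg, trial_id=tid))
        rec = dataset.trials[tid]
        zones.extend(build_target_zones(rec.episodes, rec.segments, eval_cfg,
                                        trial_id=tid))
        segments[tid] = rec.segments
    card = score_episodes(mtds, zones, segments, n_trials=len(trial_ids),
                          config=eval_cfg, participant_id=held_out)
    card.sensitivity = sens
    card.specificity = spec
    return card


def leave_one_freezer_out_cv(
    view: SideDatasetView,
    dataset: WindowDataset,
    profiles: list,
    n_features: int,
    relieff_cfg: ReliefFConfig = ReliefFConfig(),
    model_cfg: RUSBoostConfig = RUSBoostConfig(),
    eval_cfg: EvalConfig = EvalConfig(),
    master_seed: int = 0,
) -> list:
    """One fold per freezer: Relief-F on training windows → top-N subset →
    RUSBoost → window and episode scoring of the held-out freezer."""
    freezers = [p.participant_id for p in profiles if p.is_freezer]
    if len(freezers) < 2:
        raise ValueError("leave-one-freezer-out CV needs at least 2 freezers")
    cards = []
    participants = view.meta["participant_id"].to_numpy()
    y = view.meta["target"].to_numpy(dtype=bool)
    for held in freezers:
        train = participants != held
        ranking = relieff_rank(view.X[train], y[train], relieff_cfg)
        subset = top_n(ranking, n_features)
        cfg = RUSBoostConfig(
            n_learners=model_cfg.n_learners, max_splits=model_cfg.max_splits,
            target_class_ratio=model_cfg.target_class_ratio,
            learning_rate=model_cfg.learning_rate,
            seed=_model_seed(master_seed, view.side, held, n_features),
        )
        cards.append(_score_fold(view, dataset, held, subset, cfg, eval_cfg))
    return cards


@dataclass
class GridResult:
    cells: dict  # (side, n_features) -> list of EpisodeScorecard
    mean_table: pd.DataFrame  # index (side, n_features), metric columns
    rank_sums: pd.DataFrame  # side × n_features
    best: dict  # side -> n_features

    def cell_frame(self, side: str, n_features: int) -> pd.DataFrame:
        return scorecard_frame(self.cells[(side, n_features)])


def _mean_metrics(cards: list) -> dict:
    frame = pd.DataFrame([c.as_dict() for c in cards])
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN folds
        for metric in METRIC_ORIENTATION:
            out[metric] = float(np.nanmean(frame[metric].to_numpy(dtype=float)))
    return out


def run_grid(
    recordings: list,
    profiles: list,
    wspec: WindowSpec = WindowSpec(),
    bands: BandSpec = BandSpec(),
    relieff_cfg: ReliefFConfig = ReliefFConfig(),
    model_cfg: RUSBoostConfig = RUSBoostConfig(),
    eval_cfg: EvalConfig = EvalConfig(),
    feature_counts: tuple = FEATURE_COUNTS,
    sides: tuple = SIDES,
    master_seed: int = 0,
) -> GridResult:
    """Run the full 3 × 6 experiment grid and select the best model per view.

    Relief-F is computed once per (view, fold) and shared across feature
    counts — the top-N subsets nest, so this is exactly equivalent to
    re-ranking per cell, and much cheaper.
    """
    dataset = build_window_dataset(recordings, wspec, bands)
    views = build_side_datasets(dataset, profiles)
    freezers = [p.participant_id for p in profiles if p.is_freezer]
    if len(freezers) < 2:
        raise ValueError("leave-one-freezer-out CV needs at least 2 freezers")

    cells: dict = {}
    participants = dataset.meta["participant_id"].to_numpy()
    y = dataset.meta["target"].to_numpy(dtype=bool)
    for side in sides:
        view = views[side]
        rankings: dict[str, FeatureRanking] = {}
        for held in freezers:
            train = participants != held
            rankings[held] = relieff_rank(view.X[train], y[train], relieff_cfg)
        for n in feature_counts:
            cards = []
            for held in freezers:
                subset = top_n(rankings[held], n)
                cfg = RUSBoostConfig(
                    n_learners=model_cfg.n_learners,
                    max_splits=model_cfg.max_splits,
                    target_class_ratio=model_cfg.target_class_ratio,
                    learning_rate=model_cfg.learning_rate,
                    seed=_model_seed(master_seed, side, held, n),
                )
                cards.append(_score_fold(view, dataset, held, subset, cfg, eval_cfg))
            cells[(side, n)] = cards

    mean_rows = {key: _mean_metrics(cards) for key, cards in cells.items()}
    mean_table = pd.DataFrame.from_dict(mean_rows, orient="index")
    mean_table.index = pd.MultiIndex.from_tuples(
        mean_table.index, names=["side", "n_features"]
    )
    rank_rows, best = {}, {}
    for side in sides:
        side_table = mean_table.loc[side]
        best_n, sums = rank_sum_select(side_table)
        rank_rows[side] = sums
        best[side] = int(best_n)
    rank_sums = pd.DataFrame(rank_rows).T
    rank_sums.index.name = "side"
    return GridResult(cells=cells, mean_table=mean_table, rank_sums=rank_sums,
                      best=best)


def scorecard_frame(cards: list) -> pd.DataFrame:
    """Participant rows with a mean ± SD footer, mirroring per-participant
    cross-validation report tables."""
    frame = pd.DataFrame([c.as_dict() for c in cards]).set_index("participant_id")
    numeric = frame[list(METRIC_ORIENTATION)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # single-value SDs
        footer = pd.DataFrame(
            {
                col: [np.nanmean(numeric[col].astype(float)),
                      np.nanstd(numeric[col].astype(float), ddof=1)]
                for col in numeric.columns
            },
            index=["mean", "sd"],
        )
    return pd.concat([frame, footer])


def write_report(grid: GridResult, out_dir) -> list:
    """Write the grid summary, rank sums, and per-cell scorecards as CSV
    (fixed float formatting, so identical results are byte-identical)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, float_format="%.6f")
        written.append(path)

    save(grid.mean_table, "grid_summary.csv")
    save(grid.rank_sums, "rank_sums.csv")
    best = pd.DataFrame(
        {"side": list(grid.best), "n_features": list(grid.best.values())}
    ).set_index("side")
    save(best, "best_models.csv")
    for (side, n), cards in grid.cells.items():
        save(scorecard_frame(cards), f"scorecard_{side}_{n:02d}.csv")
    return written
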