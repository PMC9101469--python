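"""Experiment orchestration: side-view construction, leave-one-freezer-out
folds, leakage auditing, and the 18-cell grid."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import fogcast.experiment as exp
from fogcast.evaluation import EvalConfig
from fogcast.experiment import (
    FEATURE_COUNTS,
    SIDES,
    WindowDataset,
    build_side_datasets,
    build_window_dataset,
    leave_one_freezer_out_cv,
    run_grid,
)
from fogcast.features import build_catalog
from fogcast.relieff import ReliefFConfig
from fogcast.rusboost import RUSBoostConfig
from fogcast.synthetic import (
    EpisodeAnnotation,
    GaitSimConfig,
    ParticipantProfile,
    default_cohort_profiles,
    simulate_cohort,
)


def _crafted_dataset(rng, informative_side="LAS", n_windows=120):
    """A hand-built cohort whose class signal lives only in one side's foot
    features; trials are annotation stubs sufficient for episode scoring."""
    catalog = build_catalog()
    profiles, rows, blocks, trials = [], [], [], {}
    target = (np.arange(n_windows) >= 50) & (np.arange(n_windows) < 70)
    for i in range(4):
        pid = f"F{i}"
        mas = "left" if i % 2 == 0 else "right"
        las = "right" if mas == "left" else "left"
        profiles.append(ParticipantProfile(pid, mas, True, 1))
        tid = f"{pid}_T0"
        X = rng.normal(size=(n_windows, 333))
        foot = mas if informative_side == "MAS" else las
        X[:, catalog.side_indices(foot)[:5]] += 3.0 * target[:, None]
        blocks.append(X)
        ends = 1.0 + 0.2 * np.arange(n_windows)
        for k in range(n_windows):
            rows.append((pid, tid, k, float(ends[k] - 1.0), float(ends[k]),
                         bool(target[k])))
        trials[tid] = SimpleNamespace(
            episodes=[EpisodeAnnotation(13.0, 15.0)], segments=[]
        )
    meta = pd.DataFrame(
        rows, columns=["participant_id", "trial_id", "window_index",
                       "start_s", "end_s", "target"],
    )
    dataset = WindowDataset(
        features=np.vstack(blocks), meta=meta, catalog=catalog, trials=trials
    )
    return dataset, profiles


@pytest.fixture(scope="module")
def small_cohort():
    cfg = GaitSimConfig(trial_duration=20.0, seed=17)
    profiles = [
        ParticipantProfile("F1", "left", True, 1),
        ParticipantProfile("F2", "right", True, 1),
        ParticipantProfile("N1", "left", False, 1),
    ]
    recordings = simulate_cohort(cfg, profiles)
    return build_window_dataset(recordings), profiles


class TestBuildSideDatasets:
    def test_mas_view_selects_declared_foot(self, rng):
        dataset, profiles = _crafted_dataset(rng)
        catalog = dataset.catalog
        dataset.features[:, catalog.side_indices("left")] = 0.0
        dataset.features[:, catalog.side_indices("right")] = 1.0
        views = build_side_datasets(dataset, profiles)
        for pid, mas in (("F0", "left"), ("F1", "right")):
            rows = views["MAS"].meta["participant_id"] == pid
            expected = 0.0 if mas == "left" else 1.0
            assert (views["MAS"].X[rows.to_numpy()] == expected).all()
            assert (views["LAS"].X[rows.to_numpy()] == 1.0 - expected).all()

    def test_view_shapes(self, small_cohort):
        dataset, profiles = small_cohort
        views = build_side_datasets(dataset, profiles)
        n = dataset.features.shape[0]
        assert views["MAS"].X.shape == (n, 166)
        assert views["LAS"].X.shape == (n, 166)
        assert views["bilateral"].X.shape == (n, 333)

    def test_mas_las_partition_the_unilateral_features(self, small_cohort):
        dataset, profiles = small_cohort
        views = build_side_datasets(dataset, profiles)
        left = dataset.features[:, dataset.catalog.side_indices("left")]
        right = dataset.features[:, dataset.catalog.side_indices("right")]
        recombined = np.concatenate([views["MAS"].X, views["LAS"].X], axis=1)
        original = np.concatenate([left, right], axis=1)
        assert recombined.shape[1] == 332
        np.testing.assert_array_equal(
            np.sort(recombined, axis=1), np.sort(original, axis=1)
        )

    def test_flipping_mas_side_swaps_views(self, small_cohort):
        dataset, profiles = small_cohort
        views = build_side_datasets(dataset, profiles)
        flipped_profiles = [
            ParticipantProfile(
                p.participant_id,
                "right" if p.participant_id == "F1" else p.mas_side,
                p.is_freezer, p.n_trials,
            )
            for p in profiles
        ]
        flipped = build_side_datasets(dataset, flipped_profiles)
        rows = (dataset.meta["participant_id"] == "F1").to_numpy()
        np.testing.assert_array_equal(flipped["MAS"].X[rows], views["LAS"].X[rows])
        np.testing.assert_array_equal(flipped["LAS"].X[rows], views["MAS"].X[rows])

    def test_missing_profile_rejected(self, small_cohort):
        dataset, profiles = small_cohort
        with pytest.raises(ValueError, match="mas_side"):
            build_side_datasets(dataset, profiles[:1])


FAST_RELIEFF = ReliefFConfig(k_neighbors=5, n_sampling=120, seed=0)
FAST_MODEL = RUSBoostConfig(n_learners=8, seed=0)


class TestLeaveOneFreezerOut:
    def test_one_fold_per_freezer(self, small_cohort):
        dataset, profiles = small_cohort
        views = build_side_datasets(dataset, profiles)
        cards = leave_one_freezer_out_cv(
            views["bilateral"], dataset, profiles, n_features=5,
            relieff_cfg=FAST_RELIEFF, model_cfg=FAST_MODEL,
        )
        assert [c.participant_id for c in cards] == ["F1", "F2"]

    def test_no_heldout_window_reaches_ranking_or_fitting(
        self, small_cohort, monkeypatch
    ):
        dataset, profiles = small_cohort
        views = build_side_datasets(dataset, profiles)
        seen_rank, seen_fit = [], []
        orig_rank, orig_fit = exp.relieff_rank, exp.fit_rusboost

        def spy_rank(X, y, cfg):
            seen_rank.append(np.asarray(X).copy())
            return orig_rank(X, y, cfg)

        def spy_fit(X, y, cfg):
            seen_fit.append(np.asarray(X).copy())
            return orig_fit(X, y, cfg)

        monkeypatch.setattr(exp, "relieff_rank", spy_rank)
        monkeypatch.setattr(exp, "fit_rusboost", spy_fit)
        leave_one_freezer_out_cv(
            views["bilateral"], dataset, profiles, n_features=5,
            relieff_cfg=FAST_RELIEFF, model_cfg=FAST_MODEL,
        )
        freezers = ["F1", "F2"]
        for fold, held in enumerate(freezers):
            held_rows = {
                row.tobytes()
                for row in views["bilateral"].X[
                    (dataset.meta["participant_id"] == held).to_numpy()
                ]
            }
            train_hashes = {row.tobytes() for row in seen_rank[fold]}
            assert not held_rows & train_hashes
        # non-freezer windows participate in every fold's training set
        n1_rows = {
            row.tobytes()
            for row in views["bilateral"].X[
                (dataset.meta["participant_id"] == "N1").to_numpy()
            ]
        }
        for X_train in seen_rank:
            assert n1_rows <= {row.tobytes() for row in X_train}

    def test_too_few_freezers_rejected(self, small_cohort):
        dataset, profiles = small_cohort
        views = build_side_datasets(dataset, profiles)
        with pytest.raises(ValueError, match="freezers"):
            leave_one_freezer_out_cv(
                views["bilateral"], dataset, [profiles[0], profiles[2]], 5
            )


@pytest.fixture(scope="module")
def tiny_grid():
    cfg = GaitSimConfig(trial_duration=20.0, seed=23)
    profiles = default_cohort_profiles(2, 1, 1)
    recordings = simulate_cohort(cfg, profiles)
    return run_grid(
        recordings, profiles, relieff_cfg=FAST_RELIEFF, model_cfg=FAST_MODEL,
        master_seed=23,
    )


class TestRunGrid:
    def test_grid_has_18_cells(self, tiny_grid):
        assert len(tiny_grid.cells) == 18
        assert set(tiny_grid.cells) == {
            (side, n) for side in SIDES for n in FEATURE_COUNTS
        }

    def test_one_best_model_per_side(self, tiny_grid):
        assert set(tiny_grid.best) == set(SIDES)
        for n in tiny_grid.best.values():
            assert n in FEATURE_COUNTS

    def test_deterministic_under_master_seed(self, tiny_grid):
        cfg = GaitSimConfig(trial_duration=20.0, seed=23)
        profiles = default_cohort_profiles(2, 1, 1)
        recordings = simulate_cohort(cfg, profiles)
        again = run_grid(
            recordings, profiles, relieff_cfg=FAST_RELIEFF, model_cfg=FAST_MODEL,
            master_seed=23,
        )
        pd.testing.assert_frame_equal(tiny_grid.mean_table, again.mean_table)


def test_implanted_side_signal_orients_the_views():
    """When the class signal lives only in LAS-foot features, the LAS view
    outperforms the MAS view on window sensitivity (5-seed majority)."""
    las_wins = 0
    for seed in range(5):
        rng = np.random.default_rng(1000 + seed)
        dataset, profiles = _crafted_dataset(rng, informative_side="LAS")
        views = build_side_datasets(dataset, profiles)
        sens = {}
        for side in ("MAS", "LAS"):
            cards = leave_one_freezer_out_cv(
                views[side], dataset, profiles, n_features=5,
                relieff_cfg=ReliefFConfig(k_neighbors=5, n_sampling=150, seed=seed),
                model_cfg=RUSBoostConfig(n_learners=10, seed=seed),
                eval_cfg=EvalConfig(),
                master_seed=seed,
            )
            sens[side] = np.nanmean([c.sensitivity for c in cards])
        las_wins += sens["LAS"] > sens["MAS"]
    assert las_wins >= 3
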