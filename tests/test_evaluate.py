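"""Cross-validation regimes, ensembling, rank statistics and reporting."""

import json

import numpy as np
import pandas as pd
import pytest

from emgdecode.datatypes import EpochSet
from emgdecode.evaluate import (
    CvConfig,
    GestureSegments,
    _iter_folds,
    crossval,
    ensemble_report,
    nemenyi_critical_distance,
    rank_report,
    render_report,
    voting_ensemble,
    window_sweep,
)
from emgdecode.pipelines import make_pipeline


def separable_epochs(rng, n_subjects=3, n_sessions=2, n_per=6, e=4, s=256):
    """Epochs whose class is encoded in the variance of one channel."""
    data, labels, subj, sess = [], [], [], []
    scales = {"thumb": 1.0, "index": 8.0, "middle": 64.0, "pinky": 512.0}
    for si in range(n_subjects):
        for se in range(n_sessions):
            for lbl, sc in scales.items():
                for _ in range(n_per):
                    x = rng.standard_normal((e, s))
                    x[0] *= sc
                    data.append(x)
                    labels.append(lbl)
                    subj.append(f"S{si}")
                    sess.append(f"sess{se}")
    return EpochSet(
        data=np.array(data),
        labels=np.array(labels, dtype=object),
        subject=np.array(subj, dtype=object),
        session=np.array(sess, dtype=object),
        hand=np.full(len(labels), "right", dtype=object),
        component="phasic",
        fs=128.0,
        window_s=0.5,
    )


class TestCrossval:
    @pytest.mark.parametrize("mode", ["intra_subject", "inter_session", "inter_subject"])
    def test_separable_data_is_perfect_in_all_modes(self, rng, mode):
        epochs = separable_epochs(rng)
        rep = crossval(epochs, make_pipeline("cov"), CvConfig(mode=mode, seed=0))
        assert rep.mean_accuracy == 1.0
        assert rep.auc_macro == pytest.approx(1.0, abs=1e-9)
        # confusion rows sum to per-class test counts
        counts = [np.sum(epochs.labels == c) for c in rep.classes]
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), counts)

    def test_shuffled_labels_at_chance(self, rng):
        epochs = separable_epochs(rng, n_subjects=2, n_per=10)
        accs = []
        for seed in range(3):
            shuffled = epochs.subset(np.arange(len(epochs)))
            gen = np.random.default_rng(seed)
            # permute within subject so the 4 classes stay balanced per split
            for subj in np.unique(shuffled.subject):
                sel = np.flatnonzero(shuffled.subject == subj)
                shuffled.labels[sel] = gen.permutation(shuffled.labels[sel])
            rep = crossval(shuffled, make_pipeline("cov"), CvConfig(seed=0))
            accs.append(rep.mean_accuracy)
        assert np.mean(accs) == pytest.approx(0.25, abs=0.05)

    def test_no_subject_leakage_in_loso_folds(self, rng):
        epochs = separable_epochs(rng)
        for tr, te, _ in _iter_folds(epochs, CvConfig(mode="inter_subject")):
            assert not set(epochs.subject[tr]) & set(epochs.subject[te])

    def test_no_session_leakage_in_logo_folds(self, rng):
        epochs = separable_epochs(rng)
        for tr, te, _ in _iter_folds(epochs, CvConfig(mode="inter_session")):
            assert not set(epochs.session[tr]) & set(epochs.session[te])

    def test_each_epoch_tested_once(self, rng):
        epochs = separable_epochs(rng, n_subjects=2)
        rep = crossval(epochs, make_pipeline("cov"), CvConfig(seed=1))
        assert not np.isnan(rep.probabilities).any()


class TestVotingEnsemble:
    def test_identical_members_change_nothing(self):
        p = np.array([[0.7, 0.3], [0.2, 0.8]])
        mean, pred = voting_ensemble([p, p, p])
        np.testing.assert_allclose(mean, p, atol=1e-15)
        np.testing.assert_array_equal(pred, [0, 1])

    def test_two_member_arithmetic(self):
        mean, pred = voting_ensemble([[[0.6, 0.4]], [[0.2, 0.8]]])
        np.testing.assert_allclose(mean, [[0.4, 0.6]])
        assert pred[0] == 1

    def test_rows_still_sum_to_one(self, rng):
        members = [rng.dirichlet(np.ones(4), size=10) for _ in range(3)]
        mean, _ = voting_ensemble(members)
        np.testing.assert_allclose(mean.sum(axis=1), 1.0, atol=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            voting_ensemble([np.ones((2, 2)), np.ones((3, 2))])

    def test_ensemble_not_worse_than_weakest_member(self, rng):
        epochs = separable_epochs(rng, n_subjects=2)
        reports = [
            crossval(epochs, make_pipeline(name), CvConfig(seed=0), name)
            for name in ("cov", "xdawncov")
        ]
        ens = ensemble_report(reports)
        assert ens.mean_accuracy >= min(r.mean_accuracy for r in reports) - 1e-9


class TestRankReport:
    def test_identical_columns_full_ties(self):
        table = np.tile([[0.8], [0.9], [0.7]], (1, 4))
        rep = rank_report(table)
        np.testing.assert_allclose(rep.average_ranks, 2.5)

    def test_dominant_pipeline_ranks_first(self, rng):
        table = rng.uniform(0.5, 0.8, (6, 3))
        table[:, 1] = 0.99
        rep = rank_report(table)
        assert rep.average_ranks[1] == 1.0

    def test_critical_distance_closed_form(self):
        # q_0.05(4) = 2.569 (studentized range / sqrt 2), N = 14 datasets
        cd = nemenyi_critical_distance(4, 14)
        assert cd == pytest.approx(2.569 * np.sqrt(4 * 5 / (6 * 14)), abs=2e-3)

    def test_rank_rows_sum_to_k_choose_formula(self, rng):
        from scipy.stats import rankdata

        table = rng.uniform(size=(5, 4))
        ranks = rankdata(-table, axis=1, method="average")
        np.testing.assert_allclose(ranks.sum(axis=1), 4 * 5 / 2)

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            rank_report(np.ones((1, 3)))


def _toy_segments(rng, n_subj=2, n_per=8, e=4, t=1024):
    """Segments whose hold command separates classes but whose move does not."""
    labels, subj = [], []
    raw_sig, raw_env, move, hold = [], [], [], []
    amp = {"thumb": 1.0, "index": 2.0, "middle": 3.0, "pinky": 4.0}
    for s in range(n_subj):
        for lbl, a in amp.items():
            for _ in range(n_per):
                h = np.zeros((e, t))
                h[:, t // 4 :] = a
                m = np.zeros((e, t))
                m[:, : t // 4] = 1.0 + 0.05 * rng.standard_normal((e, t // 4))
                env = m + h
                raw_sig.append(env * rng.standard_normal((e, t)))
                raw_env.append(env)
                move.append(m)
                hold.append(h + 0.05 * rng.standard_normal((e, t)))
                labels.append(lbl)
                subj.append(f"S{s}")
    return GestureSegments(
        raw_signal=np.array(raw_sig),
        raw_env=np.array(raw_env),
        move=np.array(move),
        hold=np.array(hold),
        labels=np.array(labels, dtype=object),
        subject=np.array(subj, dtype=object),
        fs=256.0,
    )


class TestWindowSweep:
    def test_table_shape_full_sweep(self, rng):
        segs = _toy_segments(rng)
        df = window_sweep(
            segs,
            components=("raw", "move", "hold"),
            classifiers=("envelope_lr",),
            span_s=4.0,
            seed=0,
        )
        # (8 half-second windows + full span) x 3 components x 1 classifier
        assert len(df) == 9 * 3

    def test_hold_beats_move_in_late_window(self, rng):
        segs = _toy_segments(rng)
        df = window_sweep(
            segs,
            components=("move", "hold"),
            classifiers=("envelope_lr",),
            windows=[(2.0, 2.5)],
            seed=0,
        )
        acc = df.set_index("component")["accuracy"]
        assert acc["hold"] >= acc["move"]

    def test_single_class_raises(self, rng):
        segs = _toy_segments(rng)
        segs.labels[:] = "thumb"
        with pytest.raises(ValueError):
            window_sweep(segs)


class TestRenderReport:
    def test_outputs_roundtrip_and_deterministic(self, rng, tmp_path):
        epochs = separable_epochs(rng, n_subjects=2)
        rep = crossval(epochs, make_pipeline("cov"), CvConfig(seed=0), "cov")
        s1 = render_report([rep], tmp_path / "a")
        s2 = render_report([rep], tmp_path / "b")
        assert s1 == s2
        loaded = json.loads((tmp_path / "a" / "summary.json").read_text())
        assert loaded == s1
        c1 = (tmp_path / "a" / "confusion_cov_intra_subject.csv").read_bytes()
        c2 = (tmp_path / "b" / "confusion_cov_intra_subject.csv").read_bytes()
        assert c1 == c2
        conf = pd.read_csv(tmp_path / "a" / "confusion_cov_intra_subject.csv", index_col=0)
        counts = [np.sum(epochs.labels == c) for c in rep.classes]
        np.testing.assert_array_equal(conf.values.sum(axis=1), counts)

    def test_empty_reports_raise(self, tmp_path):
        with pytest.raises(ValueError):
            render_report([], tmp_path)
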