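"""Cross-validation regimes, ensembling, rank statistics and the window sweep.

Three validation configurations probe different generalization axes:

* intra-subject — stratified 5-fold within each subject, mean over folds,
  then unweighted mean over subjects;
* inter-session — leave-one-session-out over all subjects pooled;
* inter-subject — leave-one-subject-out.

Every fitted component (feature scaler, xDAWN filters, tangent-space
reference, classifier, CNN) is cloned and refit on the training split of
each fold, so nothing leaks from test data.

Pipeline comparison uses per-row midranks (rank 1 = best accuracy)
averaged per pipeline, with the Nemenyi critical distance
CD = q_0.05(k) * sqrt(k (k + 1) / (6 N)); a Friedman omnibus statistic is
computed alongside for information.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold

from .datatypes import EpochSet

CV_MODES = ("intra_subject", "inter_session", "inter_subject")


@dataclass
class CvConfig:
    mode: str = "intra_subject"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in CV_MODES:
            raise ValueError(f"mode must be one of {CV_MODES}")


@dataclass
class EvalReport:
    """Accuracies, confusion, ROC/AUC and pooled per-epoch probabilities."""

    mode: str
    pipeline: str
    classes: np.ndarray
    fold_accuracies: list
    mean_accuracy: float
    confusion: np.ndarray
    auc_macro: float
    roc_curves: dict
    probabilities: np.ndarray  # (N, K); rows for epochs never tested are NaN
    y_true: np.ndarray
    per_subject_accuracy: dict = field(default_factory=dict)


def _iter_folds(epochs: EpochSet, config: CvConfig):
    """Yield (train_idx, test_idx, fold_tag) per the configured regime."""
    y = epochs.labels
    if config.mode == "intra_subject":
        for subj in np.unique(epochs.subject):
            sel = np.flatnonzero(epochs.subject == subj)
            skf = StratifiedKFold(config.n_folds, shuffle=True, random_state=config.seed)
            for f, (tr, te) in enumerate(skf.split(sel, y[sel])):
                yield sel[tr], sel[te], {"subject": subj, "fold": f}
    else:
        groups = epochs.session if config.mode == "inter_session" else epochs.subject
        logo = LeaveOneGroupOut()
        for tr, te in logo.split(np.zeros(len(epochs)), y, groups):
            yield tr, te, {"group": groups[te][0]}


def crossval(epochs: EpochSet, pipeline, config: CvConfig, pipeline_name: str = "") -> EvalReport:
    """Run one pipeline through one cross-validation regime.

    Folds whose training split misses a class are skipped with a warning.
    Probabilities are pooled over test splits (each epoch is tested exactly
    once) and feed the confusion matrix and one-vs-rest macro ROC/AUC.
    """
    classes = np.unique(epochs.labels)
    n, k = len(epochs), classes.size
    proba = np.full((n, k), np.nan)
    fold_accs = []
    for tr, te, tag in _iter_folds(epochs, config):
        if np.unique(epochs.labels[tr]).size < k:
            warnings.warn(f"fold {tag} skipped: missing class in training split")
            continue
        model = clone(pipeline)
        model.fit(epochs.data[tr], epochs.labels[tr])
        p = model.predict_proba(epochs.data[te])
        # align columns to the global class order
        order = np.searchsorted(classes, model.classes_)
        proba[np.ix_(te, order)] = p
        pred = model.classes_[np.argmax(p, axis=1)]
        fold_accs.append({**tag, "accuracy": float(np.mean(pred == epochs.labels[te]))})
    if not fold_accs:
        raise ValueError("no usable folds")
    per_subject = {}
    if config.mode == "intra_subject":
        for subj in np.unique(epochs.subject):
            accs = [f["accuracy"] for f in fold_accs if f.get("subject") == subj]
            if accs:
                per_subject[str(subj)] = float(np.mean(accs))
        mean_acc = float(np.mean(list(per_subject.values())))
    else:
        mean_acc = float(np.mean([f["accuracy"] for f in fold_accs]))
    tested = ~np.isnan(proba[:, 0])
    y, p = epochs.labels[tested], proba[tested]
    pred = classes[np.argmax(p, axis=1)]
    conf = confusion_matrix(y, pred, labels=classes)
    auc, curves = _roc(y, p, classes)
    return EvalReport(
        mode=config.mode,
        pipeline=pipeline_name or type(pipeline).__name__,
        classes=classes,
        fold_accuracies=fold_accs,
        mean_accuracy=mean_acc,
        confusion=conf,
        auc_macro=auc,
        roc_curves=curves,
        probabilities=proba,
        y_true=epochs.labels.copy(),
        per_subject_accuracy=per_subject,
    )


def _roc(y, proba, classes):
    curves = {}
    aucs = []
    for j, cls in enumerate(classes):
        bin_true = (y == cls).astype(int)
        if bin_true.min() == bin_true.max():
            continue
        fpr, tpr, _ = roc_curve(bin_true, proba[:, j])
        curves[str(cls)] = (fpr, tpr)
        aucs.append(roc_auc_score(bin_true, proba[:, j]))
    return (float(np.mean(aucs)) if aucs else float("nan")), curves


def voting_ensemble(probability_sets) -> tuple[np.ndarray, np.ndarray]:
    """Average member probabilities; argmax prediction (lowest index wins ties).

    Returns (mean_probabilities, predicted_class_indices).
    """
    stack = [np.asarray(p, dtype=float) for p in probability_sets]
    shape = stack[0].shape
    for p in stack[1:]:
        if p.shape != shape:
            raise ValueError("probability sets must share a common shape")
    mean = np.mean(stack, axis=0)
    return mean, np.argmax(mean, axis=1)


def ensemble_report(reports: list[EvalReport]) -> EvalReport:
    """Voting ensemble of reports evaluated on the same epochs and regime."""
    first = reports[0]
    mean, pred_idx = voting_ensemble([r.probabilities for r in reports])
    tested = ~np.isnan(mean[:, 0])
    y = first.y_true[tested]
    pred = first.classes[pred_idx[tested]]
    conf = confusion_matrix(y, pred, labels=first.classes)
    auc, curves = _roc(y, mean[tested], first.classes)
    return EvalReport(
        mode=first.mode,
        pipeline="ensemble",
        classes=first.classes,
        fold_accuracies=[],
        mean_accuracy=float(np.mean(pred == y)),
        confusion=conf,
        auc_macro=auc,
        roc_curves=curves,
        probabilities=mean,
        y_true=first.y_true,
    )


@dataclass
class RankReport:
    pipelines: list
    average_ranks: np.ndarray
    critical_distance: float
    significant: np.ndarray  # pairwise |rank diff| >= CD
    friedman_pvalue: float


def nemenyi_critical_distance(k: int, n: int, alpha: float = 0.05) -> float:
    """CD = q_alpha(k) sqrt(k(k+1)/(6N)), q from the studentized range."""
    q = stats.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * n)))


def rank_report(accuracy_table, pipelines=None, alpha: float = 0.05) -> RankReport:
    """Average midranks per pipeline with the Nemenyi critical distance.

    ``accuracy_table`` is (datasets x pipelines); rank 1 is the best
    accuracy in a row, ties get midranks.
    """
    table = np.asarray(accuracy_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 rows (datasets) and 2 columns (pipelines)")
    n, k = table.shape
    ranks = stats.rankdata(-table, axis=1, method="average")
    avg = ranks.mean(axis=0)
    cd = nemenyi_critical_distance(k, n, alpha)
    diff = np.abs(avg[:, None] - avg[None, :])
    _, p_friedman = stats.friedmanchisquare(*table.T)
    return RankReport(
        pipelines=list(pipelines) if pipelines is not None else list(range(k)),
        average_ranks=avg,
        critical_distance=cd,
        significant=diff >= cd,
        friedman_pvalue=float(p_friedman),
    )


# ---------------------------------------------------------------------------
# Window sweep over the move/hold decomposition
# ---------------------------------------------------------------------------

@dataclass
class GestureSegments:
    """Per-gesture 0-4 s segments aligned at movement onset.

    ``raw_signal`` holds the band-passed multichannel EMG, ``raw_env``,
    ``move`` and ``hold`` the baseline-removed envelope and its two
    commands; all arrays are (G, E, T).
    """

    raw_signal: np.ndarray
    raw_env: np.ndarray
    move: np.ndarray
    hold: np.ndarray
    labels: np.ndarray
    subject: np.ndarray
    fs: float

    def component(self, name: str, kind: str) -> np.ndarray:
        """kind='signal' for covariance pipelines, 'env' for amplitude models."""
        if name == "raw":
            return self.raw_signal if kind == "signal" else self.raw_env
        if name == "move":
            return self.move
        if name == "hold":
            return self.hold
        raise ValueError(f"unknown component {name!r}")


def extract_gesture_segments(recordings_truths, config, span_s: float = 4.0) -> GestureSegments:
    """Build onset-aligned segments with envelopes and move/hold commands.

    ``recordings_truths`` yields (preprocessed recording, ground truth or
    None) pairs; baseline is the per-channel median envelope over the
    inter-gesture rest spans.
    """
    from .decompose import decompose_move_hold, envelope, remove_baseline
    from .synthio import rest_intervals

    raw_sig, raw_env_l, move_l, hold_l, labels, subjects = [], [], [], [], [], []
    for rec, _truth in recordings_truths:
        env = envelope(rec.signal, rec.fs)
        env = remove_baseline(env, rest_intervals(rec, config))
        n_span = int(round(span_s * rec.fs))
        for ev in rec.events:
            i0 = int(round(ev.onset_s * rec.fs))
            if i0 + n_span > rec.n_samples:
                continue
            seg_env = env.values[:, i0 : i0 + n_span]
            from .decompose import Envelope

            dec = decompose_move_hold(Envelope(seg_env, rec.fs), t0_index=0)
            raw_sig.append(rec.signal[:, i0 : i0 + n_span])
            raw_env_l.append(seg_env)
            move_l.append(dec.move)
            hold_l.append(dec.hold)
            labels.append(ev.label)
            subjects.append(rec.subject_id)
    # float32 keeps long multi-subject segment stacks memory-friendly
    return GestureSegments(
        raw_signal=np.stack(raw_sig).astype(np.float32),
        raw_env=np.stack(raw_env_l).astype(np.float32),
        move=np.stack(move_l).astype(np.float32),
        hold=np.stack(hold_l).astype(np.float32),
        labels=np.array(labels, dtype=object),
        subject=np.array(subjects, dtype=object),
        fs=config.fs,
    )


def _envelope_lr_pipeline(decimate: int = 64):
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    from .riemann import LinearGestureClassifier

    class _Downsample:
        def __init__(self, q):
            self.q = q

        def get_params(self, deep=True):
            return {"q": self.q}

        def set_params(self, **kw):
            self.q = kw.get("q", self.q)
            return self

        def fit(self, X, y=None):
            return self

        def transform(self, X):
            X = np.asarray(X, dtype=float)
            n, e, t = X.shape
            t2 = t // self.q
            return X[:, :, : t2 * self.q].reshape(n, e, t2, self.q).mean(axis=3).reshape(n, -1)

    return Pipeline(
        [
            ("down", _Downsample(decimate)),
            ("scale", StandardScaler()),
            ("clf", LinearGestureClassifier()),
        ]
    )


def _sweep_classifier(name: str):
    from .pipelines import make_pipeline

    if name == "envelope_lr":
        return _envelope_lr_pipeline()
    if name == "xdawn_cov":
        return make_pipeline("xdawncov")
    raise ValueError(f"unknown classifier {name!r}")


def window_sweep(
    segments: GestureSegments,
    components=("raw", "move", "hold"),
    classifiers=("envelope_lr", "xdawn_cov"),
    window_s: float = 0.5,
    span_s: float = 4.0,
    include_full: bool = True,
    n_folds: int = 5,
    seed: int = 0,
    windows=None,
) -> pd.DataFrame:
    """Intra-subject accuracy per 0.5 s window, component and classifier.

    For each window (and optionally the full 0-4 s span), each signal
    version, and each classifier, runs per-subject stratified K-fold CV
    and reports the mean accuracy (plus per-subject means). ``windows``
    may restrict the sweep to selected (start_s, stop_s) pairs.
    """
    if np.unique(segments.labels).size < 2:
        raise ValueError("need at least 2 gesture classes")
    fs = segments.fs
    if windows is None:
        starts = np.arange(0.0, span_s, window_s)
        windows = [(s, s + window_s) for s in starts]
        if include_full:
            windows.append((0.0, span_s))
    rows = []
    for start, stop in windows:
        i0, i1 = int(round(start * fs)), int(round(stop * fs))
        i1 -= (i1 - i0) % 16  # keep lengths pooling-friendly
        for comp in components:
            for clf_name in classifiers:
                kind = "signal" if clf_name == "xdawn_cov" else "env"
                data = segments.component(comp, kind)[:, :, i0:i1]
                epochs = EpochSet(
                    data=data,
                    labels=segments.labels,
                    subject=segments.subject,
                    session=np.full(len(segments.labels), "all", dtype=object),
                    hand=np.full(len(segments.labels), "right", dtype=object),
                    component="phasic",
                    fs=fs,
                    window_s=stop - start,
                )
                rep = crossval(
                    epochs,
                    _sweep_classifier(clf_name),
                    CvConfig(mode="intra_subject", n_folds=n_folds, seed=seed),
                    pipeline_name=clf_name,
                )
                rows.append(
                    {
                        "window_start_s": start,
                        "window_stop_s": stop,
                        "component": comp,
                        "classifier": clf_name,
                        "accuracy": rep.mean_accuracy,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(reports: list[EvalReport], out_dir) -> dict:
    """Write confusion CSVs, ROC plots, a rank diagram and a JSON summary.

    Deterministic: identical inputs give byte-identical CSV/JSON output.
    Returns the summary dict.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if not reports:
        raise ValueError("no reports to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for rep in reports:
        tag = f"{rep.pipeline}_{rep.mode}"
        conf_df = pd.DataFrame(rep.confusion, index=rep.classes, columns=rep.classes)
        conf_df.to_csv(out / f"confusion_{tag}.csv")
        fig, ax = plt.subplots(figsize=(4, 3.5))
        ax.imshow(rep.confusion, cmap="Blues")
        ax.set_xticks(range(len(rep.classes)), rep.classes, rotation=45)
        ax.set_yticks(range(len(rep.classes)), rep.classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(tag)
        fig.tight_layout()
        fig.savefig(out / f"confusion_{tag}.png", dpi=100)
        plt.close(fig)
        fig, ax = plt.subplots(figsize=(4, 3.5))
        for cls, (fpr, tpr) in rep.roc_curves.items():
            ax.plot(fpr, tpr, label=str(cls))
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        ax.set_title(f"{tag} (macro AUC {rep.auc_macro:.3f})")
        fig.tight_layout()
        fig.savefig(out / f"roc_{tag}.png", dpi=100)
        plt.close(fig)
        summary[tag] = {
            "mean_accuracy": rep.mean_accuracy,
            "auc_macro": rep.auc_macro,
            "per_subject_accuracy": rep.per_subject_accuracy,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
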