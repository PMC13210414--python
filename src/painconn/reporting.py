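"""Metrics, cross-modality aggregation, parsimony selection and stability.

Per-class metrics follow the one-vs-rest reductions of the 3x3 confusion
matrix (precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN),
with 0/0 -> 0); overall accuracy is trace/total, which equals the binary
accuracy formula under micro-pooled one-vs-rest reduction.  Macro averages
are unweighted class means.  Fold summaries use the sample SD (divisor
n-1); so does the three-modality aggregation.

The parsimony rule picks the smallest feature count k at which (i) High
Pain recall reaches and stays at or above the threshold (default 50%) for
all larger grid values, and (ii) accuracy and macro F1 are within a
tolerance (default 1 percentage point) of the full-feature model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import LABELS, ConfigError
from .evaluation import SweepResult

__all__ = [
    "fold_metrics",
    "summarise",
    "aggregate_modalities",
    "ParsimonyDecision",
    "parsimony_select",
    "stability_counts",
    "per_class_recall_table",
    "plot_sweep",
]


def fold_metrics(cm: np.ndarray) -> dict:
    """Per-class and macro metrics (in %) from a 3x3 confusion matrix.

    Rows are true classes (NP, LP, HP), columns predicted.
    """
    cm = np.asarray(cm)
    if cm.shape != (3, 3):
        raise ConfigError(f"expected a 3x3 confusion matrix, got {cm.shape}")
    if (cm < 0).any() or not np.issubdtype(cm.dtype, np.number):
        raise ConfigError("confusion matrix must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ConfigError("confusion matrix is all zero")

    out: dict = {"accuracy": 100.0 * np.trace(cm) / total, "per_class": {}}
    precs, recs, f1s = [], [], []
    for c, lab in enumerate(LABELS):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        tn = total - tp - fp - fn
        prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
        out["per_class"][lab] = {"tp": int(tp), "fp": int(fp), "fn": int(fn),
                                 "tn": int(tn), "precision": prec,
                                 "recall": rec, "f1": f1}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    out["macro_precision"] = float(np.mean(precs))
    out["macro_recall"] = float(np.mean(recs))
    out["macro_f1"] = float(np.mean(f1s))
    return out


def _cell_frame(sweep: SweepResult) -> pd.DataFrame:
    """Fold-level metric rows for every sweep cell."""
    rows = []
    for (modality, clf, k), folds in sweep.results.items():
        for fr in folds:
            m = fold_metrics(fr.confusion)
            rows.append({
                "modality": modality, "classifier": clf, "k": k,
                "fold": fr.held_out, "accuracy": m["accuracy"],
                "macro_precision": m["macro_precision"],
                "macro_recall": m["macro_recall"], "macro_f1": m["macro_f1"],
                "np_recall": m["per_class"]["NP"]["recall"],
                "lp_recall": m["per_class"]["LP"]["recall"],
                "hp_recall": m["per_class"]["HP"]["recall"],
            })
    return pd.DataFrame(rows)


_METRIC_COLS = ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                "np_recall", "lp_recall", "hp_recall")


def summarise(sweep: SweepResult) -> pd.DataFrame:
    """Mean +/- sample SD across folds per (modality, classifier, k)."""
    cells = _cell_frame(sweep)
    n_folds = {m: max(len(folds) for (mm, _, _), folds in sweep.results.items()
                      if mm == m)
               for m in sweep.modalities}
    gaps = [(m, c, k) for (m, c, k), folds in sweep.results.items()
            if len(folds) != n_folds[m]]
    if gaps:
        raise ConfigError(f"incomplete sweep cells: {sorted(gaps)}")
    agg = cells.groupby(["modality", "classifier", "k"], as_index=False).agg(
        **{f"{c}_{s}": (c, f) for c in _METRIC_COLS
           for s, f in (("mean", "mean"),
                        ("sd", lambda v: v.std(ddof=1)))})
    return agg


def aggregate_modalities(sweep: SweepResult,
                         grid: Sequence[int] | None = None) -> pd.DataFrame:
    """Per feature count: accuracy, macro F1 and HP recall, mean +/- SD
    across the modalities.

    For each (modality, k) the classifier with the best mean accuracy is
    chosen (ties broken by canonical classifier order); the chosen
    classifier per modality is recorded in the output.
    """
    grid = tuple(grid) if grid is not None else sweep.grid
    summary = summarise(sweep)
    order = {c: i for i, c in enumerate(sweep.classifiers)}
    rows = []
    for k in grid:
        picks = {}
        for modality in sweep.modalities:
            sub = summary[(summary.modality == modality) & (summary.k == k)]
            if sub.empty:
                raise ConfigError(f"modality {modality} missing at k={k}")
            sub = sub.sort_values(
                ["accuracy_mean", "classifier"],
                key=lambda s: -s if s.name == "accuracy_mean"
                else s.map(order))
            picks[modality] = sub.iloc[0]
        row = {"k": k,
               "classifiers": ",".join(f"{m}:{picks[m].classifier}"
                                       for m in sweep.modalities)}
        for metric, col in (("accuracy", "accuracy_mean"),
                            ("macro_f1", "macro_f1_mean"),
                            ("hp_recall", "hp_recall_mean")):
            vals = np.array([picks[m][col] for m in sweep.modalities])
            row[f"{metric}_mean"] = vals.mean()
            row[f"{metric}_sd"] = vals.std(ddof=1) if vals.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ParsimonyDecision:
    chosen_k: int | None
    trace: pd.DataFrame           # per-k criterion evaluation
    full_k: int
    full_accuracy: float
    full_macro_f1: float


def parsimony_select(table: pd.DataFrame,
                     hp_recall_threshold: float = 50.0,
                     tolerance_pp: float = 1.0,
                     full_k: int | None = None) -> ParsimonyDecision:
    """Smallest feature count passing both parsimony clauses.

    ``table`` needs columns ``k``, ``accuracy``, ``macro_f1``,
    ``hp_recall`` (percentages).  Clause (i): HP recall at k and at every
    larger grid value is at or above the threshold ("stabilises").
    Clause (ii): accuracy and macro F1 are within ``tolerance_pp``
    percentage points of the full (largest-k) model.  If no k passes, the
    decision carries ``chosen_k=None`` rather than raising.
    """
    required = {"k", "accuracy", "macro_f1", "hp_recall"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigError(f"summary table missing columns: {sorted(missing)}")
    tab = table.sort_values("k").reset_index(drop=True)
    if full_k is None:
        full_k = int(tab.k.iloc[-1])
    full_row = tab[tab.k == full_k]
    if full_row.empty:
        raise ConfigError(f"full model row k={full_k} not present in table")
    full_acc = float(full_row.accuracy.iloc[0])
    full_f1 = float(full_row.macro_f1.iloc[0])

    hp = tab.hp_recall.to_numpy()
    # clause (i): holds at k and at all larger grid values
    stable = np.flip(np.minimum.accumulate(np.flip(hp))) >= hp_recall_threshold
    close = ((tab.accuracy >= full_acc - tolerance_pp)
             & (tab.macro_f1 >= full_f1 - tolerance_pp)).to_numpy()
    trace = tab.copy()
    trace["hp_recall_stable"] = stable
    trace["within_tolerance"] = close
    trace["passes"] = stable & close
    chosen = trace.loc[trace.passes, "k"]
    return ParsimonyDecision(
        chosen_k=int(chosen.iloc[0]) if not chosen.empty else None,
        trace=trace, full_k=full_k,
        full_accuracy=full_acc, full_macro_f1=full_f1)


def stability_counts(sweep: SweepResult, top_m: int = 10) -> pd.DataFrame:
    """Fold-frequency of features among the top-m MI-ranked, per modality.

    Returns one row per (modality, feature) that appeared in any fold's
    top-m, sorted by descending count, with percentage = count / n_folds.
    """
    if not sweep.rankings:
        raise ConfigError("sweep carries no MI ranking logs")
    rows = []
    for modality in sweep.modalities:
        fold_rankings = {f: r for (m, f), r in sweep.rankings.items()
                         if m == modality}
        n_folds = len(fold_rankings)
        counts: dict[str, int] = {}
        for ranking in fold_rankings.values():
            for name in ranking[:top_m]:
                counts[name] = counts.get(name, 0) + 1
        for name, count in counts.items():
            rows.append({"modality": modality, "feature": name,
                         "count": count,
                         "percentage": 100.0 * count / n_folds})
    df = pd.DataFrame(rows)
    return df.sort_values(["modality", "count", "feature"],
                          ascending=[True, False, True]).reset_index(drop=True)


def per_class_recall_table(sweep: SweepResult, k: int) -> pd.DataFrame:
    """Best classifier per modality at feature count k, with per-class
    recall (mean +/- sample SD across folds)."""
    summary = summarise(sweep)
    order = {c: i for i, c in enumerate(sweep.classifiers)}
    rows = []
    for modality in sweep.modalities:
        sub = summary[(summary.modality == modality) & (summary.k == k)]
        if sub.empty:
            raise ConfigError(f"no sweep cell for modality {modality} at k={k}")
        best_acc = sub.accuracy_mean.max()
        tied = sub[sub.accuracy_mean == best_acc]
        best = tied.loc[tied.classifier.map(order).idxmin()]
        rows.append({
            "modality": modality, "model": best.classifier, "k": k,
            "accuracy_mean": best.accuracy_mean, "accuracy_sd": best.accuracy_sd,
            "np_recall_mean": best.np_recall_mean, "np_recall_sd": best.np_recall_sd,
            "lp_recall_mean": best.lp_recall_mean, "lp_recall_sd": best.lp_recall_sd,
            "hp_recall_mean": best.hp_recall_mean, "hp_recall_sd": best.hp_recall_sd,
            "tie": len(tied) > 1,
        })
    return pd.DataFrame(rows)


def plot_sweep(sweep: SweepResult, out_dir: str | Path,
               fmt: str = "png") -> list[Path]:
    """Accuracy-vs-feature-count curves (mean line + SD band) per modality.

    Writes one figure per modality plus the underlying data as TSV.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = summarise(sweep)
    paths: list[Path] = []
    for modality in sweep.modalities:
        fig, ax = plt.subplots(figsize=(6, 4))
        for clf in sweep.classifiers:
            sub = summary[(summary.modality == modality)
                          & (summary.classifier == clf)].sort_values("k")
            marker = "o" if len(sub) == 1 else None
            ax.plot(sub.k, sub.accuracy_mean, label=clf, marker=marker)
            ax.fill_between(sub.k,
                            sub.accuracy_mean - sub.accuracy_sd.fillna(0),
                            sub.accuracy_mean + sub.accuracy_sd.fillna(0),
                            alpha=0.2)
        ax.set_xlabel("number of selected features")
        ax.set_ylabel("accuracy (%)")
        ax.set_title(f"LOSO accuracy vs feature count ({modality})")
        ax.legend()
        fig.tight_layout()
        fig_path = out_dir / f"sweep_{modality}.{fmt}"
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
        tsv_path = out_dir / f"sweep_{modality}.tsv"
        summary[summary.modality == modality].to_csv(tsv_path, sep="\t",
                                                     index=False)
        paths.extend([fig_path, tsv_path])
    return paths
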