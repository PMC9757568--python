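"""Figure rendering from serialized run reports (confusion matrix, ROC,
learning curve, importance bars).  Figures are a view on the machine-readable
report, never a required output."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_confusion(level_report: dict, path: str | Path) -> None:
    rates = np.array(level_report["test"]["confusion_matrix_rates"])
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(rates, cmap="Blues", vmin=0, vmax=1)
    for i in range(2):
        for j in range(2):
            ax.text(j, i, f"{rates[i, j]:.1%}", ha="center", va="center")
    ax.set_xticks([0, 1], ["pred 0", "pred 1"])
    ax.set_yticks([0, 1], ["true 0", "true 1"])
    ax.set_title(f"Level {level_report['level']} confusion (test)")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(level_report: dict, path: str | Path) -> None:
    roc = level_report["test"]["roc"]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for cls, data in roc["per_class"].items():
        ax.plot(data["fpr"], data["tpr"], label=f"class {cls} (AUC {data['auc']:.2f})")
    ax.plot(roc["micro"]["fpr"], roc["micro"]["tpr"], "--",
            label=f"micro (AUC {roc['micro']['auc']:.2f})")
    ax.plot([0, 1], [0, 1], color="pink", ls=":", label="random")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"Level {level_report['level']} ROC "
                 f"(macro AUC {roc['macro']['auc']:.2f})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_learning_curve(level_report: dict, path: str | Path) -> None:
    pts = [p for p in level_report["learning_curve"] if "test_accuracy" in p]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot([p["size"] for p in pts], [p["train_accuracy"] for p in pts],
            "o-", label="train")
    ax.plot([p["size"] for p in pts], [p["test_accuracy"] for p in pts],
            "s-", label="test")
    ax.set_xlabel("training rows")
    ax.set_ylabel("accuracy")
    ax.set_title(f"Level {level_report['level']} learning curve")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_importance(level_report: dict, path: str | Path, top_k: int = 15) -> None:
    ranking = level_report["attribution"]["ranking"][:top_k]
    names = [r["feature"] for r in ranking][::-1]
    c0 = [r["mean_abs_class0"] for r in ranking][::-1]
    c1 = [r["mean_abs_class1"] for r in ranking][::-1]
    y = np.arange(len(names))
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(names) + 1.5))
    ax.barh(y + 0.2, c0, height=0.4, color="gray", label="class 0 (control)")
    ax.barh(y - 0.2, c1, height=0.4, color="c", label="class 1 (on effect)")
    ax.set_yticks(y, names, fontsize=7)
    ax.set_xlabel("mean |Shapley value|")
    ax.set_title(f"Level {level_report['level']} feature importance")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report_figures(payload: dict, out_dir: str | Path) -> list[Path]:
    """Regenerate all standard figures for every level in a report payload."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for level, rep in payload["levels"].items():
        for kind, fn in (("confusion", plot_confusion), ("roc", plot_roc),
                         ("learning_curve", plot_learning_curve),
                         ("importance", plot_importance)):
            path = out_dir / f"level_{level}_{kind}.png"
            fn(rep, path)
            written.append(path)
    return written
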