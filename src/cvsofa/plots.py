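"""Figures for the validation report: ROC overlay, per-level distribution
with mortality, and calibration curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import EvalReport

__all__ = ["make_figures"]


def _roc_points(scores: np.ndarray, outcomes: np.ndarray):
    order = np.argsort(-scores, kind="mergesort")
    y = outcomes[order]
    tps = np.concatenate([[0], np.cumsum(y)])
    fps = np.concatenate([[0], np.cumsum(1 - y)])
    # collapse tied thresholds
    s = scores[order]
    keep = np.concatenate([[True], s[1:] != s[:-1], [True]])
    idx = np.flatnonzero(keep)
    return fps[idx] / max(fps[-1], 1), tps[idx] / max(tps[-1], 1)


def make_figures(
    report: EvalReport,
    scores,
    outcomes,
    outdir: str | Path,
) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outcomes = np.asarray(outcomes, dtype=int)
    written = []

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in report.roc.items():
        fpr, tpr = _roc_points(scores[name].to_numpy(dtype=float), outcomes)
        ax.plot(fpr, tpr, label=f"{name} ({roc.auroc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = outdir / "roc.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    n_panels = len(report.distribution)
    fig, axes = plt.subplots(
        1, n_panels, figsize=(3.2 * n_panels, 3.2), squeeze=False
    )
    for ax, (name, table) in zip(axes[0], report.distribution.items()):
        ax2 = ax.twinx()
        ax.bar(table["score_level"], table["n"], color="#9bb8d3")
        ax2.errorbar(
            table["score_level"],
            table["observed_mortality"],
            yerr=[
                np.maximum(table["observed_mortality"] - table["ci_low"], 0.0),
                np.maximum(table["ci_high"] - table["observed_mortality"], 0.0),
            ],
            fmt="o-",
            color="#b03a2e",
            ms=3,
        )
        ax.set_title(name, fontsize=8)
        ax.set_xlabel("score")
        ax2.set_ylim(0, 1)
    fig.tight_layout()
    path = outdir / "distribution_mortality.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, table in report.calibration.items():
        if "predicted_mortality" in table:
            ax.plot(
                table["predicted_mortality"],
                table["observed_mortality"],
                "o-",
                label=name,
                ms=3,
            )
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("Predicted mortality")
    ax.set_ylabel("Observed mortality")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = outdir / "calibration.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
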