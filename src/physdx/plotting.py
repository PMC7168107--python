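"""Bar-chart and probe-curve figures for batch evaluation reports."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

from .metrics import MetricsReport


def plot_report(
    report: MetricsReport,
    out_dir: Union[str, Path],
    random_report: Optional[MetricsReport] = None,
) -> list[Path]:
    """Write before/after bar charts per metric and the mean probe curve.

    Returns the list of files written. With ``random_report`` given, the
    probe-curve figure overlays both policies.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    means = report.per_cardinality_means()
    written: list[Path] = []

    panels = [
        ("set_size", "Diagnosis-set size"),
        ("weighted_fpr", "Weighted FPR"),
        ("auc", "Health-state AUC"),
        ("wasted_effort", "Wasted effort"),
    ]
    for metric, label in panels:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        x = means.index.to_numpy()
        w = 0.38
        ax.bar(x - w / 2, means[f"{metric}_before"], w, label="before", color="#3b6fb6")
        ax.bar(x + w / 2, means[f"{metric}_after"], w, label="after", color="#4caf50")
        ax.set_xlabel("injected fault cardinality")
        ax.set_ylabel(label)
        ax.set_xticks(x)
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"{metric}_before_after.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    # top-K hit rates
    df = report.to_dataframe()
    ks = list(range(1, 6))
    fig, ax = plt.subplots(figsize=(5, 3.2))
    before = [df[f"top{k}_hit_before"].mean() for k in ks]
    after = [df[f"top{k}_hit_after"].mean() for k in ks]
    w = 0.38
    ax.bar([k - w / 2 for k in ks], before, w, label="before", color="#3b6fb6")
    ax.bar([k + w / 2 for k in ks], after, w, label="after", color="#4caf50")
    ax.set_xlabel("K")
    ax.set_ylabel("top-K hit rate")
    ax.set_xticks(ks)
    ax.legend()
    fig.tight_layout()
    path = out_dir / "topk_before_after.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(report.mean_probe_curve(), marker="o", label=report.policy)
    if random_report is not None:
        ax.plot(random_report.mean_probe_curve(), marker="s", label=random_report.policy)
    ax.set_xlabel("number of probes")
    ax.set_ylabel("mean diagnosis-set size")
    ax.legend()
    fig.tight_layout()
    path = out_dir / "probe_curve.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
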