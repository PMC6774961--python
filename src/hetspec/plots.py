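"""Optional convenience plots of the CSV tables (flag-gated; nothing in the
analysis depends on these and no test asserts on images)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .classes import BASE_CHANGE_TYPES, enumerate_classes, gc_content
from .pipeline import PipelineResult


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_binned_proportions(result: PipelineResult, path: Path,
                            copy_number: int = 1) -> None:
    """96-panel grid of class proportion (×1000) vs het bin, one line per
    region — the per-class trend view."""
    plt = _mpl()
    long = result.counts.proportions_x1000()
    long = long[long["copy_number"] == copy_number]
    fig, axes = plt.subplots(12, 8, figsize=(22, 26), sharex=True)
    for ax, cls in zip(axes.ravel(), enumerate_classes()):
        sub = long[long["class"] == cls.label]
        for region, grp in sub.groupby("region"):
            grp = grp.sort_values("het_bin")
            ax.plot(grp["het_bin"], grp["proportion_x1000"], lw=0.8, label=region)
        ax.set_title(cls.label, fontsize=7)
        ax.tick_params(labelsize=6)
    axes[0, 0].legend(fontsize=5)
    fig.suptitle(f"class proportion x1000 vs heterozygosity bin (copy {copy_number})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_slopes(result: PipelineResult, path: Path, copy_number: int = 1) -> None:
    """Per-class slopes, one line per region, transitions and transversions."""
    plt = _mpl()
    df = result.results.frame
    df = df[(df["copy_number"] == copy_number) & (df["status"] == "ok")]
    labels = [c.label for c in enumerate_classes()]
    fig, ax = plt.subplots(figsize=(18, 5))
    for region, grp in df.groupby("region"):
        grp = grp.set_index("class").reindex(labels)
        ax.plot(range(len(labels)), grp["slope"], lw=0.8, marker=".", label=region)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=5)
    ax.set_ylabel("slope (logit per bin)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_gc_trend(result: PipelineResult, path: Path, copy_number: int = 1) -> None:
    """Mean class slope vs triplet GC content, one fitted line per type."""
    plt = _mpl()
    means = result.results.mean_slopes(copy_number)
    fig, ax = plt.subplots(figsize=(6, 5))
    for change in BASE_CHANGE_TYPES:
        classes = [c for c in enumerate_classes() if c.base_change == change]
        gc = np.array([gc_content(c) for c in classes], dtype=float)
        vals = np.array([means.get(c.label, np.nan) for c in classes])
        ok = np.isfinite(vals)
        ax.scatter(gc[ok], vals[ok], s=12, label=change)
        if ok.sum() >= 2 and np.unique(gc[ok]).size >= 2:
            b, a = np.polyfit(gc[ok], vals[ok], 1)
            xs = np.array([-0.1, 3.1])
            ax.plot(xs, a + b * xs, lw=0.8)
    ax.set_xlabel("triplet GC content (0-3)")
    ax.set_ylabel("mean slope across regions")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_all(result: PipelineResult, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    out = []
    copies = sorted(
        {s.copy_number for s in result.results.slopes if s.copy_number is not None}
    )
    primary = 1 if 1 in copies else (copies[0] if copies else None)
    if primary is None:
        return out
    for name, fn in [
        ("binned_proportions.png", plot_binned_proportions),
        ("slopes.png", plot_slopes),
        ("gc_trend.png", plot_gc_trend),
    ]:
        path = outdir / name
        fn(result, path, primary)
        out.append(path)
    return out
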