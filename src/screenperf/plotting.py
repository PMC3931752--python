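"""Region plots and trajectory overlays (matplotlib, optional output)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .classification import Benchmark
from .volume_planning import boundary_curve, default_grid

__all__ = ["region_plot", "annual_vs_aggregate_plot"]


def region_plot(
    benchmark: Benchmark,
    volumes=None,
    mode: str = "continuous",
    trajectories=None,
    ax=None,
):
    """Adequate / uncertain / inadequate regions in the (volume, rate) plane.

    ``trajectories`` is an optional mapping of label -> list of
    PhysicianPeriodSummary (cumulative points) overlaid on the regions.
    """
    if volumes is None:
        volumes = default_grid(benchmark)
    scale = 1000.0 if benchmark.threshold < 0.01 else 100.0
    unit = "per 1000" if scale == 1000.0 else "%"
    points = boundary_curve(volumes, benchmark, mode=mode)
    xs = [p.volume for p in points]
    adequate = [
        None if p.adequate_boundary is None else p.adequate_boundary * scale
        for p in points
    ]
    inadequate = [
        None if p.inadequate_boundary is None else p.inadequate_boundary * scale
        for p in points
    ]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(xs, adequate, color="tab:green", label="adequacy boundary")
    ax.plot(xs, inadequate, color="tab:red", label="inadequacy boundary")
    ax.axhline(
        benchmark.threshold * scale, color="k", ls=":", lw=0.8,
        label=f"threshold {benchmark.threshold * scale:g} {unit}",
    )
    if benchmark.reference_median is not None:
        ax.axhline(
            benchmark.reference_median * scale, color="gray", ls="--", lw=0.8,
            label=f"reference median {benchmark.reference_median * scale:g} {unit}",
        )
    if trajectories:
        metric = benchmark.metric_name.lower()
        for label, summaries in trajectories.items():
            tx = [s.volume for s in summaries]
            ty = [getattr(s, metric).value * scale for s in summaries]
            ax.plot(tx, ty, marker="o", ms=3, lw=1, label=label)
    ax.set_xlabel("interpretive volume (screening exams)")
    ax.set_ylabel(f"{benchmark.metric_name} ({unit})")
    ax.legend(fontsize=8)
    return ax


def annual_vs_aggregate_plot(summaries, metric: str = "cdr", ax=None):
    """Bar chart of annual rates per physician with the aggregate alongside."""
    import pandas as pd

    frame = pd.DataFrame([s.as_dict() for s in summaries])
    scale = 1000.0 if metric == "cdr" else 100.0
    pivot = frame.pivot(index="physician_id", columns="period", values=metric) * scale
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    pivot.plot.bar(ax=ax)
    ax.set_ylabel(f"{metric.upper()} ({'per 1000' if metric == 'cdr' else '%'})")
    return ax
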