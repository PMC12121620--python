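"""Locus and peak plots.

Locus plots (one per locus x readset) stack four panels: fragment
coverage from pairs whose R-read synthesis origin lies inside the
region of interest; the same for pairs whose origin lies outside it;
the union of the two; and the convolution track with detected peak
bounds. Panels are scaled independently to their own maxima. Plots land
in ``pass/`` when any peak under that readset was called a termination
event, ``fail/`` otherwise.

Peak plots (one per locus) show fractional coverage change against
relative position for every clustered peak, with lines joining peaks
from the same readset, ellipses outlining clusters (solid when the
cluster holds a passing termination peak, dashed otherwise) and an
asterisk over significant clusters.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .compare import LocusCall
from .config import PipelineConfig
from .coverage import CoverageProfile, SINGLE, accumulate_pair
from .reference import ReferenceWindow


def _subset_coverage(
    profile: CoverageProfile, roi: tuple[int, int], inside: bool
) -> np.ndarray:
    """Total coverage from pairs whose R-read origin is inside/outside the ROI."""
    sub = CoverageProfile.empty(
        profile.locus_id,
        profile.readset_id,
        profile.condition_id,
        len(profile),
        profile.riboswitch_start,
        profile.riboswitch_end,
    )
    for pair in profile.pairs:
        if pair.orientation == SINGLE or pair.r_span is None:
            in_roi = False
        else:
            origin = pair.r_span[1] - 1
            in_roi = roi[0] <= origin < roi[1]
        if in_roi == inside:
            accumulate_pair(sub, pair, allow_single_reads=True, allow_soft_clips=True)
    return sub.total_coverage


def render_locus_plot(
    window: ReferenceWindow,
    profile: CoverageProfile,
    convolution: np.ndarray | None,
    peaks: Sequence,
    roi: tuple[int, int],
    path: Path,
) -> None:
    x = np.arange(len(profile))
    fig, axes = plt.subplots(4, 1, figsize=(9, 8), sharex=True)
    inside = _subset_coverage(profile, roi, inside=True)
    outside = _subset_coverage(profile, roi, inside=False)
    panels = [
        (inside, "pairs with R origin in ROI"),
        (outside, "pairs with R origin outside ROI"),
        (profile.total_coverage, "total fragment coverage"),
    ]
    for ax, (track, label) in zip(axes[:3], panels):
        ax.fill_between(x, track, step="mid", alpha=0.7)
        ax.set_ylabel("coverage")
        ax.set_title(label, fontsize=9, loc="left")
    ax = axes[3]
    if convolution is not None:
        ax.plot(x, convolution, lw=0.8)
        for p in peaks:
            ax.axvspan(p.left_bound, p.right_bound, alpha=0.15, color="red" if p.sign == "+" else "blue")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("amplitude")
    ax.set_title("signed-termini convolution", fontsize=9, loc="left")
    for ax in axes:
        ax.axvspan(
            window.riboswitch_start, window.riboswitch_end, color="gold", alpha=0.2
        )
    axes[3].set_xlabel("window position (nt)")
    fig.suptitle(f"{profile.locus_id} | {profile.readset_id} ({profile.condition_id})")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_peak_plot(locus_call: LocusCall, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 5))
    by_readset: dict[str, list] = {}
    for cluster in locus_call.clusters:
        for peak, cond in cluster.members:
            by_readset.setdefault(peak.readset_id, []).append(peak)
    cmap = plt.get_cmap("tab10")
    conds = sorted({c for cl in locus_call.clusters for _, c in cl.members})
    cond_color = {c: cmap(i % 10) for i, c in enumerate(conds)}
    for rid, pks in sorted(by_readset.items()):
        pks = sorted(pks, key=lambda p: p.relative_position)
        xs = [p.relative_position for p in pks]
        ys = [p.fractional_coverage_change for p in pks]
        color = cond_color.get(pks[0].condition_id, "gray")
        ax.plot(xs, ys, "-o", ms=4, lw=0.8, color=color, alpha=0.8)
    for cluster in locus_call.clusters:
        xs = [p.relative_position for p, _ in cluster.members]
        ys = [p.fractional_coverage_change for p, _ in cluster.members]
        cx, cy = np.mean(xs), np.mean(ys)
        w = max(np.ptp(xs), 0.01) * 1.6
        h = max(np.ptp(ys), 0.05) * 1.4
        style = "solid" if cluster.has_passing_termination_peak else "dashed"
        ax.add_patch(
            Ellipse(
                (cx, cy), w, h, fill=False, ls=style, ec="black", lw=0.9, alpha=0.7
            )
        )
        if cluster.decision == "significant":
            ax.annotate(
                "*",
                (cx, cy + h / 2),
                ha="center",
                fontsize=16,
                color="crimson",
            )
    handles = [
        plt.Line2D([], [], color=col, marker="o", ls="-", label=c)
        for c, col in cond_color.items()
    ]
    if handles:
        ax.legend(handles=handles, fontsize=8, title="condition")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("peak position relative to riboswitch 3' end (riboswitch-size units)")
    ax.set_ylabel("fractional coverage change")
    ax.set_title(f"{locus_call.locus_id} ({locus_call.family}) - {locus_call.verdict}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_all(
    windows: Sequence[ReferenceWindow],
    profile_results: Mapping[tuple[str, str], object],
    locus_calls: Sequence[LocusCall],
    config: PipelineConfig,
    outdir: Path,
) -> None:
    from .compare import region_of_interest

    locus_dir = outdir / "locus"
    (locus_dir / "pass").mkdir(parents=True, exist_ok=True)
    (locus_dir / "fail").mkdir(parents=True, exist_ok=True)
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(parents=True, exist_ok=True)
    windows_by_id = {w.locus_id: w for w in windows}
    for (locus_id, readset_id), result in sorted(profile_results.items()):
        window = windows_by_id[locus_id]
        roi = region_of_interest(
            window.riboswitch_start, window.riboswitch_end, config.roi_half_width_prop
        )
        any_pass = any(c.decision == "pass" for c in result.calls)
        sub = "pass" if any_pass else "fail"
        render_locus_plot(
            window,
            result.profile,
            result.convolution,
            result.peaks,
            roi,
            locus_dir / sub / f"{locus_id}__{readset_id}.png",
        )
    for lc in locus_calls:
        render_peak_plot(lc, peak_dir / f"{lc.locus_id}.png")
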