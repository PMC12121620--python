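"""End-to-end orchestration: ingest -> convolve -> call -> cluster -> report.

Runs every locus x readset through coverage accumulation, edge
detection and per-peak termination calling, then clusters peaks across
conditions per locus and applies the cross-condition mean/variance
tests. Emits ``peak_log.csv`` (one row per candidate peak),
``cluster_stats.csv`` (one row per cluster), ``verdicts.csv`` (one row
per locus), and optionally locus/peak plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import compare
from .calls import PeakCall, call_peak, noise_region
from .compare import (
    LocusCall,
    PeakCluster,
    call_locus,
    cluster_peaks,
    evaluate_clusters,
    region_of_interest,
)
from .config import PipelineConfig
from .coverage import CoverageProfile, build_profile, passes_depth_filter
from .edges import assign_relative_positions, convolve_signed_termini, detect_peaks, make_kernel
from .reference import ReferenceWindow

logger = logging.getLogger(__name__)


@dataclass
class ProfileResult:
    """Everything computed for one locus x readset."""

    profile: CoverageProfile
    passed_depth: bool
    convolution: Optional[np.ndarray] = None
    peaks: list = field(default_factory=list)
    calls: list[PeakCall] = field(default_factory=list)


@dataclass
class PipelineResult:
    locus_calls: list[LocusCall]
    profile_results: dict[tuple[str, str], ProfileResult]  # (locus, readset)
    peak_log: pd.DataFrame
    cluster_stats: pd.DataFrame
    verdicts: pd.DataFrame
    outdir: Optional[Path] = None

    def locus_call(self, locus_id: str) -> LocusCall:
        for lc in self.locus_calls:
            if lc.locus_id == locus_id:
                return lc
        raise KeyError(locus_id)


def run_pipeline(
    config: PipelineConfig,
    windows: Sequence[ReferenceWindow],
    sam_paths: Mapping[str, str | Path],
    condition_map: Mapping[str, str],
    outdir: str | Path | None = None,
    families: Mapping[str, str] | None = None,
    make_plots: bool = True,
) -> PipelineResult:
    """Run the full termination-detection pipeline.

    Parameters
    ----------
    windows : reference windows, one per riboswitch locus.
    sam_paths : readset_id -> SAM/BAM path (alignments against the windows).
    condition_map : readset_id -> condition_id.
    outdir : where to write CSVs and plots; in-memory only if None.
    families : optional locus_id -> riboswitch family for reporting.
    """
    families = dict(families or {})
    kernel = make_kernel(config.sigma, config.kernel_half_width)
    readsets = sorted(sam_paths)
    missing = [r for r in readsets if r not in condition_map]
    if missing:
        raise ValueError(f"readsets missing from condition map: {missing}")

    profile_results: dict[tuple[str, str], ProfileResult] = {}
    locus_calls: list[LocusCall] = []
    peak_rows: list[dict] = []

    for window in windows:
        region = noise_region(
            window.riboswitch_start,
            window.riboswitch_end,
            config.ext_prop,
            window_length=len(window.sequence),
        )
        roi = region_of_interest(
            window.riboswitch_start, window.riboswitch_end, config.roi_half_width_prop
        )
        roi_peaks: list[tuple] = []  # (Peak, condition_id) for clustering
        call_by_peak: dict[int, PeakCall] = {}
        per_condition_pass: dict[str, bool] = {}
        any_passed_depth = False

        for readset_id in readsets:
            condition_id = condition_map[readset_id]
            per_condition_pass.setdefault(condition_id, False)
            profile = build_profile(
                sam_paths[readset_id], window, readset_id, condition_id, config
            )
            passed = passes_depth_filter(profile, config.min_cov_depth)
            result = ProfileResult(profile=profile, passed_depth=passed)
            profile_results[(window.locus_id, readset_id)] = result
            if not passed:
                logger.info(
                    "locus %s readset %s below depth threshold (%.1f < %s)",
                    window.locus_id,
                    readset_id,
                    profile.mean_riboswitch_read_coverage,
                    config.min_cov_depth,
                )
                continue
            any_passed_depth = True

            conv = convolve_signed_termini(profile.signed_termini, kernel)
            peaks = detect_peaks(
                conv,
                config.zero_band,
                locus_id=window.locus_id,
                readset_id=readset_id,
                condition_id=condition_id,
            )
            assign_relative_positions(
                peaks, window.riboswitch_end, window.riboswitch_size
            )
            region_peaks = [p for p in peaks if region[0] <= p.summit < region[1]]
            result.convolution = conv
            result.peaks = peaks
            for peak in peaks:
                call = call_peak(
                    peak,
                    region_peaks,
                    profile,
                    region,
                    alpha=config.alpha_peak,
                    min_drop=config.min_drop,
                    min_noise_set=config.min_noise_set,
                )
                result.calls.append(call)
                call_by_peak[id(peak)] = call
                if call.decision == "pass":
                    per_condition_pass[condition_id] = True
                peak_rows.append(
                    _peak_row(window, families, call)
                )
                if roi[0] <= peak.summit < roi[1]:
                    roi_peaks.append((peak, condition_id))

        clusters = cluster_peaks(
            roi_peaks, config.cophenetic_threshold, locus_id=window.locus_id
        )
        evaluate_clusters(
            clusters,
            roi_peaks,
            call_by_peak,
            alpha_mean=config.alpha_mean,
            alpha_variance=config.alpha_variance,
            n_levene_comparisons=config.n_levene_comparisons,
            seed=config.seed,
        )
        locus_calls.append(
            call_locus(
                window.locus_id,
                families.get(window.locus_id, "unknown"),
                clusters,
                per_condition_pass,
                any_condition_passed_depth=any_passed_depth,
            )
        )

    peak_log = pd.DataFrame(peak_rows, columns=_PEAK_COLUMNS)
    cluster_stats = _cluster_frame(locus_calls)
    verdicts = _verdict_frame(locus_calls)

    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        peak_log.to_csv(out / "peak_log.csv", index=False)
        cluster_stats.to_csv(out / "cluster_stats.csv", index=False)
        verdicts.to_csv(out / "verdicts.csv", index=False)
        config.to_yaml(out / "config.yaml")
        if make_plots:
            from . import plots

            plots.render_all(
                windows, profile_results, locus_calls, config, out / "plots"
            )

    n_sig = sum(lc.verdict == compare.TERMINATION_EVIDENCE for lc in locus_calls)
    logger.info(
        "analyzed %d loci: %d with termination evidence; %d candidate peaks",
        len(windows),
        n_sig,
        len(peak_rows),
    )
    return PipelineResult(
        locus_calls=locus_calls,
        profile_results=profile_results,
        peak_log=peak_log,
        cluster_stats=cluster_stats,
        verdicts=verdicts,
        outdir=out,
    )


_PEAK_COLUMNS = [
    "locus_id",
    "family",
    "readset_id",
    "condition_id",
    "summit",
    "left_bound",
    "right_bound",
    "width",
    "amplitude",
    "sign",
    "relative_position",
    "coverage_drop_fraction",
    "noise_set_size",
    "noise_mean_width",
    "noise_mean_amplitude",
    "noise_var_width",
    "noise_var_amplitude",
    "noise_cov_wa",
    "pseudo_p",
    "decision",
    "fail_reason",
]


def _peak_row(window: ReferenceWindow, families: Mapping[str, str], call: PeakCall) -> dict:
    p = call.peak
    m = call.noise_model
    return {
        "locus_id": p.locus_id,
        "family": families.get(p.locus_id, "unknown"),
        "readset_id": p.readset_id,
        "condition_id": p.condition_id,
        "summit": p.summit,
        "left_bound": p.left_bound,
        "right_bound": p.right_bound,
        "width": p.width,
        "amplitude": p.amplitude,
        "sign": p.sign,
        "relative_position": p.relative_position,
        "coverage_drop_fraction": call.coverage_drop_fraction,
        "noise_set_size": m.n_peaks if m else 0,
        "noise_mean_width": m.mean[0] if m else float("nan"),
        "noise_mean_amplitude": m.mean[1] if m else float("nan"),
        "noise_var_width": m.covariance[0, 0] if m else float("nan"),
        "noise_var_amplitude": m.covariance[1, 1] if m else float("nan"),
        "noise_cov_wa": m.covariance[0, 1] if m else float("nan"),
        "pseudo_p": call.pseudo_p,
        "decision": call.decision,
        "fail_reason": call.fail_reason,
    }


_CLUSTER_COLUMNS = [
    "locus_id",
    "cluster_id",
    "centroid_relative_position",
    "n_members",
    "conditions",
    "has_passing_termination_peak",
    "mean_test_p",
    "variance_test_p",
    "decision",
]


def _cluster_frame(locus_calls: Sequence[LocusCall]) -> pd.DataFrame:
    rows = []
    for lc in locus_calls:
        for c in lc.clusters:
            rows.append(
                {
                    "locus_id": c.locus_id,
                    "cluster_id": c.cluster_id,
                    "centroid_relative_position": c.centroid_relative_position,
                    "n_members": c.size,
                    "conditions": ";".join(c.conditions),
                    "has_passing_termination_peak": c.has_passing_termination_peak,
                    "mean_test_p": c.mean_test_p,
                    "variance_test_p": c.variance_test_p,
                    "decision": c.decision,
                }
            )
    return pd.DataFrame(rows, columns=_CLUSTER_COLUMNS)


def _verdict_frame(locus_calls: Sequence[LocusCall]) -> pd.DataFrame:
    rows = []
    for lc in locus_calls:
        rows.append(
            {
                "locus_id": lc.locus_id,
                "family": lc.family,
                "n_conditions_analyzed": lc.n_conditions_analyzed,
                "n_clusters": len(lc.clusters),
                "verdict": lc.verdict,
                "per_condition_state": ";".join(
                    f"{c}={s}" for c, s in sorted(lc.per_condition_state.items())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "family",
            "n_conditions_analyzed",
            "n_clusters",
            "verdict",
            "per_condition_state",
        ],
    )
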