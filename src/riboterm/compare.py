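"""Cross-condition peak clustering and locus-level significance calls.

Peaks from every condition that fall within +/- half a riboswitch
length of the riboswitch 3' end are clustered on their relative
positions by complete-linkage hierarchical clustering cut at a
cophenetic distance threshold. A cluster that captured both the ON and
OFF states of a transcription-terminating riboswitch should show a
fractional coverage change whose mean is more negative (Mann-Whitney
one-tailed U-test against all other peaks) and whose variance is larger
(Levene's test against repeated size-matched random samples of other
peaks) than baseline. A locus is called as showing evidence of
condition-dependent transcription termination when at least one cluster
holds a passing termination peak and passes both tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import levene, mannwhitneyu

from .calls import PeakCall
from .edges import Peak

logger = logging.getLogger(__name__)

#: locus verdict labels
TERMINATION_EVIDENCE = "termination_evidence"
INCONCLUSIVE = "inconclusive"
LOW_COVERAGE = "low_coverage"
NO_CANDIDATE_PEAKS = "no_candidate_peaks"


@dataclass
class PeakCluster:
    cluster_id: str
    locus_id: str
    members: list[tuple[Peak, str]]  # (peak, condition_id)
    centroid_relative_position: float
    has_passing_termination_peak: bool = False
    mean_test_p: float = float("nan")
    variance_test_p: float = float("nan")
    decision: str = "not_significant"

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def conditions(self) -> list[str]:
        return sorted({c for _, c in self.members})

    @property
    def values(self) -> np.ndarray:
        return np.array(
            [p.fractional_coverage_change for p, _ in self.members], dtype=float
        )


@dataclass
class LocusCall:
    locus_id: str
    family: str
    n_conditions_analyzed: int
    clusters: list[PeakCluster]
    verdict: str
    per_condition_state: dict[str, str] = field(default_factory=dict)


def region_of_interest(
    riboswitch_start: int,
    riboswitch_end: int,
    half_width_prop: float = 0.5,
) -> tuple[int, int]:
    """Window interval within +/- ``half_width_prop`` x size of the riboswitch 3' end."""
    size = riboswitch_end - riboswitch_start
    if size <= 0:
        raise ValueError("riboswitch size must be positive")
    half = half_width_prop * size
    return int(round(riboswitch_end - half)), int(round(riboswitch_end + half))


def cluster_peaks(
    peaks: Sequence[tuple[Peak, str]],
    threshold: float = 0.04,
    locus_id: str = "",
) -> list[PeakCluster]:
    """Complete-linkage clustering of peaks on 1-D relative position.

    Flat clusters are cut where the cophenetic distance is at most
    ``threshold``, so the maximum pairwise spread of relative positions
    inside a cluster never exceeds it. Singletons are allowed. Clusters
    are returned sorted by centroid position.
    """
    if not peaks:
        return []
    positions = np.array([[p.relative_position] for p, _ in peaks], dtype=float)
    if len(peaks) == 1:
        labels = np.array([1])
    else:
        link = hierarchy.linkage(positions, method="complete")
        labels = hierarchy.fcluster(link, t=threshold, criterion="distance")
    clusters: list[PeakCluster] = []
    for lab in np.unique(labels):
        members = [pc for pc, m in zip(peaks, labels == lab) if m]
        centroid = float(np.mean([p.relative_position for p, _ in members]))
        clusters.append(
            PeakCluster(
                cluster_id="",
                locus_id=locus_id,
                members=list(members),
                centroid_relative_position=centroid,
            )
        )
    clusters.sort(key=lambda c: c.centroid_relative_position)
    for i, c in enumerate(clusters):
        c.cluster_id = f"{locus_id}::c{i}"
    return clusters


def test_cluster_mean(
    cluster_values: np.ndarray, other_values: np.ndarray
) -> float:
    """One-tailed Mann-Whitney U p-value: cluster coverage changes stochastically smaller.

    Exact null distribution when both samples are small and untied;
    midrank/normal approximation otherwise (scipy's automatic method
    selection). With no comparison peaks the test is uninformative and
    returns p = 1.
    """
    if len(other_values) == 0:
        logger.warning("no comparison peaks for cluster mean test; p = 1")
        return 1.0
    res = mannwhitneyu(cluster_values, other_values, alternative="less", method="auto")
    return float(res.pvalue)


def test_cluster_variance(
    cluster_values: np.ndarray,
    superset_values: np.ndarray,
    n_comparisons: int = 60,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Median p from repeated Levene comparisons against size-matched samples.

    Size-``n`` samples are drawn without replacement from the superset
    of all other peaks at the locus, pass by pass; when a pass exhausts
    the superset before ``n_comparisons`` comparisons are collected, all
    peaks are replaced and resampled. Each comparison is a classical
    (mean-centered) Levene test of the cluster against one sample; the
    median of the collected p-values is returned. Requires cluster size
    >= 2 and a superset at least as large as the cluster.
    """
    n = len(cluster_values)
    if n < 2:
        raise ValueError("degenerate_cluster: variance test needs >= 2 members")
    if len(superset_values) < n:
        raise ValueError("superset smaller than cluster")
    rng = np.random.default_rng(rng)
    pvals: list[float] = []
    while len(pvals) < n_comparisons:
        perm = rng.permutation(superset_values)
        n_chunks = len(perm) // n
        for i in range(n_chunks):
            sample = perm[i * n : (i + 1) * n]
            with np.errstate(all="ignore"):
                p = levene(cluster_values, sample, center="mean").pvalue
            pvals.append(1.0 if np.isnan(p) else float(p))
            if len(pvals) >= n_comparisons:
                break
    return float(np.median(pvals))


def evaluate_clusters(
    clusters: list[PeakCluster],
    all_roi_peaks: Sequence[tuple[Peak, str]],
    peak_calls: dict[int, PeakCall],
    alpha_mean: float = 0.05,
    alpha_variance: float = 0.05,
    n_levene_comparisons: int = 60,
    seed: int = 1729,
) -> None:
    """Run mean and variance tests on every cluster, in place.

    ``peak_calls`` maps ``id(peak)`` to its termination call so the
    cluster-level "has passing peak" flag can be taken from the per-peak
    stage.
    """
    rng = np.random.default_rng(seed)
    all_values = {id(p): p.fractional_coverage_change for p, _ in all_roi_peaks}
    for cluster in clusters:
        member_ids = {id(p) for p, _ in cluster.members}
        others = np.array(
            [v for pid, v in all_values.items() if pid not in member_ids],
            dtype=float,
        )
        cluster.has_passing_termination_peak = any(
            peak_calls.get(id(p)) is not None
            and peak_calls[id(p)].decision == "pass"
            for p, _ in cluster.members
        )
        cluster.mean_test_p = test_cluster_mean(cluster.values, others)
        if cluster.size >= 2 and len(others) >= cluster.size:
            cluster.variance_test_p = test_cluster_variance(
                cluster.values, others, n_comparisons=n_levene_comparisons, rng=rng
            )
        else:
            cluster.variance_test_p = float("nan")
        significant = (
            cluster.has_passing_termination_peak
            and cluster.mean_test_p < alpha_mean
            and cluster.variance_test_p < alpha_variance
        )
        cluster.decision = "significant" if significant else "not_significant"


def call_locus(
    locus_id: str,
    family: str,
    clusters: list[PeakCluster],
    per_condition_pass: dict[str, bool],
    any_condition_passed_depth: bool = True,
) -> LocusCall:
    """Combine cluster decisions into a per-locus verdict.

    ``per_condition_pass`` maps each analyzed condition to whether any
    passing termination peak was observed under it (the per-condition
    ON/OFF-state readout).
    """
    if not any_condition_passed_depth:
        verdict = LOW_COVERAGE
    elif not clusters:
        verdict = NO_CANDIDATE_PEAKS
    elif any(c.decision == "significant" for c in clusters):
        verdict = TERMINATION_EVIDENCE
    else:
        verdict = INCONCLUSIVE
    states = {
        cond: "termination_peak_present" if flag else "absent"
        for cond, flag in per_condition_pass.items()
    }
    return LocusCall(
        locus_id=locus_id,
        family=family,
        n_conditions_analyzed=len(per_condition_pass),
        clusters=clusters,
        verdict=verdict,
        per_condition_state=states,
    )
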