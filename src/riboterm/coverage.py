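"""Paired-end alignment ingest and fragment coverage pileups.

Reads coordinate-sorted SAM/BAM alignments against riboswitch reference
windows, filters read pairs by orientation, and accumulates five
mutually exclusive per-base coverage categories plus the signed
fragment-termini track that feeds the edge-detection convolution.

Orientation vocabulary (looking 5'->3' along the reference): the F read
is the forward-strand mate, the R read the reverse-strand mate. Valid
pairs are EQ (mates span the identical interval) and FR (left-most
aligned base shared or exclusive to the F read, right-most base
exclusive to the R read); single mapped reads are retained but only
counted when explicitly enabled. Everything else (RF, tandem mates, and
other malformed configurations) is discarded as likely artifactual.

Each sequenced fragment contributes exactly two termini: the F read's
left-most mapped base (its synthesis origin, scored -1) and the R read's
right-most mapped base (+1). Internal fragmentation produces matched
neighboring -1/+1 pairs that cancel under convolution; genuine
transcript 3' ends do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .config import PipelineConfig
from .reference import ReferenceWindow

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

# orientation labels
EQ = "EQ"
FR = "FR"
RF = "RF"
TANDEM = "TANDEM"
OTHER_INVALID = "OTHER_INVALID"
SINGLE = "SINGLE"

VALID_ORIENTATIONS = frozenset({EQ, FR, SINGLE})


@dataclass
class AlignedPair:
    """One read pair (or orphan read) mapped into a reference window."""

    locus_id: str
    f_span: Optional[Interval]
    r_span: Optional[Interval]
    orientation: str
    f_softclipped: bool = False
    r_softclipped: bool = False
    clipped_spans: list[Interval] = field(default_factory=list)

    @property
    def has_soft_clips(self) -> bool:
        return self.f_softclipped or self.r_softclipped


def classify_pair(
    span1: Optional[Interval],
    span2: Optional[Interval],
    strand1: str,
    strand2: str,
) -> str:
    """Classify a mate-pair configuration into an orientation label.

    Spans are 0-based half-open window intervals; a ``None`` span means
    that mate is unmapped. Strands are '+'/'-'.
    """
    if span1 is None and span2 is None:
        raise ValueError("both mates unmapped")
    if span1 is None or span2 is None:
        return SINGLE
    if strand1 == strand2:
        return TANDEM
    # orient: F = forward-strand mate, R = reverse-strand mate
    f = span1 if strand1 == "+" else span2
    r = span2 if strand1 == "+" else span1
    if f == r:
        return EQ
    fs, fe = f
    rs, re = r
    if fs <= rs and re > fe:
        return FR
    if rs < fs and re <= fe:
        return RF
    return OTHER_INVALID


@dataclass
class CoverageProfile:
    """Per-position coverage pileups for one locus x readset.

    The five category arrays partition each retained pair's footprint so
    that their elementwise sum (``total_coverage``) is the pair depth at
    every position.
    """

    locus_id: str
    readset_id: str
    condition_id: str
    riboswitch_start: int
    riboswitch_end: int
    read_coverage: np.ndarray
    clipped_fragment_coverage: np.ndarray
    overlapped_fragment_coverage: np.ndarray
    inferred_fragment_coverage: np.ndarray
    fragment_termini_coverage: np.ndarray
    signed_termini: np.ndarray
    n_pairs_retained: int = 0
    n_pairs_discarded: int = 0
    n_pairs_skipped_out_of_window: int = 0
    pairs: list[AlignedPair] = field(default_factory=list)

    @classmethod
    def empty(
        cls,
        locus_id: str,
        readset_id: str,
        condition_id: str,
        window_length: int,
        riboswitch_start: int,
        riboswitch_end: int,
    ) -> "CoverageProfile":
        z = lambda: np.zeros(window_length, dtype=np.int64)  # noqa: E731
        return cls(
            locus_id,
            readset_id,
            condition_id,
            riboswitch_start,
            riboswitch_end,
            z(),
            z(),
            z(),
            z(),
            z(),
            z(),
        )

    def __len__(self) -> int:
        return len(self.read_coverage)

    @property
    def total_coverage(self) -> np.ndarray:
        return (
            self.read_coverage
            + self.clipped_fragment_coverage
            + self.overlapped_fragment_coverage
            + self.inferred_fragment_coverage
            + self.fragment_termini_coverage
        )

    @property
    def mean_riboswitch_read_coverage(self) -> float:
        if self.riboswitch_end <= self.riboswitch_start:
            raise ValueError("zero-length riboswitch")
        return float(
            self.total_coverage[self.riboswitch_start : self.riboswitch_end].mean()
        )


def accumulate_pair(
    profile: CoverageProfile,
    pair: AlignedPair,
    allow_single_reads: bool = False,
    allow_soft_clips: bool = False,
) -> CoverageProfile:
    """Add one valid pair to the pileups.

    Category precedence per pair, so no base is double-counted:
    fragment termini > overlapped > read > inferred (inter-mate gap) >
    clipped. Pairs carrying soft clips contribute no termini unless
    ``allow_soft_clips``; orphan reads contribute only read/clipped
    coverage and only when ``allow_single_reads``.
    """
    if pair.orientation not in VALID_ORIENTATIONS:
        raise ValueError(f"cannot accumulate {pair.orientation} pair")
    n = len(profile)

    if pair.orientation == SINGLE:
        if not allow_single_reads:
            return profile
        span = pair.f_span if pair.f_span is not None else pair.r_span
        s, e = _clip(span, n)
        profile.read_coverage[s:e] += 1
        for cs in pair.clipped_spans:
            cs_, ce_ = _clip(cs, n)
            profile.clipped_fragment_coverage[cs_:ce_] += 1
        profile.n_pairs_retained += 1
        profile.pairs.append(pair)
        return profile

    (fs, fe), (rs, re) = pair.f_span, pair.r_span
    count_termini = allow_soft_clips or not pair.has_soft_clips
    f_term, r_term = fs, re - 1
    if count_termini and not (0 <= f_term < n and 0 <= r_term < n):
        profile.n_pairs_skipped_out_of_window += 1
        logger.debug(
            "pair with terminus outside window skipped at locus %s",
            profile.locus_id,
        )
        return profile

    covered = np.zeros(n, dtype=bool)  # bases already assigned a category
    if count_termini:
        profile.fragment_termini_coverage[f_term] += 1
        profile.signed_termini[f_term] -= 1
        profile.fragment_termini_coverage[r_term] += 1
        profile.signed_termini[r_term] += 1
        covered[f_term] = True
        covered[r_term] = True

    f_mask = np.zeros(n, dtype=bool)
    r_mask = np.zeros(n, dtype=bool)
    f_mask[slice(*_clip((fs, fe), n))] = True
    r_mask[slice(*_clip((rs, re), n))] = True

    overlap = f_mask & r_mask & ~covered
    profile.overlapped_fragment_coverage[overlap] += 1
    covered |= overlap

    single_mapped = (f_mask | r_mask) & ~covered
    profile.read_coverage[single_mapped] += 1
    covered |= single_mapped

    if fe < rs:  # unmapped bases between the mates belong to the fragment
        gap = np.zeros(n, dtype=bool)
        gap[slice(*_clip((fe, rs), n))] = True
        gap &= ~covered
        profile.inferred_fragment_coverage[gap] += 1
        covered |= gap

    if pair.clipped_spans:
        clip_mask = np.zeros(n, dtype=bool)
        for cs in pair.clipped_spans:
            clip_mask[slice(*_clip(cs, n))] = True
        clip_mask &= ~covered
        profile.clipped_fragment_coverage[clip_mask] += 1

    profile.n_pairs_retained += 1
    profile.pairs.append(pair)
    return profile


def _clip(span: Interval, n: int) -> Interval:
    s, e = span
    return max(0, s), min(n, e)


def passes_depth_filter(
    profile: CoverageProfile, min_cov_depth: float = 15.0
) -> bool:
    """True iff mean total coverage across the riboswitch meets the threshold."""
    return profile.mean_riboswitch_read_coverage >= min_cov_depth


def _read_spans_and_clips(read: pysam.AlignedSegment) -> tuple[Interval, bool, list[Interval]]:
    span = (read.reference_start, read.reference_end)
    clips: list[Interval] = []
    cig = read.cigartuples or []
    softclipped = False
    if cig and cig[0][0] == 4:
        softclipped = True
        clips.append((read.reference_start - cig[0][1], read.reference_start))
    if cig and cig[-1][0] == 4:
        softclipped = True
        clips.append((read.reference_end, read.reference_end + cig[-1][1]))
    return span, softclipped, clips


def collect_pairs(sam_path: str | Path, locus_id: str) -> tuple[list[AlignedPair], int]:
    """Collect classified pairs mapped to one reference window.

    Mates mapping to a different reference window are treated as
    unmapped here, so their partner enters as a SINGLE: windows are
    analyzed independently.

    Returns (pairs in valid orientations, number discarded as invalid).
    """
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    mode = "rb" if str(sam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(sam_path), mode, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_name != locus_id:
                continue
            by_name.setdefault(read.query_name, []).append(read)

    pairs: list[AlignedPair] = []
    n_discarded = 0
    for name in by_name:
        reads = by_name[name]
        if len(reads) == 1:
            (r,) = reads
            span, sc, clips = _read_spans_and_clips(r)
            if r.is_reverse:
                pair = AlignedPair(locus_id, None, span, SINGLE, False, sc, clips)
            else:
                pair = AlignedPair(locus_id, span, None, SINGLE, sc, False, clips)
            pairs.append(pair)
            continue
        if len(reads) > 2:
            n_discarded += 1
            continue
        r1, r2 = reads
        s1, sc1, c1 = _read_spans_and_clips(r1)
        s2, sc2, c2 = _read_spans_and_clips(r2)
        strand1 = "-" if r1.is_reverse else "+"
        strand2 = "-" if r2.is_reverse else "+"
        orientation = classify_pair(s1, s2, strand1, strand2)
        if orientation not in VALID_ORIENTATIONS:
            n_discarded += 1
            continue
        if strand1 == "+":
            f_span, r_span, f_sc, r_sc = s1, s2, sc1, sc2
        else:
            f_span, r_span, f_sc, r_sc = s2, s1, sc2, sc1
        pairs.append(
            AlignedPair(locus_id, f_span, r_span, orientation, f_sc, r_sc, c1 + c2)
        )
    return pairs, n_discarded


def build_profile(
    sam_path: str | Path,
    window: ReferenceWindow,
    readset_id: str,
    condition_id: str,
    config: PipelineConfig | None = None,
) -> CoverageProfile:
    """Parse one readset's alignments to one window into a CoverageProfile."""
    config = config or PipelineConfig()
    profile = CoverageProfile.empty(
        window.locus_id,
        readset_id,
        condition_id,
        len(window.sequence),
        window.riboswitch_start,
        window.riboswitch_end,
    )
    pairs, n_discarded = collect_pairs(sam_path, window.locus_id)
    profile.n_pairs_discarded = n_discarded
    for pair in pairs:
        accumulate_pair(
            profile,
            pair,
            allow_single_reads=config.allow_single_reads,
            allow_soft_clips=config.allow_soft_clips,
        )
    return profile
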