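"""Ground-truthed synthetic datasets for the termination-detection pipeline.

Emulates the generative process the method is built on: transcripts
start at a TSS and either terminate near the riboswitch 3' end (with a
per-condition termination efficiency) or read through to the window
end; transcripts are then fragmented so that adjacent fragments share a
breakpoint (the neighboring-termini property that the convolution
cancels), fragment lengths follow a biased (truncated lognormal)
distribution, and fragments below the size-selection cutoff are
discarded. Each retained fragment yields a proper F/R read pair written
to SAM against a random-sequence reference window, so every pipeline
stage can be tested without an aligner or external downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pysam

from .reference import ReferenceWindow, write_window_fasta, write_window_metadata

Interval = tuple[int, int]


@dataclass
class ConditionSpec:
    """Study conditions for one treatment: replicate readsets at a termination efficiency."""

    n_readsets: int = 4
    n_transcripts: int = 50
    termination_efficiency: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.termination_efficiency <= 1.0:
            raise ValueError("termination efficiency must be in [0, 1]")


@dataclass
class SimulationSpec:
    """Full description of one synthetic riboswitch locus experiment.

    Defaults place a 100-nt riboswitch at [1000, 1100) in a 2600-nt
    window with transcription starting at 500 and an intrinsic
    terminator releasing transcripts 5 nt past the riboswitch 3' end
    (relative position +0.05), jittered by a 2-nt-sd normal to mimic
    imprecision in release position and library processing.
    """

    seed: int = 0
    locus_id: str = "synthetic_locus"
    window_length: int = 2600
    riboswitch_start: int = 1000
    riboswitch_end: int = 1100
    tss_position: int = 500
    terminator_position: int = 1105
    terminator_jitter_sd: float = 2.0
    conditions: dict[str, ConditionSpec] = field(
        default_factory=lambda: {
            "A": ConditionSpec(termination_efficiency=0.9),
            "B": ConditionSpec(termination_efficiency=0.1),
        }
    )
    fragment_meanlog: float = math.log(300.0)
    fragment_sdlog: float = 0.35
    min_frag: int = 100
    max_frag: int = 1000
    read_length: int = 150

    def __post_init__(self) -> None:
        if not (self.tss_position < self.terminator_position <= self.window_length):
            raise ValueError("require tss < terminator_position <= window_length")

    @property
    def riboswitch_size(self) -> int:
        return self.riboswitch_end - self.riboswitch_start

    def reference_sequence(self) -> str:
        """Random uniform-nucleotide window sequence, fixed by the spec seed."""
        rng = np.random.default_rng([self.seed, 0xFA57A])
        return "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, self.window_length)]
        )

    def reference_window(self) -> ReferenceWindow:
        return ReferenceWindow(
            locus_id=self.locus_id,
            sequence=self.reference_sequence(),
            window_start_on_contig=0,
            riboswitch_start=self.riboswitch_start,
            riboswitch_end=self.riboswitch_end,
            riboswitch_size=self.riboswitch_size,
            was_reverse_complemented=False,
        )


@dataclass
class TruthRecord:
    """Ground truth for one simulated locus."""

    locus_id: str
    terminator_position: int
    efficiencies: dict[str, float]
    expected_verdict: str

    @staticmethod
    def from_spec(spec: SimulationSpec) -> "TruthRecord":
        effs = {
            c: cs.termination_efficiency for c, cs in spec.conditions.items()
        }
        detectable = (
            len(effs) >= 2 and max(effs.values()) - min(effs.values()) >= 0.3
        )
        return TruthRecord(
            locus_id=spec.locus_id,
            terminator_position=spec.terminator_position,
            efficiencies=effs,
            expected_verdict="termination_evidence" if detectable else "negative",
        )


def simulate_transcripts(
    spec: SimulationSpec, condition: str, rng: np.random.Generator
) -> list[Interval]:
    """Draw one readset's transcript pool for a condition.

    Each transcript starts at the TSS; with probability equal to the
    condition's termination efficiency it ends at the terminator
    position plus rounded N(0, jitter_sd) noise, otherwise it reads
    through to the window end.
    """
    cond = spec.conditions[condition]
    transcripts = []
    for _ in range(cond.n_transcripts):
        if rng.random() < cond.termination_efficiency:
            end = spec.terminator_position + int(
                round(rng.normal(0.0, spec.terminator_jitter_sd))
            )
            end = int(np.clip(end, spec.tss_position + 1, spec.window_length))
        else:
            end = spec.window_length
        transcripts.append((spec.tss_position, end))
    return transcripts


@dataclass
class SimulatedPair:
    fragment: Interval
    f_span: Interval
    r_span: Interval
    internal: bool  # both fragment ends are fragmentation breakpoints


def fragment_and_pair(
    transcripts: Iterable[Interval],
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> list[SimulatedPair]:
    """Fragment transcripts and sequence both ends of each retained fragment.

    Fragments are laid 5'->3': successive lengths are drawn from the
    truncated lognormal model, so every internal breakpoint appears once
    as one fragment's 3' end and once as the next fragment's 5' end. The
    final fragment is whatever remains of the transcript. Fragments
    shorter than ``min_frag`` are discarded (size selection). A fragment
    no longer than the read length yields an EQ pair spanning the whole
    fragment; longer fragments yield an FR pair reading in from each
    end.
    """
    pairs: list[SimulatedPair] = []
    for start, end in transcripts:
        pos = start
        while pos < end:
            length = _draw_fragment_length(spec, rng)
            frag_end = min(pos + length, end)
            internal = frag_end == pos + length and frag_end < end
            frag = (pos, frag_end)
            pos = frag_end
            if frag[1] - frag[0] < spec.min_frag:
                continue
            fs, fe = frag
            if fe - fs <= spec.read_length:
                f_span = r_span = frag
            else:
                f_span = (fs, fs + spec.read_length)
                r_span = (fe - spec.read_length, fe)
            pairs.append(SimulatedPair(frag, f_span, r_span, internal))
    return pairs


def _draw_fragment_length(spec: SimulationSpec, rng: np.random.Generator) -> int:
    while True:
        length = rng.lognormal(spec.fragment_meanlog, spec.fragment_sdlog)
        if spec.min_frag <= length <= spec.max_frag:
            return int(round(length))


def write_sam(
    pairs: Iterable[SimulatedPair],
    spec: SimulationSpec,
    readset_id: str,
    path: str | Path,
) -> None:
    """Write a coordinate-sorted SAM for one readset against the window reference."""
    ref = spec.reference_sequence()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.locus_id, "LN": spec.window_length}],
    }
    records = []
    for i, pair in enumerate(pairs):
        qname = f"{readset_id}.{i}"
        (fs, fe), (rs, re) = pair.f_span, pair.r_span
        tlen = re - fs
        records.append((fs, qname, 99, fs, fe, rs, tlen))  # F read
        records.append((rs, qname, 147, rs, re, fs, -tlen))  # R read
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for _, qname, flag, s, e, mate_pos, tlen in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = s
            a.mapping_quality = 60
            a.cigarstring = f"{e - s}M"
            a.next_reference_id = 0
            a.next_reference_start = mate_pos
            a.template_length = tlen
            a.query_sequence = ref[s:e]
            a.query_qualities = pysam.qualitystring_to_array("I" * (e - s))
            out.write(a)


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    window: ReferenceWindow
    sam_paths: dict[str, Path]  # readset_id -> SAM path
    condition_map: dict[str, str]  # readset_id -> condition_id
    truth: TruthRecord


def generate_dataset(spec: SimulationSpec, outdir: str | Path) -> SimulatedDataset:
    """Write the full fixture: window FASTA + metadata, per-readset SAMs, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    window = spec.reference_window()
    write_window_fasta([window], outdir / "windows.fasta")
    write_window_metadata([window], outdir / "windows.tsv")

    sam_paths: dict[str, Path] = {}
    condition_map: dict[str, str] = {}
    for ci, (cond, cspec) in enumerate(sorted(spec.conditions.items())):
        for r in range(cspec.n_readsets):
            readset_id = f"{cond}_r{r}"
            rng = np.random.default_rng([spec.seed, ci, r])
            transcripts = simulate_transcripts(spec, cond, rng)
            pairs = fragment_and_pair(transcripts, spec, rng)
            sam = outdir / f"{readset_id}.sam"
            write_sam(pairs, spec, readset_id, sam)
            sam_paths[readset_id] = sam
            condition_map[readset_id] = cond

    truth = TruthRecord.from_spec(spec)
    with (outdir / "truth.tsv").open("w") as fh:
        fh.write("locus_id\tterminator_position\tcondition\tefficiency\texpected_verdict\n")
        for cond, eff in sorted(truth.efficiencies.items()):
            fh.write(
                f"{truth.locus_id}\t{truth.terminator_position}\t{cond}\t"
                f"{eff}\t{truth.expected_verdict}\n"
            )
    with (outdir / "conditions.tsv").open("w") as fh:
        fh.write("readset_id\tcondition_id\n")
        for rid, cond in sorted(condition_map.items()):
            fh.write(f"{rid}\t{cond}\n")
    return SimulatedDataset(spec, window, sam_paths, condition_map, truth)
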