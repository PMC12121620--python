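"""Riboswitch locus parsing and reference-window construction.

Turns riboswitch predictions (Infernal ``cmscan`` tblout, or a plain TSV
locus table) and ORF predictions (Prodigal GFF) into oriented
riboswitch-neighborhood reference sequences ready for read mapping.

Coordinates are 0-based half-open everywhere inside this package;
conversion from the 1-based inclusive conventions of Infernal and
Prodigal happens only in the parsers here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


@dataclass
class OrfRecord:
    """A predicted open reading frame on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str
    orf_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"ORF {self.orf_id}: start must be < end")


@dataclass
class RiboswitchLocus:
    """A riboswitch hit on a source contig.

    ``source_start``/``source_end`` are 0-based half-open on the contig;
    minus-strand hits are stored with ``source_start < source_end`` and
    ``strand == '-'``.
    """

    locus_id: str
    contig_id: str
    family: str
    source_start: int
    source_end: int
    strand: str
    model_score: float = float("nan")
    e_value: float = float("nan")
    downstream_orf: Optional[OrfRecord] = None

    def __post_init__(self) -> None:
        if not self.source_start < self.source_end:
            raise ValueError(f"locus {self.locus_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.locus_id}: strand must be + or -")

    @property
    def size(self) -> int:
        return self.source_end - self.source_start

    @property
    def five_prime_end(self) -> int:
        """5' end of the riboswitch in contig coordinates (a boundary, not a base)."""
        return self.source_start if self.strand == "+" else self.source_end


@dataclass
class ReferenceWindow:
    """A riboswitch neighborhood, oriented 5'->3' with respect to the riboswitch.

    ``sequence`` reads 5'->3' along the riboswitch; windows from (-)-strand
    loci are reverse complemented. ``riboswitch_start``/``riboswitch_end``
    are 0-based half-open in window coordinates.
    """

    locus_id: str
    sequence: str
    window_start_on_contig: int
    riboswitch_start: int
    riboswitch_end: int
    riboswitch_size: int
    was_reverse_complemented: bool

    def __post_init__(self) -> None:
        if self.riboswitch_end - self.riboswitch_start != self.riboswitch_size:
            raise ValueError("riboswitch bounds inconsistent with size")
        if not (0 <= self.riboswitch_start < self.riboswitch_end <= len(self.sequence)):
            raise ValueError("riboswitch bounds outside window")

    @property
    def riboswitch_sequence(self) -> str:
        return self.sequence[self.riboswitch_start : self.riboswitch_end]


class TbloutParseError(ValueError):
    pass


def parse_cmscan_tblout(path: str | Path) -> list[RiboswitchLocus]:
    """Parse an Infernal ``cmscan --tblout`` file into riboswitch loci.

    One locus per target hit line; ``#`` comment lines are skipped. The
    tblout "seq from"/"seq to" columns are 1-based inclusive with
    from > to on the minus strand; they are converted to 0-based
    half-open with start < end.
    """
    loci: list[RiboswitchLocus] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 17:
                raise TbloutParseError(
                    f"{path}:{lineno}: expected >=17 whitespace-separated "
                    f"columns, found {len(parts)}"
                )
            try:
                family = parts[0]
                contig = parts[2]
                seq_from = int(parts[7])
                seq_to = int(parts[8])
                strand = parts[9]
                score = float(parts[14])
                e_value = float(parts[15])
            except ValueError as exc:
                raise TbloutParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise TbloutParseError(f"{path}:{lineno}: bad strand {strand!r}")
            start = min(seq_from, seq_to) - 1
            end = max(seq_from, seq_to)
            locus_id = f"{family}__{contig}__{start}{strand}"
            loci.append(
                RiboswitchLocus(
                    locus_id=locus_id,
                    contig_id=contig,
                    family=family,
                    source_start=start,
                    source_end=end,
                    strand=strand,
                    model_score=score,
                    e_value=e_value,
                )
            )
    if not loci:
        logger.warning("no riboswitch hits parsed from %s", path)
    return loci


def parse_locus_tsv(path: str | Path) -> list[RiboswitchLocus]:
    """Parse a plain TSV locus table (precomputed riboswitch coordinates).

    Columns: locus_id, contig, start, end, strand, family. Coordinates
    are 0-based half-open. A header line starting with ``locus_id`` is
    permitted and skipped.
    """
    loci = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "locus_id":
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            loci.append(
                RiboswitchLocus(
                    locus_id=parts[0],
                    contig_id=parts[1],
                    family=parts[5],
                    source_start=int(parts[2]),
                    source_end=int(parts[3]),
                    strand=parts[4],
                )
            )
    return loci


def write_locus_tsv(loci: Iterable[RiboswitchLocus], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("locus_id\tcontig\tstart\tend\tstrand\tfamily\n")
        for loc in loci:
            fh.write(
                f"{loc.locus_id}\t{loc.contig_id}\t{loc.source_start}\t"
                f"{loc.source_end}\t{loc.strand}\t{loc.family}\n"
            )


def parse_prodigal_gff(path: str | Path) -> list[OrfRecord]:
    """Parse Prodigal GFF output into ORF records (1-based inclusive -> 0-based half-open)."""
    orfs = []
    n = 0
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2] not in ("CDS", "gene"):
                continue
            n += 1
            contig = parts[0]
            start = int(parts[3]) - 1
            end = int(parts[4])
            strand = parts[6]
            orf_id = f"{contig}_orf{n}"
            if len(parts) >= 9:
                for attr in parts[8].split(";"):
                    if attr.startswith("ID="):
                        orf_id = attr[3:]
                        break
            orfs.append(OrfRecord(contig, start, end, strand, orf_id))
    return orfs


def assign_downstream_orf(
    locus: RiboswitchLocus, orfs: Iterable[OrfRecord]
) -> Optional[OrfRecord]:
    """Pick the downstream gene for a riboswitch.

    The downstream gene is the first same-strand ORF past the riboswitch
    5' end, reading in the riboswitch direction; ORFs that overlap the
    riboswitch qualify (their start may precede the riboswitch 3' end).
    Returns None when no same-strand ORF on the contig qualifies.
    """
    candidates = [
        o
        for o in orfs
        if o.contig_id == locus.contig_id and o.strand == locus.strand
    ]
    if locus.strand == "+":
        # reading direction start of an ORF is its left coordinate
        qualifying = [o for o in candidates if o.start >= locus.five_prime_end]
        return min(qualifying, key=lambda o: o.start, default=None)
    # minus strand: reading direction is right-to-left; an ORF "starts" at
    # its right coordinate, downstream means smaller coordinates
    qualifying = [o for o in candidates if o.end <= locus.five_prime_end]
    return max(qualifying, key=lambda o: o.end, default=None)


def build_reference_window(
    locus: RiboswitchLocus, contig_sequence: str, flank: int = 1000
) -> ReferenceWindow:
    """Trim a contig to the riboswitch neighborhood, oriented 5'->3'.

    The window spans ``[source_start - flank, source_end + flank)``
    clipped to contig bounds (so neighborhoods near contig ends may be
    smaller or asymmetric); (-)-strand loci are reverse complemented so
    the riboswitch reads 5'->3' in the returned sequence.
    """
    n = len(contig_sequence)
    if locus.source_end > n or locus.source_start < 0:
        raise ValueError(
            f"locus {locus.locus_id} outside contig bounds (contig length {n})"
        )
    wstart = max(0, locus.source_start - flank)
    wend = min(n, locus.source_end + flank)
    seq = contig_sequence[wstart:wend]
    if locus.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        rs = wend - locus.source_end
    else:
        rs = locus.source_start - wstart
    size = locus.size
    return ReferenceWindow(
        locus_id=locus.locus_id,
        sequence=seq,
        window_start_on_contig=wstart,
        riboswitch_start=rs,
        riboswitch_end=rs + size,
        riboswitch_size=size,
        was_reverse_complemented=locus.strand == "-",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as a dict of id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_window_fasta(windows: Iterable[ReferenceWindow], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(w.sequence), id=w.locus_id, description="")
        for w in windows
    ]
    SeqIO.write(records, str(path), "fasta")


def write_window_metadata(windows: Iterable[ReferenceWindow], path: str | Path) -> None:
    """Window metadata TSV consumed by the calling stage."""
    with Path(path).open("w") as fh:
        fh.write(
            "locus_id\twindow_start_on_contig\triboswitch_start\t"
            "riboswitch_end\twas_reverse_complemented\n"
        )
        for w in windows:
            fh.write(
                f"{w.locus_id}\t{w.window_start_on_contig}\t{w.riboswitch_start}\t"
                f"{w.riboswitch_end}\t{int(w.was_reverse_complemented)}\n"
            )


def read_window_metadata(
    fasta_path: str | Path, meta_path: str | Path
) -> list[ReferenceWindow]:
    seqs = read_fasta(fasta_path)
    windows = []
    with Path(meta_path).open() as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            lid, wstart, rs, re_, rc = line.rstrip("\n").split("\t")
            seq = seqs[lid]
            windows.append(
                ReferenceWindow(
                    locus_id=lid,
                    sequence=seq,
                    window_start_on_contig=int(wstart),
                    riboswitch_start=int(rs),
                    riboswitch_end=int(re_),
                    riboswitch_size=int(re_) - int(rs),
                    was_reverse_complemented=bool(int(rc)),
                )
            )
    return windows
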