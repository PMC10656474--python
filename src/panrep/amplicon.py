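"""Paired-read merging and scaffold-anchored VHH annotation.

Reconstructs full-length VHH (single-domain antibody) coding sequences from
overlapping paired amplicon reads and annotates the framework (FR1-FR4) and
complementarity-determining (CDR1-3) regions against a fixed VHH scaffold
consensus.  The annotator replaces a germline-database aligner: it assumes a
single framework scaffold with variable-length CDR loops, which is exactly
the structure of a synthetic or single-framework immune library.  Real
repertoires with framework diversity would re-insert a germline aligner
(e.g. MiXCR/IgBLAST) at this stage; everything downstream is unchanged.

All amino-acid coordinates are 0-based half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "Read",
    "MergedAmplicon",
    "VhhRecord",
    "Scaffold",
    "DEFAULT_SCAFFOLD",
    "FLANK_5P",
    "FLANK_3P",
    "REGION_ORDER",
    "revcomp",
    "translate",
    "merge_read_pair",
    "length_filter",
    "quality_filter",
    "extract_cds",
    "annotate_vhh",
    "drop_partials",
]

# ---------------------------------------------------------------------------
# Scaffold and amplicon constants
# ---------------------------------------------------------------------------

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


@dataclass(frozen=True)
class Scaffold:
    """VHH framework consensus with the four structural anchors.

    The framework segments carry the canonical anchors used to validate a
    reconstruction: the conserved cysteine terminating FR1, the conserved
    tryptophan opening FR2, the conserved cysteine terminating FR3 and the
    J-segment [WF]-G-x-G motif opening FR4.
    """

    fr1: str = "QVQLVESGGGLVQAGGSLRLSC"
    fr2: str = "WFRQAPGKEREFVA"
    fr3: str = "DSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYC"
    fr4: str = "WGQGTQVTVSS"
    # search windows for CDR lengths (aa), deliberately wider than any
    # library design so the annotator does not presuppose the generator
    cdr1_window: tuple[int, int] = (1, 20)
    cdr2_window: tuple[int, int] = (1, 20)
    cdr3_window: tuple[int, int] = (1, 40)

    def __post_init__(self) -> None:
        assert self.fr1.endswith("C") and self.fr3.endswith("C")
        assert self.fr2.startswith("W")
        assert self.fr4[0] in "WF" and self.fr4[1] == "G" and self.fr4[3] == "G"

    @property
    def framework_length(self) -> int:
        return len(self.fr1) + len(self.fr2) + len(self.fr3) + len(self.fr4)


DEFAULT_SCAFFOLD = Scaffold()

# Constant amplicon flanks (vector sequence + PCR primers).  Sized so that a
# coding sequence of 82 framework aa plus CDRs up to 8+9+36 aa gives an
# amplicon of at most 175 + 3*135 = 580 nt, i.e. always overlap-mergeable
# from 2x300 nt reads with a 20 nt minimum overlap.
FLANK_5P = (
    "ATGCCCACTGCTATCCGGTAACGGACGAGGCCTGGTACCTAGGTTTTCA"
    "TAGAAACTCAACACTTCCTCTCAGCAAGGCTTACTACCATG"
)
FLANK_3P = (
    "TTAGTCGGGTGACTCAGGAAGCCCTGCGAACAGTGGCTAAAGATTGTTA"
    "CGTCCCAGAAATGACCGCTGACTCAGAAGACCGACC"
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate in frame 0 with the standard code; trailing partial codon
    dropped; any codon containing an ambiguous base yields 'X'."""
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE = _build_codon_table()
    tbl = _CODON_TABLE
    return "".join(
        tbl.get(nt[i : i + 3].upper(), "X") for i in range(0, len(nt) - len(nt) % 3, 3)
    )


# ---------------------------------------------------------------------------
# Read merging
# ---------------------------------------------------------------------------


class Read(NamedTuple):
    """One sequencing read: identifier, bases and Phred qualities (ASCII-33)."""

    id: str
    seq: str
    qual: str


@dataclass
class MergedAmplicon:
    """Consensus amplicon reconstructed from one read pair."""

    sequence: str
    qualities: bytes  # Phred scores (not ASCII-offset)
    merge_overlap_length: int
    mean_quality: float
    read_id: str

    def __len__(self) -> int:
        return len(self.sequence)


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33


def merge_read_pair(
    read1: Read,
    read2: Read,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.05,
) -> Optional[MergedAmplicon]:
    """Overlap-merge a read pair into a consensus amplicon.

    Read 2 is reverse-complemented; among all alignments with overlap >=
    ``min_overlap`` the one with the lowest mismatch rate is taken (ties
    prefer the longer overlap).  The merge is accepted when that rate is at
    most ``max_mismatch_rate``.  Disagreeing bases inside the overlap are
    resolved by the higher Phred quality, ties going to read 1.  Returns
    ``None`` when no acceptable overlap exists.
    """
    if not read1.seq or not read2.seq:
        raise ValueError("empty read")
    s1 = read1.seq
    s2 = revcomp(read2.seq)
    q1 = _phred(read1.qual)
    q2 = _phred(read2.qual)[::-1]
    n1, n2 = len(s1), len(s2)
    max_ov = min(n1, n2)
    if min_overlap < 1 or min_overlap > max_ov:
        return None

    a1 = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode("ascii"), dtype=np.uint8)

    def rate_at(t: int) -> tuple[float, int, int]:
        ov = min(n1 - t, n2)
        mm = int(np.count_nonzero(a1[t : t + ov] != a2[:ov]))
        return mm / ov, mm, ov

    # Fast path: seed k-mers from the start of the reverse-complemented read 2
    # located exactly in read 1.  Falls back to an exhaustive offset scan.
    k = min(min_overlap, 16)
    candidates: set[int] = set()
    for off in range(0, min(n2 - k + 1, 4 * k), k):
        seed = s2[off : off + k]
        p = s1.find(seed)
        while p != -1:
            t = p - off
            if 0 <= t <= n1 - min_overlap:
                candidates.add(t)
            p = s1.find(seed, p + 1)

    best: Optional[tuple[float, int, int, int]] = None  # rate, t, mm, ov
    for t in sorted(candidates):
        r, mm, ov = rate_at(t)
        if best is None or r < best[0] or (r == best[0] and t < best[1]):
            best = (r, t, mm, ov)
    if best is None or best[0] > max_mismatch_rate:
        for t in range(max(0, n1 - n2), n1 - min_overlap + 1):
            r, mm, ov = rate_at(t)
            if best is None or r < best[0] or (r == best[0] and t < best[1]):
                best = (r, t, mm, ov)
    if best is None or best[0] > max_mismatch_rate:
        return None

    _, t, mm, ov = best
    # tail: rest of read 2 past the overlap, or of read 1 when it contains read 2
    tail_s = a2[ov:].tobytes() if ov < n2 else a1[t + ov :].tobytes()
    tail_q = q2[ov:] if ov < n2 else q1[t + ov :]
    cons = bytearray(a1[:t].tobytes() + a1[t : t + ov].tobytes() + tail_s)
    qual = np.concatenate([q1[:t], np.maximum(q1[t : t + ov], q2[:ov]), tail_q])
    if mm:
        sl1, sl2 = a1[t : t + ov], a2[:ov]
        for i in np.nonzero(sl1 != sl2)[0]:
            if q2[i] > q1[t + i]:
                cons[t + i] = sl2[i]
    return MergedAmplicon(
        sequence=cons.decode("ascii"),
        qualities=bytes(int(q) for q in qual),
        merge_overlap_length=ov,
        mean_quality=float(qual.mean()),
        read_id=read1.id,
    )


def length_filter(
    amplicons: Iterable[MergedAmplicon], min_len: int = 550, max_len: int = 850
) -> list[MergedAmplicon]:
    """Keep amplicons within the gel-cut band [min_len, max_len], inclusive."""
    return [a for a in amplicons if min_len <= len(a) <= max_len]


def quality_filter(
    amplicons: Iterable[MergedAmplicon], min_mean_q: float = 20.0
) -> list[MergedAmplicon]:
    """Drop amplicons whose mean Phred quality falls below ``min_mean_q``."""
    return [a for a in amplicons if a.mean_quality >= min_mean_q]


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_cds(
    amplicon: MergedAmplicon | str,
    primer5: str = FLANK_5P,
    primer3: str = FLANK_3P,
    max_primer_mismatches: int = 2,
    search_slack: int = 8,
) -> Optional[str]:
    """Strip the constant flanks and return the enclosed coding sequence.

    Each flank is located within ``search_slack`` positions of its end of the
    amplicon, tolerating up to ``max_primer_mismatches`` substitutions; the
    reading frame is anchored at the first base after the 5' flank.  Returns
    ``None`` when either flank cannot be located.
    """
    seq = amplicon.sequence if isinstance(amplicon, MergedAmplicon) else amplicon
    L5, L3 = len(primer5), len(primer3)
    if len(seq) < L5 + L3 + 3:
        return None

    best5: Optional[tuple[int, int]] = None  # (mismatches, pos)
    for p in range(0, min(search_slack, len(seq) - L5) + 1):
        mm = _hamming(seq[p : p + L5], primer5)
        if mm <= max_primer_mismatches and (best5 is None or mm < best5[0]):
            best5 = (mm, p)
            if mm == 0:
                break
    if best5 is None:
        return None

    best3: Optional[tuple[int, int]] = None
    lo = max(best5[1] + L5, len(seq) - L3 - search_slack)
    for p in range(len(seq) - L3, lo - 1, -1):
        mm = _hamming(seq[p : p + L3], primer3)
        if mm <= max_primer_mismatches and (best3 is None or mm < best3[0]):
            best3 = (mm, p)
            if mm == 0:
                break
    if best3 is None:
        return None

    cds = seq[best5[1] + L5 : best3[1]]
    return cds if len(cds) >= 3 else None


# ---------------------------------------------------------------------------
# Scaffold-anchored annotation
# ---------------------------------------------------------------------------


@dataclass
class VhhRecord:
    """A reconstructed VHH with FR/CDR boundaries on the amino-acid sequence.

    ``regions`` maps region name to a 0-based half-open interval; complete
    records tile [FR1 start, FR4 end) contiguously in scaffold order.
    """

    nt_cds: str
    aa_sequence: str
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    anchor_matches: dict[str, bool] = field(default_factory=dict)
    complete: bool = False
    read_id: str = ""

    def region_aa(self, name: str) -> str:
        s, e = self.regions[name]
        return self.aa_sequence[s:e]

    def region_nt(self, name: str) -> str:
        s, e = self.regions[name]
        return self.nt_cds[3 * s : 3 * e]

    @property
    def cdr1_aa(self) -> str:
        return self.region_aa("CDR1")

    @property
    def cdr2_aa(self) -> str:
        return self.region_aa("CDR2")

    @property
    def cdr3_aa(self) -> str:
        return self.region_aa("CDR3")

    @property
    def full_aa(self) -> str:
        """Amino acids spanning FR1 start to FR4 end."""
        return self.aa_sequence[self.regions["FR1"][0] : self.regions["FR4"][1]]


def _find_segment(
    aa: str, segment: str, lo: int, hi: int, max_mismatch: int
) -> Optional[int]:
    """Best start position of ``segment`` in ``aa`` within [lo, hi]."""
    m = len(segment)
    p = aa.find(segment, lo, hi + m)
    if p != -1 and p <= hi:
        return p
    best: Optional[tuple[int, int]] = None
    for p in range(lo, min(hi, len(aa) - m) + 1):
        mm = _hamming(aa[p : p + m], segment)
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, p)
    return None if best is None else best[1]


def annotate_vhh(
    nt_cds: str,
    scaffold: Scaffold = DEFAULT_SCAFFOLD,
    max_fr_mismatches: int = 3,
    read_id: str = "",
) -> VhhRecord:
    """Annotate a coding sequence against the scaffold consensus.

    The sequence is translated in the anchored frame and the three internal
    framework segments are located by mismatch-tolerant search inside the
    CDR-length windows, transferring FR/CDR boundaries from scaffold
    coordinates.  A record is complete iff all four anchors (FR1 cysteine,
    FR2 tryptophan, FR3 cysteine, FR4 [WF]GxG) match, there is no internal
    stop codon, no ambiguous residue falls inside a CDR, and the CDR3 length
    is within 1-36 aa.
    """
    if len(nt_cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    aa = translate(nt_cds)
    rec = VhhRecord(nt_cds=nt_cds, aa_sequence=aa, read_id=read_id)
    n1 = len(scaffold.fr1)

    anchors = {"FR1_cys": False, "FR2_trp": False, "FR3_cys": False, "FR4_jmotif": False}
    rec.anchor_matches = anchors
    if len(aa) < scaffold.framework_length + 3:
        return rec

    anchors["FR1_cys"] = aa[n1 - 1] == "C"

    lo, hi = scaffold.cdr1_window
    p2 = _find_segment(aa, scaffold.fr2, n1 + lo, n1 + hi, max_fr_mismatches)
    if p2 is None:
        return rec
    e2 = p2 + len(scaffold.fr2)
    anchors["FR2_trp"] = aa[p2] == "W"

    lo, hi = scaffold.cdr2_window
    p3 = _find_segment(aa, scaffold.fr3, e2 + lo, e2 + hi, max_fr_mismatches)
    if p3 is None:
        return rec
    e3 = p3 + len(scaffold.fr3)
    anchors["FR3_cys"] = aa[e3 - 1] == "C"

    lo, hi = scaffold.cdr3_window
    p4 = _find_segment(aa, scaffold.fr4, e3 + lo, e3 + hi, max_fr_mismatches)
    if p4 is None:
        return rec
    e4 = p4 + len(scaffold.fr4)
    anchors["FR4_jmotif"] = (
        aa[p4] in "WF" and aa[p4 + 1] == "G" and len(aa) > p4 + 3 and aa[p4 + 3] == "G"
    )

    rec.regions = {
        "FR1": (0, n1),
        "CDR1": (n1, p2),
        "FR2": (p2, e2),
        "CDR2": (e2, p3),
        "FR3": (p3, e3),
        "CDR3": (e3, p4),
        "FR4": (p4, e4),
    }
    body = aa[:e4]
    cdr3_len = p4 - e3
    rec.complete = (
        all(anchors.values())
        and "*" not in body
        and 1 <= cdr3_len <= 36
        and not any("X" in rec.region_aa(r) for r in ("CDR1", "CDR2", "CDR3"))
    )
    return rec


def drop_partials(records: Iterable[VhhRecord]) -> list[VhhRecord]:
    """Retain only fully reconstructed records (``complete=True``)."""
    return [r for r in records if r.complete]
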