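"""IUPAC consensus motif scanning over promoter windows.

Promoters default to the 3 kb window upstream of the translation start
(ATG anchor); scanning matches an IUPAC consensus with a mismatch budget
on both strands.  The canonical Stat3 site (SIE, ``TTCCNGGAA``) is
reverse-complement palindromic, so plus- and minus-strand hits coincide
and are collapsed rather than double-counted.

Coordinates are 0-based half-open internally; human-readable outputs use
1-based inclusive positions and say so in their headers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("oxpattern")

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_SEQ_CODE = np.full(256, 4, dtype=np.uint8)  # 4 = anything non-ACGT (incl. N)
for _i, _b in enumerate("ACGT"):
    _SEQ_CODE[ord(_b)] = _i
    _SEQ_CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity classes."""
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifConsensus:
    """A named IUPAC consensus with a mismatch budget."""

    name: str
    pattern: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        bad = set(self.pattern.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC letter(s) {sorted(bad)} in {self.pattern!r}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.pattern.upper()) == self.pattern.upper()


#: Default consensus set.  SIE is the canonical Stat3 site; HRE (Hif-1a),
#: TRE (AP-1/cJun) and ARE (Nrf2) are the standard oxidative-stress response
#: elements.  The 2-mismatch budget applies to SIE and ARE; HRE and TRE are
#: exact by default.  All are configuration, not constants of the method.
DEFAULT_MOTIFS: tuple[MotifConsensus, ...] = (
    MotifConsensus("SIE", "TTCCNGGAA", max_mismatch=2),
    MotifConsensus("HRE", "RCGTG", max_mismatch=0),
    MotifConsensus("TRE", "TGACTCA", max_mismatch=0),
    MotifConsensus("ARE", "TGACNNNGC", max_mismatch=2),
)


@dataclass(frozen=True)
class PromoterRegion:
    """A promoter window on the genome, read 5'->3' toward the anchor."""

    gene_id: str
    contig: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    anchor: str = "ATG"
    window_length: int = 3000

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.end - self.start > self.window_length:
            raise ValueError("interval longer than window_length")


@dataclass(frozen=True)
class MotifHit:
    """One consensus match inside a promoter window.

    *offset* is 0-based from the window's 5' end on the gene's coding
    orientation; *strand* is relative to the window.
    """

    gene_id: str
    motif: str
    offset: int
    strand: str
    mismatches: int
    matched: str = ""


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _mismatch_profile(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count at every window offset for one oriented pattern.

    ``codes`` is the uint8-encoded sequence (A,C,G,T -> 0..3, other -> 4).
    A position mismatches when the sequence base is outside the pattern
    letter's IUPAC class; non-ACGT sequence bases (N) never match.
    """
    L = len(pattern)
    n_off = len(codes) - L + 1
    if n_off <= 0:
        return np.zeros(0, dtype=np.int32)
    mism = np.zeros(n_off, dtype=np.int32)
    for j, ch in enumerate(pattern.upper()):
        allowed = IUPAC_SETS[ch]
        table = np.ones(5, dtype=bool)  # True = mismatch
        for b in allowed:
            table["ACGT".index(b)] = False
        mism += table[codes[j : j + n_off]]
    return mism


def scan_sequence(
    sequence: str,
    motif: MotifConsensus,
    strands: str = "both",
    gene_id: str = "",
) -> list[MotifHit]:
    """All matches of *motif* in *sequence* within the mismatch budget.

    With ``strands="both"`` the reverse complement of the pattern is also
    scanned against the forward sequence (offsets stay window-relative).
    For reverse-complement-palindromic patterns the two strands produce
    identical hit sets, which would double-count: only the plus strand is
    reported.
    """
    if strands not in ("both", "+", "-"):
        raise ValueError("strands must be 'both', '+' or '-'")
    codes = _SEQ_CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    todo: list[tuple[str, str]] = []
    if strands in ("both", "+"):
        todo.append(("+", motif.pattern))
    if strands in ("both", "-") and not (strands == "both" and motif.is_palindromic):
        todo.append(("-", revcomp(motif.pattern)))
    hits: list[MotifHit] = []
    L = len(motif.pattern)
    for strand, pat in todo:
        mism = _mismatch_profile(codes, pat)
        for off in np.flatnonzero(mism <= motif.max_mismatch):
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    motif=motif.name,
                    offset=int(off),
                    strand=strand,
                    mismatches=int(mism[off]),
                    matched=sequence[off : off + L].upper(),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    sequences: Mapping[str, str],
    motifs: Sequence[MotifConsensus] = DEFAULT_MOTIFS,
    strands: str = "both",
) -> pd.DataFrame:
    """Scan every promoter with every motif; tidy hit table."""
    rows = []
    for gene_id, seq in sequences.items():
        for motif in motifs:
            for h in scan_sequence(seq, motif, strands=strands, gene_id=gene_id):
                rows.append(
                    {
                        "gene_id": h.gene_id,
                        "motif": h.motif,
                        "offset": h.offset,
                        "offset_1based": h.offset + 1,
                        "strand": h.strand,
                        "mismatches": h.mismatches,
                        "matched_sequence": h.matched,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "motif", "offset", "offset_1based",
            "strand", "mismatches", "matched_sequence",
        ],
    )


def genes_with_motif(
    hits: pd.DataFrame, gene_set: Iterable[str], motif: str | None = None
) -> tuple[int, int, pd.DataFrame]:
    """Count genes in *gene_set* with at least one hit (optionally one motif).

    Returns ``(k, n, per_gene)`` — read as "k/n genes carry the site";
    multiplicity within a gene does not matter.
    """
    genes = list(dict.fromkeys(gene_set))
    sub = hits if motif is None else hits[hits["motif"] == motif]
    have = set(sub["gene_id"]) & set(genes)
    per_gene = pd.DataFrame(
        {
            "gene_id": genes,
            "n_hits": [int((sub["gene_id"] == g).sum()) for g in genes],
            "has_motif": [g in have for g in genes],
        }
    )
    return len(have), len(genes), per_gene


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

def extract_promoters(
    anchors: pd.DataFrame,
    genome,
    window_length: int = 3000,
) -> tuple[list[PromoterRegion], dict[str, str]]:
    """Cut upstream windows from the genome at per-gene anchor points.

    *anchors* has columns ``gene_id, contig, position, strand, anchor``
    with *position* the 0-based coordinate of the anchor base (the A of
    ATG, or the TSS).  *genome* is a mapping from contig name to sequence
    (a :class:`pyfaidx.Fasta` works directly).  For a plus-strand gene the
    window is ``[position - window_length, position)``; for a minus-strand
    gene ``[position + 1, position + 1 + window_length)`` reverse-
    complemented, so every returned sequence reads 5'->3' toward the
    anchor.  Windows are clipped at contig boundaries; genes on unknown
    contigs are skipped with a warning.
    """
    regions: list[PromoterRegion] = []
    seqs: dict[str, str] = {}
    for row in anchors.itertuples(index=False):
        contig = str(row.contig)
        try:
            contig_seq = genome[contig]
        except KeyError:
            warnings.warn(f"gene {row.gene_id}: contig {contig!r} not in genome; skipped",
                          stacklevel=2)
            continue
        clen = len(contig_seq)
        a = int(row.position)
        anchor = getattr(row, "anchor", "ATG")
        if row.strand == "+":
            start, end = max(0, a - window_length), min(a, clen)
        else:
            start, end = max(0, a + 1), min(a + 1 + window_length, clen)
        if end <= start:
            warnings.warn(f"gene {row.gene_id}: empty promoter window; skipped",
                          stacklevel=2)
            continue
        seq = str(contig_seq[start:end]).upper()
        if row.strand == "-":
            seq = revcomp(seq)
        regions.append(
            PromoterRegion(
                gene_id=str(row.gene_id), contig=contig, start=start, end=end,
                strand=str(row.strand), anchor=str(anchor),
                window_length=window_length,
            )
        )
        seqs[str(row.gene_id)] = seq
    return regions, seqs
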