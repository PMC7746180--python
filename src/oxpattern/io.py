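"""Read/write adapters for the standard formats the pipeline touches.

Counts and metadata as TSV, promoters as FASTA (pyfaidx-compatible),
annotation as GFF3 (parsed with gffutils) or BED6 anchors, peaks as
BED3-plus-name-plus-two-depth-columns TSV, planted truth as JSON.  Every
written table carries a comment header naming its coordinate convention;
malformed input lines are reported with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .de import CountMatrix
from .peaks import PEAK_COLUMNS, GeneModel


class FormatError(ValueError):
    """A malformed input file; message carries path and line number."""


# ---------------------------------------------------------------------------
# counts + metadata
# ---------------------------------------------------------------------------

def write_counts(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.samples.to_csv(metadata_path, sep="\t", index_label="sample")


def read_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{counts_path}: not a gene_id-indexed TSV ({exc})") from exc
    try:
        samples = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{metadata_path}: not a sample-indexed TSV ({exc})") from exc
    return CountMatrix(counts, samples)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            elif line:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: sequence before header")
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

_PEAK_HEADER = (
    "# peaks: BED-style 0-based half-open intervals; "
    "columns contig, start, end, name, sample_depth, control_depth\n"
)


def write_peaks(peaks: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_PEAK_HEADER)
        peaks[PEAK_COLUMNS].to_csv(fh, sep="\t", index=False, header=False)


def read_peaks(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                rows.append(
                    {
                        "contig": parts[0],
                        "start": int(parts[1]),
                        "end": int(parts[2]),
                        "name": parts[3],
                        "sample_depth": float(parts[4]),
                        "control_depth": float(parts[5]),
                    }
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if rows[-1]["end"] <= rows[-1]["start"]:
                raise FormatError(f"{path}:{lineno}: end must exceed start")
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


# ---------------------------------------------------------------------------
# annotation: GFF3 / BED anchors and gene models
# ---------------------------------------------------------------------------

def _gff_db(path: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )


def anchors_from_gff3(path: str | Path, anchor: str = "ATG") -> pd.DataFrame:
    """Per-gene anchor points from GFF3.

    ``anchor="ATG"`` takes the translation start from CDS features
    (5'-most CDS base in coding orientation); ``anchor="TSS"`` takes the
    transcript/gene start.  GFF3 is 1-based inclusive; returned positions
    are 0-based coordinates of the anchor base.
    """
    if anchor not in ("ATG", "TSS"):
        raise ValueError("anchor must be 'ATG' or 'TSS'")
    db = _gff_db(path)
    rows = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        if anchor == "ATG":
            cds = list(db.children(gene, featuretype="CDS"))
            if not cds:
                continue
            if gene.strand == "+":
                pos = min(c.start for c in cds) - 1
            else:
                pos = max(c.end for c in cds) - 1
        else:
            pos = gene.start - 1 if gene.strand == "+" else gene.end - 1
        rows.append(
            {"gene_id": gene_id, "contig": gene.seqid, "position": pos,
             "strand": gene.strand, "anchor": anchor}
        )
    return pd.DataFrame(rows, columns=["gene_id", "contig", "position", "strand", "anchor"])


def anchors_from_bed(path: str | Path, anchor: str = "ATG") -> pd.DataFrame:
    """Anchor points from a BED6 file (0-based half-open intervals).

    The anchor base is the interval's 5' end in coding orientation:
    ``start`` for plus-strand records, ``end - 1`` for minus-strand.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            strand = parts[5]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            rows.append(
                {"gene_id": parts[3], "contig": parts[0],
                 "position": start if strand == "+" else end - 1,
                 "strand": strand, "anchor": anchor}
            )
    return pd.DataFrame(rows, columns=["gene_id", "contig", "position", "strand", "anchor"])


def gene_models_from_gff3(path: str | Path) -> list[GeneModel]:
    """Gene models (TSS + exons) from GFF3 for peak annotation."""
    db = _gff_db(path)
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        tss = exons[0][0] if gene.strand == "+" else exons[-1][1] - 1
        models.append(
            GeneModel(gene_id=gene.id, contig=gene.seqid, strand=gene.strand,
                      tss=tss, exons=tuple(exons))
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene + exon + CDS rows).

    The CDS is written identical to the exon span — sufficient for anchor
    extraction on synthetic annotations.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            s, e = gm.span
            fh.write(
                f"{gm.contig}\toxpattern\tgene\t{s+1}\t{e}\t.\t{gm.strand}\t.\tID={gm.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(gm.exons):
                fh.write(
                    f"{gm.contig}\toxpattern\texon\t{xs+1}\t{xe}\t.\t{gm.strand}\t.\t"
                    f"ID={gm.gene_id}.e{i};Parent={gm.gene_id}\n"
                )
                fh.write(
                    f"{gm.contig}\toxpattern\tCDS\t{xs+1}\t{xe}\t.\t{gm.strand}\t0\t"
                    f"ID={gm.gene_id}.c{i};Parent={gm.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# tables and truth
# ---------------------------------------------------------------------------

def write_de_table(table: pd.DataFrame, path: str | Path, comparison: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# differential expression{': ' + comparison if comparison else ''}; "
                 "logfc = log2(group_b / group_a)\n")
        table.to_csv(fh, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", comment="#")
    return t.set_index("gene_id", drop=False)


def write_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
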