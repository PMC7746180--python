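import numpy as np
import pandas as pd
import pytest

from oxpattern import CountMatrix, GeneModel


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 genes x 8 samples (2x2 design, 2 replicates), hand-set counts."""
    samples = pd.DataFrame(
        {
            "genotype": ["WT"] * 4 + ["C3S"] * 4,
            "treatment": ["basal", "basal", "oxidation", "oxidation"] * 2,
            "replicate": [1, 2, 1, 2] * 2,
        },
        index=pd.Index(
            [f"{g}_{t}_r{r}" for g, t, r in zip(
                ["WT"] * 4 + ["C3S"] * 4,
                ["basal", "basal", "oxidation", "oxidation"] * 2,
                [1, 2, 1, 2] * 2,
            )],
            name="sample",
        ),
    )
    counts = pd.DataFrame(
        [
            [100, 110, 800, 780, 95, 105, 98, 102],   # up in WT-ox only
            [50, 55, 48, 52, 49, 51, 50, 54],          # flat
            [9, 9, 9, 9, 9, 9, 10, 10],                # borderline filter
            [0, 0, 0, 0, 0, 0, 0, 0],                  # silent
        ],
        index=pd.Index(["g_up", "g_flat", "g_edge", "g_zero"], name="gene_id"),
        columns=samples.index,
    )
    return CountMatrix(counts, samples)


@pytest.fixture
def three_gene_models() -> list[GeneModel]:
    """Hand-constructed models on one contig: plus, minus, two-exon plus."""
    return [
        GeneModel("gA", "chr1", "+", tss=100_000,
                  exons=((100_000, 100_500), (101_000, 101_400))),
        GeneModel("gB", "chr1", "-", tss=200_999,
                  exons=((200_000, 201_000),)),
        GeneModel("gC", "chr1", "+", tss=300_000, exons=((300_000, 300_200),)),
    ]


def brute_force_scan(sequence: str, pattern: str, max_mismatch: int,
                     strands: str = "both") -> set[tuple[int, str, int]]:
    """Position-by-position IUPAC scan oracle: {(offset, strand, mismatches)}.

    Independent of the package scanner: pure-Python set membership per
    character.  Palindromic patterns scanned on both strands collapse to
    the plus strand, mirroring the documented no-double-count convention.
    """
    from oxpattern.motifs import IUPAC_SETS, revcomp

    seq = sequence.upper()
    out: set[tuple[int, str, int]] = set()
    oriented = []
    if strands in ("both", "+"):
        oriented.append(("+", pattern.upper()))
    pal = revcomp(pattern.upper()) == pattern.upper()
    if strands in ("both", "-") and not (strands == "both" and pal):
        oriented.append(("-", revcomp(pattern.upper())))
    for strand, pat in oriented:
        L = len(pat)
        for off in range(len(seq) - L + 1):
            mm = 0
            for a, b in zip(seq[off : off + L], pat):
                if a not in IUPAC_SETS.get(b, frozenset()):
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                out.add((off, strand, mm))
    return out
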