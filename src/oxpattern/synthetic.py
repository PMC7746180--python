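"""Synthetic data with planted truth for every pipeline stage.

Three generators emulate the study's data types so each downstream stage
has an oracle: negative-binomial count matrices for the 2 genotype x
2 treatment x 2 replicate design with planted four-position regulation
codes; promoter windows with planted IUPAC consensus instances; and ChIP
peak tables with planted fold-enrichment over an IgG-style control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .de import CountMatrix
from .patterns import PatternCode, code_to_str

CONDITIONS = (("WT", "basal"), ("WT", "oxidation"), ("C3S", "basal"), ("C3S", "oxidation"))

_BASES = np.array(list("ACGT"))
_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class UnrealisablePatternError(ValueError):
    """A four-position code with no consistent set of condition means."""

    def __init__(self, code: PatternCode):
        super().__init__(
            f"pattern code {code_to_str(code)} is unrealisable: positions 1, 2 "
            "and 4 fix the four condition means from the WT-basal anchor, and "
            "position 3 contradicts them"
        )
        self.code = code


@dataclass
class SimulationDesign:
    """Parameters of the count simulation.

    ``dispersion`` is the NB ``alpha`` with ``var = mu + alpha * mu**2``;
    ``effect_logfc`` is the magnitude of every planted log2 fold change;
    ``pattern_spec`` maps a code to the fraction of genes planted with it,
    remaining genes carry (0,0,0,0).  ``size_factor_range`` perturbs
    per-sample library sizes to exercise normalisation.
    """

    n_genes: int
    replicates_per_condition: int = 2
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    effect_logfc: float = 3.0
    pattern_spec: Mapping[PatternCode, float] = field(default_factory=dict)
    seed: int = 0
    size_factor_range: tuple[float, float] | None = (0.7, 1.3)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.replicates_per_condition <= 0:
            raise ValueError("n_genes and replicates_per_condition must be positive")
        if self.baseline_mean <= 0 or self.dispersion < 0 or self.effect_logfc < 0:
            raise ValueError("baseline_mean > 0, dispersion >= 0, effect_logfc >= 0 required")
        total = sum(self.pattern_spec.values())
        if total > 1 + 1e-12:
            raise ValueError("pattern_spec fractions must sum to <= 1")
        for code in self.pattern_spec:
            condition_log2_means(code, self.effect_logfc, self.baseline_mean)


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: exactly one record per gene/peak."""

    codes: dict[str, PatternCode] = field(default_factory=dict)
    motifs: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    enriched: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "codes": {g: list(c) for g, c in self.codes.items()},
            "motifs": self.motifs,
            "enriched": self.enriched,
        }


def condition_log2_means(
    code: PatternCode, effect_logfc: float, baseline_mean: float, tol: float = 1e-9
) -> dict[tuple[str, str], float]:
    """Derive log2 condition means for a code from the WT-basal anchor.

    Positions 1, 2 and 4 set WT-oxidation, C3S-basal and C3S-oxidation from
    the anchor; position 3 must then be consistent (checked in log space to
    *tol*), otherwise the code is rejected.  A code is realisable with a
    single effect magnitude iff ``c1 + c4 == c2 + c3``.
    """
    c1, c2, c3, c4 = code
    if any(c not in (-1, 0, 1) for c in code):
        raise ValueError(f"code entries must be in {{-1,0,1}}: {code}")
    wb = float(np.log2(baseline_mean))
    wo = wb + effect_logfc * c1
    cb = wb + effect_logfc * c2
    co = wo + effect_logfc * c4
    if abs((co - cb) - effect_logfc * c3) > tol:
        raise UnrealisablePatternError(tuple(code))
    return {
        ("WT", "basal"): wb,
        ("WT", "oxidation"): wo,
        ("C3S", "basal"): cb,
        ("C3S", "oxidation"): co,
    }


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) samples with var = mu + alpha mu^2; alpha=0 is Poisson."""
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(design: SimulationDesign) -> tuple[CountMatrix, PlantedTruth]:
    """Simulate the 2x2xR count matrix with planted pattern codes.

    Gene-to-code assignment, library-size factors and NB draws all come
    from one seeded generator, so identical designs give identical output.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    # deterministic block sizes, randomised gene assignment
    codes = list(design.pattern_spec)
    counts_per_code = [int(round(design.pattern_spec[c] * n)) for c in codes]
    order = rng.permutation(n)
    truth = PlantedTruth()
    gene_code: dict[int, PatternCode] = {}
    pos = 0
    for code, k in zip(codes, counts_per_code):
        for idx in order[pos : pos + k]:
            gene_code[idx] = tuple(code)
        pos += k
    null_code = (0, 0, 0, 0)
    for i, g in enumerate(gene_ids):
        truth.codes[g] = gene_code.get(i, null_code)

    # per-gene per-condition means
    log2_means = np.empty((n, len(CONDITIONS)))
    cache: dict[PatternCode, list[float]] = {}
    for i, g in enumerate(gene_ids):
        code = truth.codes[g]
        if code not in cache:
            m = condition_log2_means(code, design.effect_logfc, design.baseline_mean)
            cache[code] = [m[c] for c in CONDITIONS]
        log2_means[i] = cache[code]
    means = 2.0 ** log2_means

    reps = design.replicates_per_condition
    sample_names = [
        f"{g}_{t}_r{r+1}" for (g, t) in CONDITIONS for r in range(reps)
    ]
    n_samples = len(sample_names)
    if design.size_factor_range is not None:
        lo, hi = design.size_factor_range
        sfs = rng.uniform(lo, hi, size=n_samples)
    else:
        sfs = np.ones(n_samples)

    mat = np.empty((n, n_samples), dtype=np.int64)
    for j in range(n_samples):
        mu = means[:, j // reps] * sfs[j]
        mat[:, j] = _nb_draw(rng, mu, design.dispersion)

    counts = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"), columns=sample_names)
    samples = pd.DataFrame(
        {
            "genotype": [g for (g, t) in CONDITIONS for _ in range(reps)],
            "treatment": [t for (g, t) in CONDITIONS for _ in range(reps)],
            "replicate": [r + 1 for _ in CONDITIONS for r in range(reps)],
        },
        index=pd.Index(sample_names, name="sample"),
    )
    return CountMatrix(counts, samples), truth


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_promoters(
    gene_ids: Sequence[str],
    window_length: int = 3000,
    gc_fraction: float = 0.5,
    planted: Iterable[tuple[str, str, str, int, str]] = (),
    seed: int = 0,
) -> tuple[dict[str, str], PlantedTruth]:
    """Random promoter windows with exactly written motif instances.

    Background bases are i.i.d. with the given GC fraction.  Each planted
    record ``(gene_id, motif_name, consensus, offset, strand)`` realises the
    IUPAC consensus (ambiguity letters drawn uniformly from their class),
    reverse-complemented for strand ``-``, and writes it at *offset* from
    the window's 5' end.  Overlapping plants within one gene are rejected —
    an overlap on either strand would overwrite an earlier instance and
    silently falsify the planted truth.
    """
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seqs = {
        g: rng.choice(_BASES, size=window_length, p=p) for g in gene_ids
    }
    truth = PlantedTruth()
    occupied: dict[str, list[tuple[int, int]]] = {}
    for gene_id, motif_name, consensus, offset, strand in planted:
        if gene_id not in seqs:
            raise KeyError(f"unknown gene id {gene_id!r}")
        L = len(consensus)
        if offset < 0 or offset + L > window_length:
            raise ValueError(
                f"motif {motif_name!r} at offset {offset} does not fit window of "
                f"length {window_length}"
            )
        for s0, e0 in occupied.get(gene_id, []):
            if offset < e0 and s0 < offset + L:
                raise ValueError(
                    f"planted motif collision in {gene_id}: [{offset},{offset+L}) "
                    f"overlaps [{s0},{e0})"
                )
        instance = "".join(
            rng.choice(list(_IUPAC_CHOICES[ch])) for ch in consensus.upper()
        )
        if strand == "-":
            instance = _revcomp(instance)
        elif strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        seqs[gene_id][offset : offset + L] = list(instance)
        occupied.setdefault(gene_id, []).append((offset, offset + L))
        truth.motifs.setdefault(gene_id, []).append((motif_name, offset, strand))
    for g in gene_ids:
        truth.motifs.setdefault(g, [])
    return {g: "".join(s) for g, s in seqs.items()}, truth


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    n_peaks: int,
    contig_lengths: Mapping[str, int],
    enriched_fraction: float = 0.5,
    enriched_fold: float = 4.0,
    depth_noise: float = 0.0,
    seed: int = 0,
    base_depth: float = 20.0,
    peak_length: int = 200,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Peak intervals with sample/control depths and planted enrichment.

    Enriched peaks have expected sample/control depth ratio *enriched_fold*;
    the rest sit at ratio 1.  *depth_noise* is the sigma of independent
    multiplicative lognormal noise on each depth.
    """
    if enriched_fold <= 1:
        raise ValueError("enriched_fold must be > 1")
    if not 0 <= enriched_fraction <= 1:
        raise ValueError("enriched_fraction must lie in [0, 1]")
    if any(l < peak_length for l in contig_lengths.values()):
        raise ValueError("every contig must fit at least one peak")
    rng = np.random.default_rng(seed)
    contigs = list(contig_lengths)
    chosen = rng.integers(0, len(contigs), size=n_peaks)
    starts = np.array(
        [rng.integers(0, contig_lengths[contigs[c]] - peak_length + 1) for c in chosen]
    )
    n_enriched = int(round(enriched_fraction * n_peaks))
    enriched = np.zeros(n_peaks, dtype=bool)
    enriched[rng.permutation(n_peaks)[:n_enriched]] = True

    noise = lambda: np.exp(rng.normal(0.0, depth_noise, size=n_peaks)) if depth_noise > 0 else 1.0
    control = base_depth * noise()
    sample = base_depth * np.where(enriched, enriched_fold, 1.0) * noise()

    names = [f"peak{i:05d}" for i in range(n_peaks)]
    table = pd.DataFrame(
        {
            "contig": [contigs[c] for c in chosen],
            "start": starts,
            "end": starts + peak_length,
            "name": names,
            "sample_depth": np.round(np.atleast_1d(sample * np.ones(n_peaks)), 4),
            "control_depth": np.round(np.atleast_1d(control * np.ones(n_peaks)), 4),
        }
    )
    truth = PlantedTruth(enriched={n: bool(e) for n, e in zip(names, enriched)})
    return table, truth
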