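"""Hypergeometric gene-set enrichment and overlap statistics.

Over-representation of a query gene list in annotation sets, and overlap
significance between two gene sets within a finite universe, both via the
upper-tail hypergeometric probability P(X >= k) computed in log space.
BH correction is shared bit-for-bit with the DE module.  A frequency
pruning step mimics restricting GO terms to a band of annotation
frequency before reporting the top few.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .de import bh_adjust


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene labels."""

    name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str], source: str = "") -> "GeneSet":
        return cls(name=name, members=frozenset(members), source=source)


# ---------------------------------------------------------------------------
# hypergeometric upper tail
# ---------------------------------------------------------------------------

def _hypergeom_logpmf(k: np.ndarray, m: int, K: int, N: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K, m), via log-gamma."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(m - k + 1) - gammaln(N - K - m + k + 1)
        - (gammaln(N + 1) - gammaln(m + 1) - gammaln(N - m + 1))
    )


def _validate_kmKN(k: int, m: int, K: int, N: int) -> None:
    if not (0 <= k <= min(m, K) <= N and m <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, m={m}, K={K}, N={N}")


def hypergeom_upper_tail(k: int, m: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, m), summed in log space.

    X counts the overlap when *m* items are drawn without replacement from
    a universe of *N* containing *K* marked items.
    """
    _validate_kmKN(k, m, K, N)
    if k == 0:
        return 1.0
    lo = max(0, m + K - N)
    hi = min(m, K)
    ks = np.arange(max(k, lo), hi + 1)
    if ks.size == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(_hypergeom_logpmf(ks, m, K, N)))))


def hypergeom_upper_tail_table(m: int, K: int, N: int) -> np.ndarray:
    """P(X >= k) for every k = 0..min(m, K), same log-space route.

    Computed as a reverse cumulative logsumexp over the support; entry 0
    is exactly 1.  Used for exhaustive agreement checks against direct
    summation.
    """
    _validate_kmKN(0, m, K, N)
    hi = min(m, K)
    lo = max(0, m + K - N)
    logpmf = np.full(hi + 1, -np.inf)
    if hi >= lo:
        logpmf[lo:] = _hypergeom_logpmf(np.arange(lo, hi + 1), m, K, N)
    # reverse cumulative logaddexp: tail[k] = logsumexp(logpmf[k:])
    tail_log = np.logaddexp.accumulate(logpmf[::-1])[::-1]
    return np.minimum(np.exp(tail_log), 1.0)


# ---------------------------------------------------------------------------
# enrichment / overlap
# ---------------------------------------------------------------------------

def enrich(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of *query* in each collection set.

    Query members outside the universe are dropped (count reported in the
    ``n_query_dropped`` DataFrame attribute); collection sets are
    intersected with the universe; BH correction runs across the whole
    collection; rows sorted by p ascending.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    q_all = set(query)
    q = q_all & uni
    rows = []
    for gs in collection:
        members = gs.members & uni
        if not members:
            continue
        k = len(q & members)
        rows.append(
            {
                "set": gs.name,
                "k": k,
                "m": len(q),
                "K": len(members),
                "N": len(uni),
                "p": hypergeom_upper_tail(k, len(q), len(members), len(uni)),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "k", "m", "K", "N", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    out.attrs["n_query_dropped"] = len(q_all - uni)
    return out


def frequency_prune(
    results: pd.DataFrame,
    min_freq: float = 0.001,
    max_freq: float = 0.01,
    top_n: int = 5,
) -> pd.DataFrame:
    """Keep sets with annotation frequency strictly inside (min, max), then
    the *top_n* smallest p-values."""
    if len(results) == 0:
        return results.copy()
    freq = results["K"] / results["N"]
    kept = results.loc[(freq > min_freq) & (freq < max_freq)]
    return kept.nsmallest(top_n, "p", keep="first").reset_index(drop=True)


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> pd.Series:
    """One-sided (over-representation) overlap test between two gene sets.

    ``k = |A ∩ B ∩ U|``, ``m = |A ∩ U|``, ``K = |B ∩ U|``, ``N = |U|``.
    """
    uni = set(universe)
    a = set(set_a) & uni
    b = set(set_b) & uni
    if not a or not b:
        raise ValueError("both sets must intersect the universe")
    k, m, K, N = len(a & b), len(a), len(b), len(uni)
    return pd.Series(
        {"k": k, "m": m, "K": K, "N": N, "p": hypergeom_upper_tail(k, m, K, N)}
    )


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a standard GMT file (name TAB description TAB member...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, source = parts[0], parts[1]
            members = [g for g in parts[2:] if g]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet.from_iterable(name, members, source=source))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source or "na", *sorted(gs.members)]) + "\n")
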