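"""Discretisation of the four pairwise comparisons into pattern codes.

Each gene's behaviour across the 2x2 design is summarised as an ordered
4-tuple over {-1, 0, 1}: position 1 is oxidation vs basal in WT cells,
position 2 is mutant vs WT at basal, position 3 is oxidation vs basal in
the mutant, position 4 is mutant vs WT after oxidation.  Significant
up-regulation scores 1, down-regulation -1, no significant change 0.
Genes sharing a code form a cluster; "oxidation-responsive" clusters are
those where the WT responds to oxidant (position 1 nonzero) but the
redox-insensitive mutant dis-regulates that response.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

PatternCode = tuple[int, int, int, int]

POSITION_SEMANTICS = {
    1: "WT oxidation vs WT basal",
    2: "C3S vs WT at basal",
    3: "C3S oxidation vs C3S basal",
    4: "C3S vs WT after oxidation",
}


def code_to_str(code: Sequence[int]) -> str:
    """Serialise a code as comma-joined signed integers, e.g. ``-1,0,0,1``."""
    return ",".join(str(int(c)) for c in code)


def str_to_code(text: str) -> PatternCode:
    parts = tuple(int(x) for x in text.split(","))
    if len(parts) != 4 or any(p not in (-1, 0, 1) for p in parts):
        raise ValueError(f"not a valid pattern code: {text!r}")
    return parts


def discretise(significant: bool, logfc: float) -> int:
    """One comparison's score: sign(logfc) if significant else 0."""
    if not significant:
        return 0
    return 1 if logfc > 0 else (-1 if logfc < 0 else 0)


def assign_patterns(tables: Mapping[int, pd.DataFrame]) -> dict[str, PatternCode]:
    """Combine four called DE tables (keyed by position 1-4) into codes.

    Only genes present in all four tables are coded (the intersection is
    used; a mismatch count is reported via the return of
    :func:`gene_universe_mismatch`).  Genes with all-zero codes are kept
    here and excluded later by :func:`enumerate_clusters`.
    """
    missing = [p for p in (1, 2, 3, 4) if p not in tables]
    if missing:
        raise ValueError(f"missing comparison position(s): {missing}")
    common = tables[1].index
    for p in (2, 3, 4):
        common = common.intersection(tables[p].index)
    codes: dict[str, PatternCode] = {}
    per_pos = {
        p: (
            tables[p].loc[common, "significant"].to_numpy(),
            tables[p].loc[common, "logfc"].to_numpy(),
        )
        for p in (1, 2, 3, 4)
    }
    for i, g in enumerate(common):
        codes[g] = tuple(
            discretise(bool(per_pos[p][0][i]), float(per_pos[p][1][i]))
            for p in (1, 2, 3, 4)
        )
    return codes


def gene_universe_mismatch(tables: Mapping[int, pd.DataFrame]) -> dict[int, int]:
    """How many genes each table carries beyond the common intersection."""
    common = tables[1].index
    for p in (2, 3, 4):
        common = common.intersection(tables[p].index)
    return {p: len(tables[p].index.difference(common)) for p in tables}


def enumerate_clusters(codes: Mapping[str, PatternCode]) -> pd.DataFrame:
    """Cluster table: one row per distinct nonzero code.

    The all-zero code never forms a cluster; membership counts sum to the
    size of the DE gene set (genes with at least one nonzero position).
    """
    members: dict[PatternCode, list[str]] = {}
    for g, code in codes.items():
        if any(code):
            members.setdefault(tuple(code), []).append(g)
    rows = [
        {"code": code_to_str(c), "n_genes": len(gs), "gene_ids": ";".join(sorted(gs))}
        for c, gs in sorted(members.items(), key=lambda kv: -len(kv[1]))
    ]
    return pd.DataFrame(rows, columns=["code", "n_genes", "gene_ids"])


def default_selection_rule(code: PatternCode) -> bool:
    """Oxidation-responsive: WT responds, mutant's response is lost, and the
    dis-regulation is visible in at least one WT-vs-mutant comparison."""
    c1, c2, c3, c4 = code
    return c1 != 0 and c3 == 0 and (c2 != 0 or c4 != 0)


def select_responsive(
    table: pd.DataFrame,
    rule: Callable[[PatternCode], bool] | Sequence[str] = default_selection_rule,
) -> pd.DataFrame:
    """Filter the cluster table to oxidation-responsive codes.

    *rule* is either a predicate over codes or an explicit list of code
    strings (so a published cluster list can be supplied verbatim).  Adds a
    ``direction`` column from position 1 (``up``/``down``).
    """
    if not callable(rule):
        allowed = {str_to_code(s) for s in rule}
        predicate = lambda c: c in allowed
    else:
        predicate = rule
    if len(table) == 0:
        return table.assign(direction=pd.Series(dtype=str))
    keep = table["code"].map(lambda s: predicate(str_to_code(s)))
    out = table.loc[keep].copy()
    out["direction"] = out["code"].map(
        lambda s: "up" if str_to_code(s)[0] > 0 else "down"
    )
    return out


def selection_summary(selected: pd.DataFrame) -> dict:
    """Per-direction gene counts over the selected clusters."""
    if len(selected) == 0:
        return {"n_clusters": 0, "n_genes": 0, "n_up": 0, "n_down": 0}
    up = int(selected.loc[selected["direction"] == "up", "n_genes"].sum())
    down = int(selected.loc[selected["direction"] == "down", "n_genes"].sum())
    return {
        "n_clusters": int(len(selected)),
        "n_genes": up + down,
        "n_up": up,
        "n_down": down,
    }
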