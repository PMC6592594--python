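"""Gene-set over-representation with the EASE-modified Fisher's exact test.

Candidate gene lists are tested for over-representation of annotation terms
(GO-like, pathway-like, phenotype categories) against an explicit gene
universe — here the expressed genes of the contrast, not an external
reference genome. The per-term P value is the EASE score: the one-sided
hypergeometric upper tail of the 2x2 overlap table with the overlap count
decremented by one (a deliberately conservative penalty that makes
single-gene overlaps unremarkable by construction). P values are adjusted
per category with Benjamini-Hochberg, and terms with FDR below 0.05 are
flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("cryodiff")

DEFAULT_FDR = 0.05
MIN_SET_SIZE = 2  # EASE cannot reach significance below this


class MarginError(ValueError):
    """Inconsistent 2x2 table margins."""


@dataclass
class GeneSet:
    term_id: str
    name: str
    category: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named annotation sets over a stated gene universe.

    Sets are pruned at load time to the universe; sets left with fewer than
    two members are dropped (they cannot attain EASE significance).
    """

    universe: frozenset[str]
    sets: dict[str, GeneSet]

    @classmethod
    def build(
        cls, universe: set[str], sets: dict[str, GeneSet], prune: bool = True
    ) -> "GeneSetCollection":
        universe = frozenset(universe)
        kept: dict[str, GeneSet] = {}
        for term_id, gs in sets.items():
            members = frozenset(gs.members) & universe
            if prune and len(members) < MIN_SET_SIZE:
                continue
            kept[term_id] = GeneSet(gs.term_id, gs.name, gs.category, members)
        return cls(universe, kept)

    def categories(self) -> list[str]:
        return sorted({gs.category for gs in self.sets.values()})


def _check_margins(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise MarginError(f"inconsistent 2x2 margins: k={k} n={n} K={K} N={N}")


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """EASE P for an overlap of ``k`` genes between a list of ``n`` and a
    term of ``K`` members in a universe of ``N``.

    Equals the hypergeometric upper tail P(X >= k-1) with the decrement
    floored at zero, so k in {0, 1} gives exactly 1.
    """
    _check_margins(k, n, K, N)
    if k <= 1:
        return 1.0
    # P(X >= k-1) = sf(k-2) for X ~ Hypergeom(N, K, n)
    return float(hypergeom.sf(k - 2, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Observed/expected overlap ratio ``(k/n) / (K/N)``.

    Undefined (NaN) when a margin is zero.
    """
    _check_margins(k, n, K, N)
    if n == 0 or K == 0 or N == 0:
        return float("nan")
    return (k / n) / (K / N)


def enrich(
    genes: set[str],
    collection: GeneSetCollection,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Over-representation chart for a candidate list.

    Genes outside the collection's universe are dropped (with a logged
    count). BH adjustment runs across all tested terms within each
    category. Rows are sorted by P ascending.
    """
    in_universe = set(genes) & collection.universe
    dropped = len(set(genes)) - len(in_universe)
    if dropped:
        logger.info("enrich: %d query genes outside the universe dropped", dropped)
    n = len(in_universe)
    N = len(collection.universe)

    columns = [
        "term",
        "name",
        "category",
        "overlap",
        "list_size",
        "set_size",
        "universe_size",
        "fold_enrichment",
        "p_value",
    ]
    if n == 0:
        empty = pd.DataFrame(columns=columns)
        empty["fdr"] = pd.Series(dtype=float)
        empty["significant"] = pd.Series(dtype=bool)
        return empty

    rows = []
    for term_id, gs in sorted(collection.sets.items()):
        K = len(gs.members)
        k = len(gs.members & in_universe)
        rows.append(
            {
                "term": term_id,
                "name": gs.name,
                "category": gs.category,
                "overlap": k,
                "list_size": n,
                "set_size": K,
                "universe_size": N,
                "fold_enrichment": fold_enrichment(k, n, K, N) if n else float("nan"),
                "p_value": ease_score(k, n, K, N),
            }
        )
    table = pd.DataFrame(rows, columns=columns)
    if table.empty:
        table["fdr"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
        return table

    table["fdr"] = np.nan
    for _, idx in table.groupby("category").groups.items():
        pvals = table.loc[idx, "p_value"].to_numpy()
        table.loc[idx, "fdr"] = multipletests(pvals, method="fdr_bh")[1]
    table["significant"] = table["fdr"] < fdr_threshold
    return table.sort_values(["p_value", "term"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT I/O

def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Load a GMT file (term, description, members...).

    The description field may carry the category as ``category|free text``;
    otherwise the category defaults to ``"sets"``. When no ``universe`` is
    given, the union of all members is used.
    """
    sets: dict[str, GeneSet] = {}
    members_union: set[str] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            term, desc = parts[0], parts[1]
            members = frozenset(g for g in parts[2:] if g)
            category, _, name = desc.partition("|")
            if not name:
                category, name = "sets", desc or term
            sets[term] = GeneSet(term, name, category, members)
            members_union |= members
    return GeneSetCollection.build(universe or members_union, sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, gs in sorted(collection.sets.items()):
            members = "\t".join(sorted(gs.members))
            fh.write(f"{term_id}\t{gs.category}|{gs.name}\t{members}\n")


def write_chart(table: pd.DataFrame, path: str | Path) -> None:
    """Write the enrichment chart TSV (count and fold enrichment per term)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
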