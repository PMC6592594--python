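"""Ortholog-phenotype intersection.

Down-regulated candidate genes are checked against a table of
model-organism (mouse-style) knockout phenotypes via an ortholog mapping,
flagging genes whose orthologs are annotated with developmentally critical
phenotypes such as embryonic lethality. The mapping is supplied as a TSV
(``gene  ortholog  terms``, terms pipe-separated); one row is emitted per
(gene, ortholog) pair, so one-to-many orthology yields several rows.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class PhenotypeMap:
    """gene id -> list of (ortholog id, set of phenotype terms)."""

    entries: dict[str, list[tuple[str, frozenset[str]]]] = field(default_factory=dict)

    def add(self, gene: str, ortholog: str, terms: set[str]) -> None:
        terms = frozenset(t for t in terms if t)
        if not terms:
            return
        self.entries.setdefault(gene, []).append((ortholog, terms))


def phenotype_hits(
    genes: set[str],
    pheno_map: PhenotypeMap,
    term_filter: set[str] | None = None,
) -> tuple[pd.DataFrame, Counter]:
    """Rows for input genes whose ortholog carries >= 1 phenotype term.

    ``term_filter`` restricts to the given terms; an empty or None filter
    means no restriction. Also returns a term-frequency summary over the
    reported rows.
    """
    use_filter = bool(term_filter)
    rows = []
    freq: Counter = Counter()
    for gene in sorted(genes):
        for ortholog, terms in pheno_map.entries.get(gene, []):
            kept = terms & term_filter if use_filter else terms
            if not kept:
                continue
            rows.append(
                {"gene": gene, "ortholog": ortholog, "terms": "|".join(sorted(kept))}
            )
            freq.update(kept)
    return pd.DataFrame(rows, columns=["gene", "ortholog", "terms"]), freq


# ---------------------------------------------------------------------------
# I/O

def read_phenotype_map(path: str | Path) -> PhenotypeMap:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene", "ortholog", "terms"}
    if not needed.issubset(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(needed)}")
    pmap = PhenotypeMap()
    for _, row in df.iterrows():
        pmap.add(str(row["gene"]), str(row["ortholog"]), set(str(row["terms"]).split("|")))
    return pmap


def write_phenotype_map(pmap: PhenotypeMap, path: str | Path) -> None:
    rows = [
        {"gene": g, "ortholog": o, "terms": "|".join(sorted(t))}
        for g, lst in sorted(pmap.entries.items())
        for o, t in lst
    ]
    pd.DataFrame(rows, columns=["gene", "ortholog", "terms"]).to_csv(
        path, sep="\t", index=False
    )


def write_hits(hits: pd.DataFrame, freq: Counter, tsv_path: str | Path, json_path: str | Path) -> None:
    hits.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(dict(sorted(freq.items())), fh, indent=2)
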