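"""Synthetic data with the statistical structure the analysis assumes.

No raw reads were deposited for the study this pipeline re-implements, so
every downstream stage is exercised on simulated data that emulates the
design: 12 samples (3 embryo days x FRSH/CRYO x 2 matched replicates),
on the order of 29,000 expressed genes per embryo, negative-binomial counts
around log-normal gene baselines, log-normal library sizes, and condition
effects planted inside designated annotation sets (as the study observed
for oxidative-phosphorylation, ribosome and histone gene sets).

Planted genes receive a log2 baseline boost with a tight within-set spread:
the gene sets the study flagged are coherent, highly expressed housekeeping
programmes, and a pooled-TPM-difference test is by construction most
sensitive exactly there. The generator therefore plants effects where the
study found them — in abundant transcripts — rather than uniformly across
the dynamic range.

Alongside the count matrix the module fabricates matched annotation sets
(planted sets verbatim plus decoys of null genes), a confidence-scored
interaction network with dense, high-confidence planted modules, and a
synthetic ortholog-phenotype table enriched for embryonic-lethality terms
among planted down-regulated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GeneSet, GeneSetCollection, write_gmt
from .network import ConfidenceNetwork, write_network
from .phenotype import PhenotypeMap, write_phenotype_map
from .quantify import CountMatrix, SampleSheet

logger = logging.getLogger("cryodiff")

#: average number of transcripts detected per embryo in the study design
DEFAULT_N_GENES = 29_196
DEFAULT_DAYS = (8, 10, 12)

# embryonic-lethality-style phenotype vocabulary for the synthetic map
LETHALITY_TERMS = (
    "embryonic lethality before implantation-complete penetrance",
    "embryonic lethality during organogenesis",
    "embryonic growth retardation",
)
BENIGN_TERMS = ("normal phenotype", "decreased body weight")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedSet:
    """One annotation set carrying a condition effect.

    ``log2_effect`` multiplies the CRYO-side mean by ``2**log2_effect``;
    down-regulated sets carry negative values.
    """

    name: str
    size: int
    log2_effect: float


@dataclass
class SimConfig:
    n_genes: int = DEFAULT_N_GENES
    n_days: int = 3
    replicates_per_condition: int = 2
    mean_library_size: float = 5e6
    nb_dispersion: float = 0.2
    planted_down_sets: tuple[PlantedSet, ...] = ()
    planted_up_sets: tuple[PlantedSet, ...] = ()
    baseline_log_mean_sd: float = 1.5
    gene_length_range: tuple[float, float] = (200.0, 10_000.0)
    seed: int = 0
    # high-abundance, low-spread baselines for planted sets (coherent
    # housekeeping programmes such as ribosome/oxphos/histone genes)
    planted_baseline_log2_boost: float = 3.0
    planted_baseline_sd: float = 0.5
    library_size_cv: float = 0.20

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_days < 1 or self.replicates_per_condition < 1:
            raise ConfigError("n_genes, n_days, replicates_per_condition must be >= 1")
        if self.mean_library_size <= 0 or self.nb_dispersion <= 0:
            raise ConfigError("mean_library_size and nb_dispersion must be positive")
        if self.baseline_log_mean_sd <= 0:
            raise ConfigError("baseline_log_mean_sd must be positive")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ConfigError("gene_length_range must satisfy 0 < min <= max")
        self.planted_down_sets = tuple(
            s if isinstance(s, PlantedSet) else PlantedSet(*s) for s in self.planted_down_sets
        )
        self.planted_up_sets = tuple(
            s if isinstance(s, PlantedSet) else PlantedSet(*s) for s in self.planted_up_sets
        )
        names = [s.name for s in self.planted_down_sets + self.planted_up_sets]
        if len(names) != len(set(names)):
            raise ConfigError("planted sets overlap: duplicate set names")
        for s in self.planted_down_sets:
            if s.log2_effect > 0:
                raise ConfigError(f"down set {s.name} must have log2_effect <= 0")
        for s in self.planted_up_sets:
            if s.log2_effect < 0:
                raise ConfigError(f"up set {s.name} must have log2_effect >= 0")
        total_planted = sum(s.size for s in self.planted_down_sets + self.planted_up_sets)
        if total_planted > self.n_genes:
            raise ConfigError("planted set members exceed n_genes")

    @property
    def days(self) -> list[int]:
        base = list(DEFAULT_DAYS)
        while len(base) < self.n_days:
            base.append(base[-1] + 2)
        return base[: self.n_days]

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("planted_down_sets", "planted_up_sets"):
            if key in d:
                d[key] = tuple(
                    PlantedSet(**s) if isinstance(s, dict) else PlantedSet(*s)
                    for s in d[key]
                )
        if "gene_length_range" in d:
            d["gene_length_range"] = tuple(d["gene_length_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-gene planted status: down / up / null, log2 effect, set label."""

    table: pd.DataFrame  # columns: gene, status, log2_effect, set_label

    def genes_with_status(self, status: str) -> list[str]:
        return self.table.loc[self.table["status"] == status, "gene"].tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene"].tolist()

    def planted_sets(self) -> dict[str, list[str]]:
        planted = self.table[self.table["set_label"] != ""]
        return {
            name: sub["gene"].tolist() for name, sub in planted.groupby("set_label")
        }


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SampleSheet, GroundTruth]:
    """Draw the count matrix, sample sheet and ground truth.

    Counts for gene g in sample s are negative binomial with mean
    ``libsize_s * a_g * len_g / sum(a * len)`` where ``a_g`` is the gene's
    relative abundance (doubled per unit of planted log2 effect on CRYO
    samples) and variance ``mu + dispersion * mu^2``. Identical configs
    (including the seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(n)])

    lo, hi = config.gene_length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    # planted-set assignment: disjoint by construction
    all_sets = list(config.planted_down_sets) + list(config.planted_up_sets)
    total_planted = sum(s.size for s in all_sets)
    planted_idx = rng.choice(n, size=total_planted, replace=False)
    status = np.full(n, "null", dtype=object)
    effect = np.zeros(n)
    set_label = np.full(n, "", dtype=object)
    cursor = 0
    for s in all_sets:
        idx = planted_idx[cursor : cursor + s.size]
        cursor += s.size
        status[idx] = "down" if s.log2_effect < 0 else ("up" if s.log2_effect > 0 else "null")
        effect[idx] = s.log2_effect
        set_label[idx] = s.name

    # baselines: log2 abundance; planted genes boosted and coherent
    log2_base = rng.normal(0.0, config.baseline_log_mean_sd, size=n)
    planted_mask = set_label != ""
    log2_base[planted_mask] = rng.normal(
        config.planted_baseline_log2_boost, config.planted_baseline_sd,
        size=int(planted_mask.sum()),
    )
    abundance = np.power(2.0, log2_base)

    # sample layout: per day, FRSH then CRYO replicates; matched pair = rep
    days = config.days
    reps = config.replicates_per_condition
    sample_rows = []
    for day in days:
        for cond in ("FRSH", "CRYO"):
            for r in range(1, reps + 1):
                sample_rows.append(
                    {
                        "sample": f"D{day}_{cond}{r}",
                        "day": day,
                        "condition": cond,
                        "pair": f"P{day}_{r}",
                    }
                )
    sheet = SampleSheet(pd.DataFrame(sample_rows))

    n_samples = len(sample_rows)
    cv = config.library_size_cv
    sigma = np.sqrt(np.log1p(cv**2))
    lib_sizes = rng.lognormal(
        np.log(config.mean_library_size) - sigma**2 / 2.0, sigma, size=n_samples
    )

    # per-condition expected read fractions (abundance x length weighting)
    frsh_weight = abundance * lengths
    cryo_weight = abundance * np.power(2.0, effect) * lengths
    frsh_p = frsh_weight / frsh_weight.sum()
    cryo_p = cryo_weight / cryo_weight.sum()

    counts = np.empty((n, n_samples), dtype=np.int64)
    d = config.nb_dispersion
    for j, row in enumerate(sample_rows):
        p_vec = cryo_p if row["condition"] == "CRYO" else frsh_p
        mu = lib_sizes[j] * p_vec
        if d < 1e-8:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / d
            counts[:, j] = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=[r["sample"] for r in sample_rows]),
        pd.Series(lengths, index=genes, name="length"),
    )
    truth = GroundTruth(
        pd.DataFrame(
            {"gene": genes, "status": status, "log2_effect": effect, "set_label": set_label}
        )
    )
    return cm, sheet, truth


def simulate_annotations(
    truth: GroundTruth,
    n_decoy_sets: int,
    seed: int,
    decoy_set_size: int | None = None,
) -> GeneSetCollection:
    """Planted sets verbatim plus decoy sets of random null genes.

    The universe is the full simulated gene list. Decoy sets default to the
    mean planted-set size (20 when nothing is planted).
    """
    if truth.table.empty:
        raise ConfigError("ground truth is empty")
    rng = np.random.default_rng(seed)
    planted = truth.planted_sets()
    sets: dict[str, GeneSet] = {
        name: GeneSet(name, name, "simulated", frozenset(members))
        for name, members in planted.items()
    }
    if decoy_set_size is None:
        sizes = [len(m) for m in planted.values()]
        decoy_set_size = int(round(np.mean(sizes))) if sizes else 20
    null_genes = np.array(truth.genes_with_status("null"))
    if n_decoy_sets and decoy_set_size > null_genes.size:
        raise ConfigError("not enough null genes for the requested decoy sets")
    for i in range(n_decoy_sets):
        members = rng.choice(null_genes, size=decoy_set_size, replace=False)
        name = f"decoy_{i:03d}"
        sets[name] = GeneSet(name, name, "simulated", frozenset(members.tolist()))
    return GeneSetCollection.build(set(truth.gene_ids), sets, prune=False)


def simulate_network(
    truth: GroundTruth,
    intra_set_edge_prob: float,
    background_edge_prob: float,
    score_means: tuple[float, float] = (0.9, 0.4),
    seed: int = 0,
    score_sd: float = 0.08,
) -> ConfidenceNetwork:
    """STRING-like network with dense, high-confidence planted modules.

    Pairs within a planted set are connected with ``intra_set_edge_prob``
    and scores centred on ``score_means[0]``; every remaining pair with
    ``background_edge_prob`` and scores centred on ``score_means[1]``.
    Scores are clipped to [0, 1].
    """
    if not 0 <= background_edge_prob <= intra_set_edge_prob <= 1:
        raise ConfigError("need 0 <= background_edge_prob <= intra_set_edge_prob <= 1")
    rng = np.random.default_rng(seed)
    genes = truth.gene_ids
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    mu_intra, mu_bg = score_means

    edges: list[tuple[str, str, float]] = []
    intra_pairs: set[tuple[int, int]] = set()
    for members in truth.planted_sets().values():
        idx = sorted(index[g] for g in members)
        for a_pos, i in enumerate(idx):
            for j in idx[a_pos + 1 :]:
                intra_pairs.add((i, j))
                if rng.random() < intra_set_edge_prob:
                    score = float(np.clip(rng.normal(mu_intra, score_sd), 0.0, 1.0))
                    edges.append((genes[i], genes[j], score))

    if background_edge_prob > 0:
        n_pairs = n * (n - 1) // 2
        if n_pairs <= 3_000_000:
            iu, ju = np.triu_indices(n, k=1)
            mask = rng.random(iu.size) < background_edge_prob
            cand = zip(iu[mask].tolist(), ju[mask].tolist())
            bg_pairs = [p for p in cand if p not in intra_pairs]
        else:  # sparse regime: sample the binomial edge count directly
            n_bg_pairs = n_pairs - len(intra_pairs)
            target = rng.binomial(n_bg_pairs, background_edge_prob)
            seen: set[tuple[int, int]] = set()
            while len(seen) < target:
                i = int(rng.integers(0, n))
                j = int(rng.integers(0, n))
                if i == j:
                    continue
                pair = (min(i, j), max(i, j))
                if pair in intra_pairs or pair in seen:
                    continue
                seen.add(pair)
            bg_pairs = sorted(seen)
        scores = np.clip(rng.normal(mu_bg, score_sd, size=len(bg_pairs)), 0.0, 1.0)
        edges.extend(
            (genes[i], genes[j], float(s)) for (i, j), s in zip(bg_pairs, scores)
        )

    return ConfidenceNetwork.from_edges(edges, nodes=genes)


def simulate_phenotypes(
    truth: GroundTruth,
    seed: int = 0,
    ortholog_prob: float = 0.8,
    lethal_prob_down: float = 0.6,
    lethal_prob_other: float = 0.05,
) -> PhenotypeMap:
    """Synthetic ortholog-phenotype table.

    Most genes map to a mouse-style ortholog (``Mm_<gene>``); planted
    down-regulated genes are annotated with embryonic-lethality terms with
    high probability, other genes rarely (mostly benign terms).
    """
    rng = np.random.default_rng(seed)
    pmap = PhenotypeMap()
    down = set(truth.genes_with_status("down"))
    for gene in truth.gene_ids:
        if rng.random() > ortholog_prob:
            continue  # no ortholog: the mapping is a partial function
        lethal_p = lethal_prob_down if gene in down else lethal_prob_other
        terms: set[str] = set()
        if rng.random() < lethal_p:
            terms.add(LETHALITY_TERMS[int(rng.integers(len(LETHALITY_TERMS)))])
        if rng.random() < 0.15:
            terms.add(BENIGN_TERMS[int(rng.integers(len(BENIGN_TERMS)))])
        if terms:
            pmap.add(gene, f"Mm_{gene}", terms)
    return pmap


# ---------------------------------------------------------------------------
# writers: the TSV/GMT bundle consumed by the downstream CLI stages

def write_simulation(
    outdir: str | Path,
    counts: CountMatrix,
    sheet: SampleSheet,
    truth: GroundTruth,
    annotations: GeneSetCollection | None = None,
    net: ConfidenceNetwork | None = None,
    phenotypes: PhenotypeMap | None = None,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "lengths": outdir / "lengths.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    counts.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    counts.lengths.to_frame("length_bp").to_csv(paths["lengths"], sep="\t", index_label="gene")
    sheet.table.to_csv(paths["samples"], sep="\t", index=False)
    truth.table.to_csv(paths["truth"], sep="\t", index=False)
    if annotations is not None:
        paths["annotations"] = outdir / "annotations.gmt"
        write_gmt(annotations, paths["annotations"])
    if net is not None:
        paths["network"] = outdir / "network.tsv"
        write_network(net, paths["network"])
    if phenotypes is not None:
        paths["phenotypes"] = outdir / "phenotypes.tsv"
        write_phenotype_map(phenotypes, paths["phenotypes"])
    logger.info("simulation written to %s", outdir)
    return paths
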