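"""Permutation-null differential expression with a fold-change filter.

The test statistic is the per-gene difference of mean TPM between the two
conditions (CRYO minus FRSH by convention, so positive differences mean
higher expression after frozen-thawed-sperm conception). With only two
replicates per condition a per-gene label permutation admits just
C(4,2) = 6 distinct assignments, so the null is pooled genome-wide: every
gene's pseudo-differences from every permutation round enter one empirical
null distribution, and each gene's observed difference is ranked against it
two-sidedly (on absolute value, ties counted as exceedances, add-one
corrected). A gene is a candidate when its permutation P falls below the
chosen threshold *and* its fold change (CRYO/FRSH ratio of mean TPM, with a
pseudocount) is at least the fold threshold — the fold filter guards
against calling genes whose absolute difference is large purely because
their expression is high.

Two permutation schemes are exposed:

``label_within_gene``
    each permutation reassigns every gene's observed values to
    pseudo-groups uniformly at random (the default; it preserves each
    gene's scale).
``global_score_shuffle``
    each permutation shuffles TPM values across genes within each sample
    before differencing (destroys gene identity entirely).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix, InputError, SampleSheet

logger = logging.getLogger("cryodiff")

#: y-coordinate of the volcano significance guide line: -log10(0.05)
VOLCANO_P_LINE = round(-math.log10(0.05), 2)  # 1.30
#: x-coordinates of the volcano fold-change guide lines (log2 of fold 2)
VOLCANO_FC_LINES = (-1.0, 1.0)

PermutationMode = Literal["label_within_gene", "global_score_shuffle"]

_CHUNK_PERMS = 250  # permutations per vectorised chunk (bounds memory)


class ContrastError(ValueError):
    """A contrast cannot be formed (empty group, bad permutation count)."""


@dataclass
class ContrastSpec:
    """One per-day two-group comparison (group B relative to group A).

    Defaults follow the study conventions: FRSH as baseline, CRYO as the
    treatment side, P < 0.01 with a fold-change >= 2 filter, 10,000
    permutation rounds. ``p_threshold`` may be relaxed to 0.05 or tightened
    to 0.001 (the rescue threshold used when a candidate list is too long
    to annotate).
    """

    day: int
    group_a: str = "FRSH"
    group_b: str = "CRYO"
    mode: PermutationMode = "label_within_gene"
    n_permutations: int = 10_000
    p_threshold: float = 0.01
    fold_threshold: float = 2.0
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ContrastError("contrast groups must differ")
        if self.n_permutations < 1:
            raise ContrastError("n_permutations must be >= 1")
        if not 0.0 < self.p_threshold < 1.0:
            raise ContrastError("p_threshold must lie in (0, 1)")
        if self.fold_threshold < 1.0:
            raise ContrastError("fold_threshold must be >= 1")


@dataclass
class NullDistribution:
    """Pooled empirical null of pseudo-differences.

    ``values`` is the flat genome-wide pool; ``exhaustive`` marks a null
    built by complete enumeration of label assignments (equal weights), in
    which case P values are exact and need no add-one correction.
    """

    values: np.ndarray
    mode: PermutationMode
    exhaustive: bool = False
    _sorted_abs: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_values(self) -> int:
        return int(self.values.size)

    def sorted_abs(self) -> np.ndarray:
        if self._sorted_abs is None:
            self._sorted_abs = np.sort(np.abs(self.values))
        return self._sorted_abs


def _group_matrices(
    tpm: ExpressionMatrix, samples: SampleSheet, contrast: ContrastSpec
) -> tuple[np.ndarray, int, int]:
    """Gene x (A-samples ++ B-samples) value matrix and the group sizes."""
    cols_a = samples.samples_for(contrast.day, contrast.group_a)
    cols_b = samples.samples_for(contrast.day, contrast.group_b)
    if not cols_a or not cols_b:
        raise ContrastError(
            f"day {contrast.day}: empty group "
            f"({contrast.group_a}: {len(cols_a)}, {contrast.group_b}: {len(cols_b)})"
        )
    missing = [c for c in cols_a + cols_b if c not in tpm.values.columns]
    if missing:
        raise ContrastError(f"samples absent from expression matrix: {missing}")
    x = tpm.values[cols_a + cols_b].to_numpy(dtype=float)
    return x, len(cols_a), len(cols_b)


def observed_difference(
    tpm: ExpressionMatrix, samples: SampleSheet, contrast: ContrastSpec
) -> pd.Series:
    """Per-gene mean TPM in group B minus mean TPM in group A."""
    x, n_a, n_b = _group_matrices(tpm, samples, contrast)
    diff = x[:, n_a:].mean(axis=1) - x[:, :n_a].mean(axis=1)
    return pd.Series(diff, index=tpm.values.index, name="diff")


def _pseudo_diffs_label(x: np.ndarray, n_a: int, order: np.ndarray) -> np.ndarray:
    """Pseudo-differences for permuted column orders (perms x genes)."""
    permuted = np.take_along_axis(x[None, :, :], order, axis=2)
    return permuted[:, :, n_a:].mean(axis=2) - permuted[:, :, :n_a].mean(axis=2)


def permutation_null(
    tpm: ExpressionMatrix,
    samples: SampleSheet,
    contrast: ContrastSpec,
    exhaustive: bool = False,
) -> NullDistribution:
    """Materialise the pooled null distribution of pseudo-differences.

    With ``exhaustive=True`` (``label_within_gene`` only) every one of the
    C(n_a+n_b, n_a) label assignments is enumerated per gene with equal
    weight, giving the exact null the sampled one converges to.

    For large matrices prefer :func:`permutation_test`, which streams the
    null in chunks instead of holding it in memory.
    """
    x, n_a, n_b = _group_matrices(tpm, samples, contrast)
    n = n_a + n_b
    rng = np.random.default_rng(contrast.seed)

    if exhaustive:
        if contrast.mode != "label_within_gene":
            raise ContrastError("exhaustive enumeration requires label_within_gene")
        orders = _all_label_orders(n_a, n_b)  # (n_comb, n); broadcast over genes
        diffs = _pseudo_diffs_label(
            x, n_a, np.broadcast_to(orders[:, None, :], (orders.shape[0], x.shape[0], n))
        )
        return NullDistribution(diffs.ravel(), contrast.mode, exhaustive=True)

    chunks: list[np.ndarray] = []
    for start in range(0, contrast.n_permutations, _CHUNK_PERMS):
        size = min(_CHUNK_PERMS, contrast.n_permutations - start)
        chunks.append(_null_chunk(x, n_a, size, contrast.mode, rng))
    return NullDistribution(np.concatenate([c.ravel() for c in chunks]), contrast.mode)


def _all_label_orders(n_a: int, n_b: int) -> np.ndarray:
    """Every assignment of the pooled columns to pseudo-groups A|B."""
    n = n_a + n_b
    orders = []
    for combo in itertools.combinations(range(n), n_a):
        rest = [i for i in range(n) if i not in combo]
        orders.append(list(combo) + rest)
    return np.asarray(orders)


def _null_chunk(
    x: np.ndarray,
    n_a: int,
    n_perms: int,
    mode: PermutationMode,
    rng: np.random.Generator,
) -> np.ndarray:
    """One chunk of pseudo-differences, shape (n_perms, genes)."""
    n_genes, n = x.shape
    if mode == "label_within_gene":
        order = np.argsort(rng.random((n_perms, n_genes, n)), axis=2)
        return _pseudo_diffs_label(x, n_a, order)
    if mode == "global_score_shuffle":
        shuffled = rng.permuted(
            np.broadcast_to(x, (n_perms, n_genes, n)).copy(), axis=1
        )
        return shuffled[:, :, n_a:].mean(axis=2) - shuffled[:, :, :n_a].mean(axis=2)
    raise ContrastError(f"unknown permutation mode: {mode}")


def permutation_pvalue(
    observed: pd.Series | np.ndarray,
    null: NullDistribution,
    add_one: bool | None = None,
) -> pd.Series | np.ndarray:
    """Two-sided exceedance P against the pooled null.

    ``P = (1 + #{|null| >= |observed|}) / (N + 1)`` — ties count as
    exceedances and the add-one correction keeps P off zero, so
    ``P ∈ [1/(N+1), 1]``. For an exhaustive null the count is exact and no
    correction is applied (the identity assignment already ties the
    observation).
    """
    if null.n_values == 0:
        raise ContrastError("empty null distribution")
    if add_one is None:
        add_one = not null.exhaustive
    obs = np.abs(np.asarray(observed, dtype=float))
    sorted_abs = null.sorted_abs()
    n = sorted_abs.size
    exceed = n - np.searchsorted(sorted_abs, obs, side="left")
    if add_one:
        p = (1.0 + exceed) / (n + 1.0)
    else:
        p = exceed / n
    if isinstance(observed, pd.Series):
        return pd.Series(p, index=observed.index, name="p_value")
    return p


def _log2_fold_change(
    mean_a: np.ndarray, mean_b: np.ndarray, pseudocount: float
) -> np.ndarray:
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount))


def permutation_test(
    tpm: ExpressionMatrix,
    samples: SampleSheet,
    contrast: ContrastSpec,
) -> pd.DataFrame:
    """Full differential-expression table for one contrast.

    Streams the pooled null chunk-by-chunk, accumulating per-gene
    exceedance counts, so memory stays bounded for genome-scale matrices.

    Returns a DataFrame indexed by gene with columns ``mean_a``, ``mean_b``,
    ``diff``, ``log2_fc``, ``p_value``, ``passed_p``, ``passed_fc``,
    ``candidate`` and ``direction``.
    """
    x, n_a, n_b = _group_matrices(tpm, samples, contrast)
    mean_a = x[:, :n_a].mean(axis=1)
    mean_b = x[:, n_a:].mean(axis=1)
    obs = mean_b - mean_a
    abs_obs = np.abs(obs)

    rng = np.random.default_rng(contrast.seed)
    exceed = np.zeros(x.shape[0], dtype=np.int64)
    n_null = 0
    for start in range(0, contrast.n_permutations, _CHUNK_PERMS):
        size = min(_CHUNK_PERMS, contrast.n_permutations - start)
        chunk = np.sort(np.abs(_null_chunk(x, n_a, size, contrast.mode, rng).ravel()))
        exceed += chunk.size - np.searchsorted(chunk, abs_obs, side="left")
        n_null += chunk.size
    p = (1.0 + exceed) / (n_null + 1.0)

    log2_fc = _log2_fold_change(mean_a, mean_b, contrast.pseudocount)
    passed_p = p < contrast.p_threshold
    passed_fc = np.abs(log2_fc) >= np.log2(contrast.fold_threshold)
    candidate = passed_p & passed_fc
    direction = np.where(log2_fc > 0, "up", np.where(log2_fc < 0, "down", "none"))

    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "diff": obs,
            "log2_fc": log2_fc,
            "p_value": p,
            "passed_p": passed_p,
            "passed_fc": passed_fc,
            "candidate": candidate,
            "direction": direction,
        },
        index=tpm.values.index.rename("gene"),
    )


def apply_thresholds(
    results: pd.DataFrame, p_threshold: float, fold_threshold: float
) -> pd.DataFrame:
    """Re-flag an existing table at different thresholds (the Day-8-style
    rescue re-thresholding: tightening P from 0.01 to 0.001 without
    recomputing the permutation null)."""
    out = results.copy()
    out["passed_p"] = out["p_value"] < p_threshold
    out["passed_fc"] = out["log2_fc"].abs() >= np.log2(fold_threshold)
    out["candidate"] = out["passed_p"] & out["passed_fc"]
    return out


def select_candidates(
    results: pd.DataFrame, contrast: ContrastSpec
) -> tuple[list[str], list[str]]:
    """Up- and down-regulated candidate gene lists.

    Candidate: ``P < p_threshold`` and ``|log2 FC| >= log2(fold_threshold)``;
    partitioned by the sign of the log2 fold change and sorted by P
    ascending, then |log2 FC| descending.
    """
    flagged = apply_thresholds(results, contrast.p_threshold, contrast.fold_threshold)
    cands = flagged[flagged["candidate"]].copy()
    cands["abs_fc"] = cands["log2_fc"].abs()
    cands = cands.sort_values(["p_value", "abs_fc"], ascending=[True, False])
    up = cands.index[cands["log2_fc"] > 0].tolist()
    down = cands.index[cands["log2_fc"] < 0].tolist()
    return up, down


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano coordinates.

    x is the log2 CRYO/FRSH fold change; y is -log10 P (finite by
    construction since P >= 1/(N+1)). ``flagged`` marks candidate genes for
    red rendering; the guide lines sit at x = ±1 and y = 1.30 (P = 0.05).
    """
    return pd.DataFrame(
        {
            "x": results["log2_fc"],
            "y": -np.log10(results["p_value"]),
            "flagged": results["candidate"],
        },
        index=results.index,
    )


def volcano_plot(results: pd.DataFrame, path=None, title: str = ""):
    """Render the volcano with the study's guide-line conventions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = volcano_table(results)
    fig, ax = plt.subplots(figsize=(6, 5))
    bg = table[~table["flagged"]]
    fg = table[table["flagged"]]
    ax.scatter(bg["x"], bg["y"], s=8, c="0.6", linewidths=0)
    ax.scatter(fg["x"], fg["y"], s=10, c="red", linewidths=0)
    for xline in VOLCANO_FC_LINES:
        ax.axvline(xline, ls="--", c="k", lw=0.8)
    ax.axhline(VOLCANO_P_LINE, ls="--", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change (CRYO / FRSH)")
    ax.set_ylabel("-log10 P")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
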