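"""Expression quantification: counts to TPM/RPKM and the expression floor.

The study design is a matched-pair, two-condition bulk RNA-seq experiment:
embryos conceived with fresh (FRSH) or frozen-thawed (CRYO) sperm, collected
on days 8, 10 and 12 after ovulation, two replicates per condition per day.
Raw gene-level counts are converted to length-normalised expression (TPM for
testing, RPKM for the expression floor), and a gene is considered expressed
when its RPKM exceeds a floor (default 0.4) in at least one sample of the
contrast under consideration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger("cryodiff")

DEFAULT_EXPRESSION_FLOOR = 0.4

FloorScope = Literal["any", "all", "condition-mean"]


class InputError(ValueError):
    """Invalid input data (bad lengths, inconsistent shapes, wrong units)."""


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-gene effective lengths (bp).

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
    lengths
        Series of effective transcript lengths in base pairs, indexed by
        gene id; must cover every gene in ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise InputError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise InputError("duplicate sample ids in count matrix")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:5].tolist()
            raise InputError(f"genes without a length: {missing} ...")
        if (self.lengths <= 0).any():
            raise InputError("gene lengths must be strictly positive")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression values with a unit tag."""

    values: pd.DataFrame
    unit: Literal["TPM", "RPKM"]

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class SampleSheet:
    """Per-sample metadata: day, condition (FRSH/CRYO) and matched-pair id."""

    table: pd.DataFrame  # columns: sample, day, condition, pair

    REQUIRED = ("sample", "day", "condition", "pair")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise InputError(f"sample sheet missing columns: {missing}")
        if self.table["sample"].duplicated().any():
            raise InputError("duplicate sample ids in sample sheet")
        self.table = self.table.reset_index(drop=True)

    @property
    def days(self) -> list[int]:
        return sorted(self.table["day"].unique().tolist())

    def samples_for(self, day: int, condition: str) -> list[str]:
        mask = (self.table["day"] == day) & (self.table["condition"] == condition)
        return self.table.loc[mask, "sample"].tolist()

    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique().tolist())


def compute_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Transcripts per kilobase million.

    Per sample: ``rate_g = count_g / length_g(kb)``;
    ``TPM_g = 1e6 * rate_g / sum(rate)``. Every column with at least one
    nonzero count sums to exactly one million; an all-zero sample yields an
    all-zero column (with a warning).
    """
    lengths_kb = counts.lengths.to_numpy(dtype=float) / 1000.0
    rate = counts.counts.to_numpy(dtype=float) / lengths_kb[:, None]
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        logger.warning(
            "all-zero sample column(s) in TPM: %s",
            [s for s, z in zip(counts.sample_ids, zero_cols) if z],
        )
    safe = np.where(zero_cols, 1.0, colsum)
    tpm = 1e6 * rate / safe[None, :]
    tpm[:, zero_cols] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.counts.index, columns=counts.counts.columns),
        unit="TPM",
    )


def compute_rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    ``RPKM_g = 1e9 * count_g / (length_g(bp) * total_counts_in_sample)``.
    """
    lengths = counts.lengths.to_numpy(dtype=float)
    mat = counts.counts.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    zero_cols = libsize == 0
    if zero_cols.any():
        logger.warning(
            "all-zero sample column(s) in RPKM: %s",
            [s for s, z in zip(counts.sample_ids, zero_cols) if z],
        )
    safe = np.where(zero_cols, 1.0, libsize)
    rpkm = 1e9 * mat / (lengths[:, None] * safe[None, :])
    rpkm[:, zero_cols] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns),
        unit="RPKM",
    )


def filter_expressed(
    rpkm: ExpressionMatrix,
    floor: float = DEFAULT_EXPRESSION_FLOOR,
    scope: FloorScope = "any",
    samples: SampleSheet | None = None,
    sample_subset: list[str] | None = None,
) -> set[str]:
    """Genes considered expressed: RPKM strictly above ``floor``.

    ``scope`` controls how the floor is applied across the samples of the
    contrast: ``"any"`` retains a gene expressed in at least one sample
    (default), ``"all"`` requires every sample, ``"condition-mean"`` requires
    the per-condition mean RPKM to exceed the floor in at least one
    condition (needs ``samples``). A gene at exactly the floor is excluded:
    the rule is a strict ``>``.
    """
    if rpkm.unit != "RPKM":
        raise InputError(f"expression floor is defined on RPKM, got {rpkm.unit}")
    values = rpkm.values
    if sample_subset is not None:
        values = values[sample_subset]
    if scope == "any":
        keep = (values > floor).any(axis=1)
    elif scope == "all":
        keep = (values > floor).all(axis=1)
    elif scope == "condition-mean":
        if samples is None:
            raise InputError("condition-mean scope requires a sample sheet")
        sheet = samples.table.set_index("sample")["condition"]
        conds = sheet.reindex(values.columns)
        if conds.isna().any():
            raise InputError("samples missing from sample sheet")
        keep = pd.Series(False, index=values.index)
        for cond in conds.unique():
            cols = values.columns[(conds == cond).to_numpy()]
            keep |= values[cols].mean(axis=1) > floor
    else:  # pragma: no cover - guarded by Literal type
        raise InputError(f"unknown floor scope: {scope}")
    return set(values.index[keep])


# ---------------------------------------------------------------------------
# TSV I/O (formats shared with the synthetic-data writer)

def read_counts(counts_path: str | Path, lengths_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts, lengths)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t"))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path, unit: Literal["TPM", "RPKM"]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0), unit=unit)
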