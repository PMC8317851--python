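"""Expression / clinical data containers, TSV readers, cohort alignment, normalization.

Expression files are plain TSV: first column gene IDs, first row sample IDs,
nonnegative numeric body.  Clinical files are TSV with a header carrying at
least ``sample_id``, ``os_time`` (days) and ``os_event`` (1 = dead); any
further columns are kept as covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("survgate")

REQUIRED_CLINICAL = ("sample_id", "os_time", "os_event")
#: canonical covariate column names recognised downstream
CANONICAL_COVARIATES = ("age", "mycn", "stage", "inss_risk", "gender")


class DataValidationError(ValueError):
    """Input data violates a structural invariant (duplicate IDs, bad values)."""


@dataclass
class ExpressionMatrix:
    """Genes x samples nonnegative expression values.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifier lists.
    values
        ``(len(gene_ids), len(sample_ids))`` float array, finite and >= 0.
    normalized
        True once per-gene min-max scaling has been applied (entries in [0, 1]).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataValidationError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("duplicate sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("non-finite expression values")
        if np.any(self.values < 0):
            raise DataValidationError("negative expression values")
        if self.normalized and (self.values.max(initial=0.0) > 1.0 + 1e-12):
            raise DataValidationError("normalized matrix has entries > 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[rows], self.normalized
        )

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids), list(samples), self.values[:, cols], self.normalized
        )


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus optional covariates.

    ``data`` is indexed by sample_id and carries ``os_time`` (nonnegative,
    days), ``os_event`` in {0, 1} and any further covariate columns
    (``efs_time``/``efs_event`` when present are validated the same way).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise DataValidationError("clinical table lacks sample_id")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise DataValidationError("duplicate sample_id in clinical table")
        for col in ("os_time", "os_event"):
            if col not in df.columns:
                raise DataValidationError(f"clinical table missing required column {col!r}")
        n_missing = df["os_time"].isna().sum() + (df["os_time"].notna() & df["os_event"].isna()).sum()
        keep = df["os_time"].notna() & df["os_event"].notna()
        if not keep.all():
            logger.warning("dropping %d clinical rows with missing os_time/os_event", int((~keep).sum()))
            df = df.loc[keep]
        for ecol in ("os_event", "efs_event"):
            if ecol in df.columns:
                vals = df[ecol].dropna()
                if not vals.isin([0, 1]).all():
                    raise DataValidationError(f"{ecol} values outside {{0,1}}")
        if (df["os_time"] < 0).any():
            raise DataValidationError("negative os_time")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def os_time(self) -> np.ndarray:
        return self.data["os_time"].to_numpy(dtype=float)

    @property
    def os_event(self) -> np.ndarray:
        return self.data["os_event"].to_numpy(dtype=int)

    @property
    def covariates(self) -> pd.DataFrame:
        drop = [c for c in ("os_time", "os_event", "efs_time", "efs_event") if c in self.data.columns]
        return self.data.drop(columns=drop)

    def subset(self, samples: list[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())


def read_expression(path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV into an (unnormalized) :class:`ExpressionMatrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate gene IDs in {path}: {dups[:5]}")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise DataValidationError(
            f"malformed numeric cell in {path} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(list(df.index), list(df.columns), body.to_numpy(dtype=float))


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV (``sample_id``, ``os_time``, ``os_event``, covariates...)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"sample_id": str})
    for col in REQUIRED_CLINICAL:
        if col not in df.columns:
            raise DataValidationError(f"clinical file {path} missing required column {col!r}")
    return ClinicalTable(df)


def align_cohort(expr: ExpressionMatrix, clin: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both tables to their shared samples, in expression-matrix order."""
    shared = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if not shared:
        raise DataValidationError("expression and clinical tables share no sample IDs")
    dropped = (expr.n_samples - len(shared)) + (len(clin.sample_ids) - len(shared))
    if dropped:
        logger.info("align_cohort: dropped %d unmatched samples", dropped)
    return expr.subset_samples(shared), clin.subset(shared)


def normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene min-max scaling to [0, 1]: f' = (f - min f) / (max f - min f).

    Constant genes (max = min) map to all zeros, with a warning: such a gene
    carries no class information and scores 0 in the chi-square screen anyway.
    """
    x = expr.values
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) normalized to all-zero", stacklevel=2
        )
    safe = np.where(span == 0, 1.0, span)
    out = (x - lo) / safe
    out[constant] = 0.0
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), out, normalized=True)
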