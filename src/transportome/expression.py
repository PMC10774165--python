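"""Expression-matrix handling and relative qPCR quantification.

The expression side of the workflow has two jobs: (i) carry a genes x
induction-conditions matrix of transcript abundances through the log /
z-score transforms used before correlation clustering, and (ii) turn raw
qPCR threshold-cycle (Ct) tables into fold changes with the 2^-ddCT method,
normalising the target gene to a reference gene (actin in the motivating
experiments) and a calibrator group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "QpcrTable",
    "DdctResult",
    "log_transform",
    "standardize_rows",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x conditions matrix of expression values (arbitrary units).

    Parameters
    ----------
    data :
        DataFrame with gene labels as the index and condition labels as the
        columns.  Values must be finite; pre-transform values must be >= 0.
    constant_rows :
        Labels of rows that were constant when a variance-destroying
        transform (row standardisation) was applied.  Downstream correlation
        code treats these rows as having undefined Pearson r.
    """

    data: pd.DataFrame
    constant_rows: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene labels in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate condition labels in expression matrix")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def conditions(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @classmethod
    def from_arrays(
        cls, genes, conditions, values, constant_rows=frozenset()
    ) -> "ExpressionMatrix":
        df = pd.DataFrame(np.asarray(values, dtype=float), index=list(genes), columns=list(conditions))
        return cls(df, frozenset(constant_rows))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df.astype(float))

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2-transform every cell: value <- log2(value + pseudocount).

    The base is immaterial for Pearson correlation (it is an affine map of
    the natural log) but base 2 is the convention for expression data.
    """
    vals = m.values + pseudocount
    if np.any(vals <= 0):
        raise ValueError("log_transform: value + pseudocount <= 0")
    out = pd.DataFrame(np.log2(vals), index=m.data.index, columns=m.data.columns)
    return replace(m, data=out)


def standardize_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """z-score each row: (row - mean) / sd, sample sd (ddof=1).

    Constant rows cannot be standardised; they are mapped to all-zeros and
    recorded in ``constant_rows`` so that correlation code can flag them
    instead of producing NaNs silently.
    """
    if m.data.shape[1] < 2:
        raise ValueError("standardize_rows requires >= 2 conditions")
    vals = m.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    out = (vals - mean) / sd
    out[constant] = 0.0
    flagged = m.constant_rows | frozenset(np.asarray(m.genes)[constant])
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), flagged
    )


@dataclass(frozen=True)
class QpcrTable:
    """Long-format qPCR Ct table.

    One row per (sample, gene) with the three technical-replicate Ct values.
    ``group`` is "treatment" or "calibrator"; ``gene`` is "target" or
    "reference".  Every sample must have both a target and a reference row.
    """

    data: pd.DataFrame  # columns: sample_id, group, gene, ct1, ct2, ct3

    REQUIRED = ("sample_id", "group", "gene", "ct1", "ct2", "ct3")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"qPCR table missing columns: {missing}")
        bad_group = set(self.data["group"]) - {"treatment", "calibrator"}
        if bad_group:
            raise ValueError(f"unknown groups in qPCR table: {sorted(bad_group)}")
        bad_gene = set(self.data["gene"]) - {"target", "reference"}
        if bad_gene:
            raise ValueError(f"unknown gene roles in qPCR table: {sorted(bad_gene)}")
        for sid, sub in self.data.groupby("sample_id"):
            roles = set(sub["gene"])
            if roles != {"target", "reference"}:
                raise ValueError(
                    f"sample {sid!r} must have exactly target and reference rows"
                )

    @classmethod
    def from_csv(cls, path) -> "QpcrTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class DdctResult:
    fold_change: float
    ddct: float
    dct_mean: dict[str, float]  # per group mean of per-sample dCT
    se_dct: dict[str, float]  # per group standard error of per-sample dCT


def ddct_fold_change(q: QpcrTable) -> DdctResult:
    """Relative quantification by the 2^-ddCT method.

    Per sample: dCT = mean(target Ct triplicate) - mean(reference Ct
    triplicate).  ddCT = mean_treatment(dCT) - mean_calibrator(dCT); the
    fold change of the target, normalised to the reference gene and relative
    to the calibrator group, is 2^-ddCT.  The per-group standard error is
    computed on the per-sample dCT values (sample sd / sqrt(n)), the scale on
    which qPCR error is approximately additive.
    """
    ct_cols = ["ct1", "ct2", "ct3"]
    mean_ct = q.data.assign(ct=q.data[ct_cols].mean(axis=1))
    wide = mean_ct.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct"
    ).reset_index()
    dct = wide["target"] - wide["reference"]
    groups = wide["group"]
    dct_mean: dict[str, float] = {}
    se_dct: dict[str, float] = {}
    for g in ("treatment", "calibrator"):
        vals = dct[groups == g].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"ddct_fold_change: no samples in group {g!r}")
        dct_mean[g] = float(vals.mean())
        se_dct[g] = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    ddct = dct_mean["treatment"] - dct_mean["calibrator"]
    return DdctResult(float(2.0 ** (-ddct)), float(ddct), dct_mean, se_dct)
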