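"""Relative quantification and preprocessing of qPCR Ct tables.

Raw cycle-threshold (Ct) tables are turned into analysis-ready log2
expression matrices in four steps: ddCt relative quantification against a
housekeeping-gene baseline and a calibrator sample, detection filtering,
log2 transform with imputation, and pairwise Pearson correlation with
Bonferroni-Holm correction.

The ddCt model assumes an amplification efficiency of 2, so one PCR cycle
corresponds to a twofold change in template quantity.  Normalising to the
arithmetic mean of the housekeeping Ct values is then exactly equivalent to
dividing by the geometric mean of their linear quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CtTable",
    "ExpressionMatrix",
    "compute_rq",
    "filter_detected",
    "log2_and_impute",
    "pairwise_correlation",
]


@dataclass
class CtTable:
    """Samples x (signature + housekeeping) matrix of raw Ct values.

    Missing / undetermined reactions are NaN.  Exactly one sample is the
    calibrator to which all relative quantities refer.
    """

    ct: pd.DataFrame
    hkg_names: tuple[str, ...]
    calibrator_id: str

    def __post_init__(self) -> None:
        self.hkg_names = tuple(self.hkg_names)
        if len(self.hkg_names) == 0:
            raise ValueError("at least one housekeeping gene is required")
        missing_hkg = [h for h in self.hkg_names if h not in self.ct.columns]
        if missing_hkg:
            raise ValueError(f"housekeeping genes not in table: {missing_hkg}")
        if self.calibrator_id not in self.ct.index:
            raise ValueError(f"calibrator sample {self.calibrator_id!r} not found")
        values = self.ct.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (values <= 0) | (values > 45.0)
        if np.any(bad & ~np.isnan(values)):
            raise ValueError("Ct values must lie in (0, 45] or be missing")

    @property
    def gene_names(self) -> list[str]:
        return [c for c in self.ct.columns if c not in self.hkg_names]


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values, either relative quantities or log2.

    ``kind`` records the provenance of the values ("rq" for linear relative
    quantities, "log2" for their binary log).  Missing cells are NaN.
    """

    values: pd.DataFrame
    kind: str = "rq"

    def __post_init__(self) -> None:
        if self.kind not in ("rq", "log2"):
            raise ValueError(f"kind must be 'rq' or 'log2', got {self.kind!r}")
        if self.kind == "rq":
            vals = self.values.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if np.any((vals <= 0) & ~np.isnan(vals)):
                    raise ValueError("relative quantities must be > 0 where present")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


def compute_rq(ct: CtTable, detection_limit_ct: float | None = None) -> ExpressionMatrix:
    """ddCt relative quantification.

    For sample ``s`` and gene ``g``::

        dCt(s, g)  = Ct(s, g) - mean over HKGs of Ct(s, .)
        ddCt(s, g) = dCt(s, g) - dCt(calibrator, g)
        RQ(s, g)   = 2 ** (-ddCt(s, g))

    The calibrator row is therefore 1 for every gene.  Gene Ct values at or
    above ``detection_limit_ct`` (if given) are treated as undetermined and
    reported missing; samples with any missing housekeeping Ct cannot be
    normalised and have all their RQs flagged missing (with a warning),
    except that a missing housekeeping Ct in the calibrator is an error.
    """
    genes = ct.gene_names
    gene_ct = ct.ct[genes].astype(float).copy()
    hkg_ct = ct.ct[list(ct.hkg_names)].astype(float)

    if hkg_ct.loc[ct.calibrator_id].isna().any():
        raise ValueError("calibrator sample has missing housekeeping Ct values")
    if detection_limit_ct is not None:
        gene_ct = gene_ct.mask(gene_ct >= detection_limit_ct)

    hkg_mean = hkg_ct.mean(axis=1, skipna=False)
    bad_samples = hkg_mean.index[hkg_mean.isna()]
    if len(bad_samples) > 0:
        warnings.warn(
            f"{len(bad_samples)} sample(s) with missing housekeeping Ct; "
            f"their relative quantities are reported missing: {list(bad_samples)}",
            stacklevel=2,
        )

    dct = gene_ct.sub(hkg_mean, axis=0)
    ddct = dct.sub(dct.loc[ct.calibrator_id], axis=1)
    rq = np.power(2.0, -ddct)
    return ExpressionMatrix(values=rq, kind="rq")


def filter_detected(
    expr: ExpressionMatrix,
    signature: list[str] | None = None,
    max_undetected_frac: float = 0.75,
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes that are undetected in more than ``max_undetected_frac``
    of samples.

    "Undetected" means a missing relative quantity, which covers both failed
    reactions and Ct values masked at the detection limit by
    :func:`compute_rq`.  Returns the filtered matrix and the exclusion list.
    """
    if signature is None:
        signature = expr.genes
    missing_cols = [g for g in signature if g not in expr.values.columns]
    if missing_cols:
        raise KeyError(f"signature genes absent from matrix: {missing_cols}")

    frac_missing = expr.values[signature].isna().mean(axis=0)
    excluded = [g for g in signature if frac_missing[g] > max_undetected_frac]
    retained = [g for g in signature if g not in excluded]
    if not retained:
        raise ValueError(
            "all genes excluded by the detection rule "
            f"(threshold {max_undetected_frac:.0%}); check the input table"
        )
    return ExpressionMatrix(expr.values[retained].copy(), kind=expr.kind), excluded


def log2_and_impute(
    expr: ExpressionMatrix,
    method: str = "median",
    seed: int | None = None,
) -> ExpressionMatrix:
    """log2-transform relative quantities and impute remaining missing cells.

    ``method="median"`` (default) fills each gene's missing cells with the
    median of its observed log2 values.  ``method="iterative"`` uses seeded
    round-robin regression imputation (each gene regressed on the others),
    which approximates chained-equations behaviour with a single completed
    data set.
    """
    if expr.kind != "rq":
        raise ValueError("log2_and_impute expects a relative-quantity matrix")
    log2 = np.log2(expr.values.astype(float))

    if log2.isna().all(axis=0).any():
        empty = list(log2.columns[log2.isna().all(axis=0)])
        raise ValueError(f"genes with no observed values cannot be imputed: {empty}")

    if method == "median":
        filled = log2.fillna(log2.median(axis=0))
    elif method == "iterative":
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        imp = IterativeImputer(random_state=seed, sample_posterior=False, max_iter=25)
        filled = pd.DataFrame(
            imp.fit_transform(log2.to_numpy()), index=log2.index, columns=log2.columns
        )
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return ExpressionMatrix(values=filled, kind="log2")


def pairwise_correlation(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    strong_r: float = 0.6,
) -> pd.DataFrame:
    """All-pairs Pearson correlation with Bonferroni-Holm adjustment.

    Returns one row per unordered gene pair with columns ``gene_a, gene_b,
    r, p, p_holm, significant, strong``.  Pairs involving a zero-variance
    gene get NaN correlation and are excluded from the Holm family.
    """
    values = expr.values
    if values.isna().any().any():
        raise ValueError("correlation requires a complete matrix; impute first")
    if len(values) < 3:
        raise ValueError("at least 3 samples are required")

    genes = list(values.columns)
    sds = values.std(axis=0, ddof=0)
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            if sds[ga] == 0 or sds[gb] == 0:
                rows.append((ga, gb, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(values[ga], values[gb])
            rows.append((ga, gb, float(r), float(p)))
    report = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"])

    report["p_holm"] = np.nan
    ok = report["p"].notna()
    if ok.any():
        _, p_adj, _, _ = multipletests(report.loc[ok, "p"], method="holm")
        report.loc[ok, "p_holm"] = p_adj
    report["significant"] = report["p_holm"] <= alpha
    report["strong"] = report["significant"] & (report["r"] > strong_r)
    return report
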