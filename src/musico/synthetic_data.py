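"""Synthetic inputs with planted, recoverable structure.

Patient-level cohort data of the kind this pipeline analyses are not
publicly deposited, so every input is emulated here: a survival cohort with
clinical covariates and co-correlated log-normal gene expression driving a
proportional-hazards outcome; raw Ct tables consistent with the ddCt model;
tissue expression matrices with genes planted to co-vary with designated
targets; and GMT gene-set collections with one planted enriched set.

The cohort defaults mirror the study conditions the pipeline is built for:
186 patients with advanced serous ovarian carcinoma, ~29 % deaths during
follow-up, 21 modelled signature genes with a correlated immune block
(pairwise r around 0.5-0.7 among the leukocyte-associated genes), and six
clinical covariates (age, FIGO stage, grading, histology, residual disease,
peritoneal carcinomatosis) with the codings described in
:mod:`musico.signature`.  Event times come from an exponential
proportional-hazards model; censoring is uniform on an administrative
horizon that is tuned by bisection to reach the target event fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxph import SurvivalOutcome
from .network import GeneSetCollection
from .qpcr import CtTable, ExpressionMatrix
from .signature import CLINICAL_VARIABLES, MODELED_GENES, TISSUE_HKGS

__all__ = [
    "CohortSpec",
    "Cohort",
    "CtSpec",
    "TissueMatrixSpec",
    "default_gene_correlation",
    "default_planted_betas",
    "generate_cohort",
    "generate_ct_table",
    "generate_tissue_matrix",
    "generate_gene_sets",
]

#: Genes in the correlated leukocyte/immune block (pairwise r ~ 0.55).
IMMUNE_BLOCK = (
    "PTPRC",
    "APOBEC3C",
    "APOBEC3D",
    "APOBEC3G",
    "APOBEC3H",
    "NUGGC",
    "PRDM1",
    "AICDA",
)

#: Genes in the correlated DNA-repair / ID block.
REPAIR_BLOCK = ("ID2", "ID3", "XRCC5", "XRCC6", "NANOG")


def default_gene_correlation(gene_names=MODELED_GENES) -> pd.DataFrame:
    """Block-structured correlation matrix on the log2 scale.

    Weak global correlation (0.10) with stronger planted blocks: an immune
    block at 0.55, a repair/ID block at 0.45 with ID2-ID3 and XRCC5-XRCC6
    at 0.65, and PAX5-FCER2 at 0.60; the estrogen receptors are left near
    independent of the rest.
    """
    genes = list(gene_names)
    n = len(genes)
    corr = np.full((n, n), 0.10)

    def set_pair(a, b, r):
        if a in genes and b in genes:
            i, j = genes.index(a), genes.index(b)
            corr[i, j] = corr[j, i] = r

    def set_block(block, r):
        members = [g for g in block if g in genes]
        for a in members:
            for b in members:
                if a != b:
                    set_pair(a, b, r)

    set_block(IMMUNE_BLOCK, 0.55)
    set_block(REPAIR_BLOCK, 0.45)
    set_pair("ID2", "ID3", 0.65)
    set_pair("XRCC5", "XRCC6", 0.65)
    set_pair("PAX5", "FCER2", 0.60)
    for esr in ("ESR1", "ESR2"):
        if esr in genes:
            i = genes.index(esr)
            corr[i, :] = corr[:, i] = 0.02
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


def default_planted_betas(gene_names=MODELED_GENES) -> pd.Series:
    """Planted per-SD log hazard ratios for clinical and gene variables.

    Magnitudes follow the typical standardised effects seen in advanced
    serous ovarian carcinoma: peritoneal carcinomatosis and age dominate the
    clinical block; among the genes, ID3 and AID carry adverse effects and
    APOBEC3G a protective one.
    """
    betas = {v: 0.0 for v in (*CLINICAL_VARIABLES, *gene_names)}
    betas.update(
        {
            "peritoneal": 0.45,
            "age": 0.40,
            "histology": 0.25,
            "figo": 0.25,
            "residual": 0.22,
            "grading": 0.20,
        }
    )
    for gene, b in (
        ("ID3", 0.60),
        ("AICDA", 0.40),
        ("APOBEC3G", -0.40),
        ("PTPRC", 0.40),
        ("ID2", -0.15),
        ("ESR1", -0.25),
    ):
        if gene in betas:
            betas[gene] = b
    return pd.Series(betas)


#: Clinical covariate marginals: age ~ truncated normal; the rest are the
#: category frequencies of an advanced-stage serous ovarian cancer cohort.
DEFAULT_CLINICAL_SPEC: dict = {
    "age": {"dist": "normal", "mean": 57.0, "sd": 11.0, "min": 26.0, "max": 85.0},
    "figo": {"dist": "ordinal", "levels": (0, 1, 2), "p": (0.048, 0.796, 0.156)},
    "grading": {"dist": "bernoulli", "p": 0.737},
    "histology": {"dist": "bernoulli", "p": 0.118},
    "residual": {"dist": "bernoulli", "p": 0.290},
    "peritoneal": {"dist": "bernoulli", "p": 0.500},
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic survival cohort generator."""

    n_patients: int = 186
    gene_names: tuple = MODELED_GENES
    gene_correlation: pd.DataFrame | None = None
    gene_sd: float = 1.5  # marginal SD of log2 expression
    planted_betas: pd.Series | None = None
    clinical_spec: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_SPEC))
    # baseline hazard: None (default) tunes the rate by bisection so the
    # realised event fraction matches the target within the fixed
    # administrative horizon; a number fixes the rate instead
    baseline_hazard: float | None = None
    weibull_shape: float = 1.0  # 1 = exponential event times
    horizon: float = 49.0  # administrative follow-up in months
    target_event_fraction: float = 0.29
    seed: int = 0

    def resolve(self):
        corr = (
            default_gene_correlation(self.gene_names)
            if self.gene_correlation is None
            else self.gene_correlation
        )
        betas = (
            default_planted_betas(self.gene_names)
            if self.planted_betas is None
            else self.planted_betas
        )
        return corr, betas


@dataclass
class Cohort:
    """A generated cohort: clinical table, log2 expression, outcome."""

    clinical: pd.DataFrame
    expression_log2: pd.DataFrame
    outcome: SurvivalOutcome
    true_linear_predictor: pd.Series
    horizon: float

    @property
    def expression_rq(self) -> pd.DataFrame:
        return np.power(2.0, self.expression_log2)

    def model_matrix(self, variables: str) -> pd.DataFrame:
        """Design matrix for one variable set: clinics | genes | combined."""
        if variables == "clinics":
            return self.clinical.copy()
        if variables == "genes":
            return self.expression_log2.copy()
        if variables == "combined":
            return pd.concat([self.clinical, self.expression_log2], axis=1)
        raise ValueError(f"unknown variable set {variables!r}")


def _draw_clinical(spec: dict, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name in CLINICAL_VARIABLES:
        cfg = spec[name]
        if cfg["dist"] == "normal":
            vals = rng.normal(cfg["mean"], cfg["sd"], n)
            vals = np.clip(vals, cfg["min"], cfg["max"])
        elif cfg["dist"] == "ordinal":
            vals = rng.choice(cfg["levels"], size=n, p=cfg["p"])
        elif cfg["dist"] == "bernoulli":
            vals = (rng.uniform(size=n) < cfg["p"]).astype(float)
        else:
            raise ValueError(f"unknown clinical distribution {cfg['dist']!r}")
        cols[name] = np.asarray(vals, dtype=float)
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from the proportional-hazards generator.

    The linear predictor is ``planted_betas . standardized covariates``;
    event times are Weibull (exponential by default) with that relative
    hazard; the censoring time is uniform on ``[0, horizon]`` with the
    horizon found by bisection so that the realised event fraction matches
    the target in expectation.  Identical seeds give identical cohorts.
    """
    corr, betas = spec.resolve()
    genes = list(spec.gene_names)
    if list(corr.index) != genes or list(corr.columns) != genes:
        corr = corr.loc[genes, genes]
    cmat = corr.to_numpy(dtype=float)
    if not np.allclose(cmat, cmat.T):
        raise ValueError("gene correlation matrix must be symmetric")
    if not np.allclose(np.diag(cmat), 1.0):
        raise ValueError("gene correlation matrix must have unit diagonal")
    try:
        chol = np.linalg.cholesky(cmat)
    except np.linalg.LinAlgError as err:
        eigmin = float(np.linalg.eigvalsh(cmat).min())
        raise ValueError(
            f"gene correlation matrix is not positive definite "
            f"(smallest eigenvalue {eigmin:.3g})"
        ) from err
    if not 0 < spec.target_event_fraction < 1:
        raise ValueError("target event fraction must lie in (0, 1)")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    z = rng.standard_normal((n, len(genes)))
    expr = pd.DataFrame(z @ chol.T * spec.gene_sd, columns=genes)
    clinical = _draw_clinical(spec.clinical_spec, n, rng)

    X = pd.concat([clinical, expr], axis=1)
    missing = [v for v in X.columns if v not in betas.index]
    if missing:
        raise ValueError(f"planted_betas lacks entries for: {missing}")
    sds = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Xs = (X - X.mean(axis=0)) / sds
    lp = Xs.to_numpy() @ betas[X.columns].to_numpy()

    u = rng.uniform(size=n)
    u_cens = rng.uniform(size=n)
    cens = u_cens * spec.horizon  # independent uniform censoring on [0, horizon]

    def event_times(rate):
        return (-np.log(u) / (rate * np.exp(lp))) ** (1.0 / spec.weibull_shape)

    if spec.baseline_hazard is not None:
        rate = spec.baseline_hazard
    else:
        # bisect the baseline rate so the realised event fraction hits the
        # target inside the fixed administrative horizon
        lo_r, hi_r = 1e-8, 10.0
        for _ in range(200):
            mid = 0.5 * (lo_r + hi_r)
            if np.mean(event_times(mid) <= cens) < spec.target_event_fraction:
                lo_r = mid
            else:
                hi_r = mid
        rate = 0.5 * (lo_r + hi_r)

    t_event = event_times(rate)
    time = np.minimum(t_event, cens)
    event = (t_event <= cens).astype(int)
    time = np.maximum(time, 1e-6)

    return Cohort(
        clinical=clinical,
        expression_log2=expr,
        outcome=SurvivalOutcome(time=time, event=event, label="OS"),
        true_linear_predictor=pd.Series(lp, name="true_lp"),
        horizon=spec.horizon,
    )


@dataclass
class CtSpec:
    """Parameters of the synthetic Ct-table generator."""

    n_samples: int = 24
    gene_names: tuple = MODELED_GENES
    hkg_names: tuple = TISSUE_HKGS
    calibrator_id: str = "CAL"
    true_rq: pd.DataFrame | None = None  # samples x genes, calibrator row incl.
    ct_noise_sd: float = 0.0
    undetermined_ct: float = 40.0
    seed: int = 0

    def sample_ids(self) -> list[str]:
        if self.true_rq is not None:
            return list(self.true_rq.index)
        ids = [f"S{i + 1:03d}" for i in range(self.n_samples - 1)]
        return [self.calibrator_id, *ids]


def generate_ct_table(spec: CtSpec) -> tuple[CtTable, pd.DataFrame]:
    """Ct values consistent with the ddCt model at efficiency 2.

    ``Ct(s, g) = offset_g + loading_s - log2(true_rq(s, g)) + noise``, with
    housekeeping genes carrying the per-sample loading only.  With zero
    noise, :func:`musico.qpcr.compute_rq` recovers ``true_rq`` exactly up
    to normalisation by the calibrator row.  Cts above ``undetermined_ct``
    are reported missing.  Returns the table together with the ground-truth
    RQ matrix (relative to the calibrator row).
    """
    if spec.ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    overlap = set(spec.hkg_names) & set(spec.gene_names)
    if overlap:
        raise ValueError(f"housekeeping genes overlap the signature: {overlap}")
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_ids()
    if spec.calibrator_id not in samples:
        raise ValueError("calibrator sample missing from true_rq index")
    genes = list(spec.gene_names)

    if spec.true_rq is None:
        rq = pd.DataFrame(
            np.power(2.0, rng.normal(0.0, 1.5, (len(samples), len(genes)))),
            index=samples,
            columns=genes,
        )
        rq.loc[spec.calibrator_id] = 1.0
    else:
        rq = spec.true_rq.astype(float).copy()
        if (rq.to_numpy() <= 0).any():
            raise ValueError("true_rq must be strictly positive")

    offsets = pd.Series(rng.uniform(22.0, 30.0, len(genes)), index=genes)
    hkg_offsets = pd.Series(
        rng.uniform(18.0, 22.0, len(spec.hkg_names)), index=list(spec.hkg_names)
    )
    loading = pd.Series(rng.normal(0.0, 0.5, len(samples)), index=samples)

    ct_genes = (-np.log2(rq)).add(offsets, axis=1).add(loading, axis=0)
    ct_hkg = pd.DataFrame(
        np.tile(hkg_offsets.to_numpy(), (len(samples), 1)),
        index=samples,
        columns=list(spec.hkg_names),
    ).add(loading, axis=0)
    ct = pd.concat([ct_genes, ct_hkg], axis=1)
    if spec.ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.ct_noise_sd, ct.shape)
    ct = ct.mask(ct > spec.undetermined_ct)
    ct = ct.clip(lower=1e-3)

    truth = rq.div(rq.loc[spec.calibrator_id], axis=1)
    table = CtTable(ct=ct, hkg_names=tuple(spec.hkg_names), calibrator_id=spec.calibrator_id)
    return table, truth


@dataclass
class TissueMatrixSpec:
    """Parameters of the tissue expression-matrix generator."""

    n_samples: int = 530
    n_background_genes: int = 400
    target_genes: tuple = ("APOBEC3G", "ESR1", "ID2", "ID3", "PTPRC")
    n_coregulated_per_target: int = 20
    planted_r: float = 0.8
    hkg_block: int = 45
    noise_sd: float = 1.0
    seed: int = 0

    def planted_genes(self, target: str) -> list[str]:
        return [f"{target}_CO{i + 1:02d}" for i in range(self.n_coregulated_per_target)]

    def background_genes(self) -> list[str]:
        return [f"BG{i + 1:04d}" for i in range(self.n_background_genes)]

    def hkg_genes(self) -> list[str]:
        return [f"HKG{i + 1:02d}" for i in range(self.hkg_block)]


def generate_tissue_matrix(spec: TissueMatrixSpec) -> ExpressionMatrix:
    """Expression matrix with genes planted to co-vary with each target.

    Planted genes are ``r * target + sqrt(1 - r^2) * noise`` on the
    standardised scale; housekeeping columns share one latent factor with
    tiny independent noise so that their pairwise correlations exceed 0.99;
    background genes are independent.  All columns receive gene-specific
    log2-intensity offsets.
    """
    if not -1.0 <= spec.planted_r <= 1.0:
        raise ValueError("planted_r must lie in [-1, 1]")
    if spec.n_coregulated_per_target >= spec.n_background_genes:
        raise ValueError("need more background genes than planted genes per target")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"A{i + 1:04d}" for i in range(n)]

    cols: dict[str, np.ndarray] = {}
    for target in spec.target_genes:
        t = rng.standard_normal(n)
        cols[target] = t
        r = spec.planted_r
        for name in spec.planted_genes(target):
            eps = rng.standard_normal(n)
            cols[name] = r * t + np.sqrt(max(0.0, 1.0 - r * r)) * eps * spec.noise_sd

    latent = rng.standard_normal(n)
    for name in spec.hkg_genes():
        cols[name] = latent + 0.03 * rng.standard_normal(n)

    for name in spec.background_genes():
        cols[name] = rng.standard_normal(n)

    mat = pd.DataFrame(cols, index=samples)
    offsets = rng.uniform(4.0, 12.0, mat.shape[1])
    mat = mat + offsets
    return ExpressionMatrix(values=mat, kind="log2")


def generate_gene_sets(
    universe,
    n_sets: int,
    planted_set,
    seed: int = 0,
    set_size_range: tuple[int, int] = (10, 50),
) -> GeneSetCollection:
    """Random gene-set collection plus one set containing the planted genes."""
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    planted = list(dict.fromkeys(planted_set))
    stray = [g for g in planted if g not in universe]
    if stray:
        raise ValueError(f"planted genes outside the universe: {stray[:5]}")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {"PLANTED_SET": planted}
    descriptions = {"PLANTED_SET": "synthetic planted enriched set"}
    lo, hi = set_size_range
    hi = min(hi, len(universe))
    lo = min(lo, hi)
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        name = f"RANDOM_SET_{i + 1:03d}"
        sets[name] = members
        descriptions[name] = "synthetic random set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
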