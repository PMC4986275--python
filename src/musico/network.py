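"""Co-expression extraction, gene-set enrichment and overlap ranking.

Reconstructs the pathways associated with the prognostic target genes from
a tissue expression matrix (samples x genes, log2 intensities):

1. per target gene, restrict to the samples in the lowest and highest
   expression deciles of the target (extreme-group selection removes genes
   that track the target only through non-modulated baseline expression);
2. quality-check the subset via housekeeping-gene homogeneity (all pairwise
   Pearson r above a threshold);
3. extract the top-k genes co-expressed with the target over the subset;
4. pool the per-target lists into a "mixed" list capturing the joint
   signature signal;
5. test each gene set of a GMT collection for over-representation with the
   right-tailed Fisher exact test;
6. rank the enriched terms by two complementary algorithms: the top mixed
   terms annotated with their per-target positions (algorithm I), and the
   mixed-significant terms ordered by how many per-target lists also
   contain them, ties broken by the mixed p-value (algorithm II).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "CoexpressionList",
    "read_gmt",
    "write_gmt",
    "select_extreme_samples",
    "hkg_quality_check",
    "top_coexpressed",
    "build_mixed_list",
    "fisher_enrich",
    "rank_algorithm_I",
    "rank_algorithm_II",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.descriptions is None:
            self.descriptions = {name: "" for name in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out.update(members)
        return out


@dataclass
class CoexpressionList:
    """Genes ranked by Pearson correlation with one target gene."""

    target: str
    table: pd.DataFrame  # columns: gene, r
    samples: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def select_extreme_samples(
    matrix: pd.DataFrame, target: str, lo: float = 0.10, hi: float = 0.90
) -> pd.Series:
    """Samples in the extreme expression groups of the target gene.

    Rank-based: the ``floor(lo * n)`` samples with the lowest and the
    ``floor((1 - hi) * n)`` with the highest target expression are
    selected (at n = 530 this yields 53 + 53 = 106 samples).  Returns a
    Series of "low"/"high" labels indexed by the selected samples.
    """
    if target not in matrix.columns:
        raise KeyError(f"target gene {target!r} not in matrix")
    if not (0 < lo < hi < 1):
        raise ValueError("quantile thresholds must satisfy 0 < lo < hi < 1")
    values = matrix[target].to_numpy(dtype=float)
    n = len(values)
    # tolerant floor: (1 - 0.9) * 530 is 52.999... in floating point
    n_lo = int(np.floor(lo * n + 1e-9))
    n_hi = int(np.floor((1 - hi) * n + 1e-9))
    if n_lo < 1 or n_hi < 1:
        raise ValueError(f"too few samples (n={n}) for non-empty extreme groups")
    if np.ptp(values) == 0:
        raise ValueError(f"target {target!r} shows no expression modulation")
    order = np.argsort(values, kind="stable")
    low_idx = matrix.index[order[:n_lo]]
    high_idx = matrix.index[order[n - n_hi :]]
    return pd.Series(
        ["low"] * n_lo + ["high"] * n_hi,
        index=list(low_idx) + list(high_idx),
        name=f"{target}_group",
    )


def hkg_quality_check(
    matrix: pd.DataFrame, hkg_list, threshold: float = 0.99
) -> dict:
    """Housekeeping-gene homogeneity QC.

    Passes when every pairwise Pearson correlation among the housekeeping
    columns exceeds ``threshold``; otherwise the offending pairs are
    listed.  A failing check indicates sample-quality differences rather
    than intrinsic regulation of the target gene.
    """
    hkg_list = list(hkg_list)
    missing = [h for h in hkg_list if h not in matrix.columns]
    if missing:
        raise ValueError(f"housekeeping columns absent: {missing}")
    if len(hkg_list) < 2:
        raise ValueError("QC requires at least two housekeeping columns")
    corr = matrix[hkg_list].corr(method="pearson")
    iu = np.triu_indices(len(hkg_list), k=1)
    pair_r = corr.to_numpy()[iu]
    failing = [
        (hkg_list[i], hkg_list[j], float(corr.iloc[i, j]))
        for i, j in zip(*iu)
        if not corr.iloc[i, j] > threshold
    ]
    return {
        "pass": len(failing) == 0,
        "min_r": float(np.min(pair_r)),
        "median_r": float(np.median(pair_r)),
        "failing_pairs": failing,
        "threshold": threshold,
    }


def top_coexpressed(
    matrix: pd.DataFrame,
    subset,
    target: str,
    k: int = 50,
    use_abs: bool = False,
) -> CoexpressionList:
    """Top-k genes co-expressed with the target across the sample subset.

    Genes are ranked by signed Pearson r (descending) by default; set
    ``use_abs`` to rank by |r|.  Zero-variance genes are skipped.
    """
    samples = list(subset.index) if isinstance(subset, pd.Series) else list(subset)
    if len(samples) < 3:
        raise ValueError("at least 3 samples required for correlation")
    sub = matrix.loc[samples]
    target_vals = sub[target].to_numpy(dtype=float)
    if target_vals.std(ddof=0) == 0:
        raise ValueError(f"target {target!r} constant on the selected subset")

    others = [g for g in sub.columns if g != target]
    X = sub[others].to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=0)
    ok = sds > 0
    Xc = X[:, ok] - X[:, ok].mean(axis=0)
    tc = target_vals - target_vals.mean()
    r = (Xc * tc[:, None]).sum(axis=0) / (
        np.sqrt((Xc**2).sum(axis=0)) * np.sqrt((tc**2).sum())
    )
    table = pd.DataFrame({"gene": np.array(others)[ok], "r": r})
    key = table["r"].abs() if use_abs else table["r"]
    table = table.loc[key.sort_values(ascending=False, kind="stable").index]
    table = table.head(k).reset_index(drop=True)
    return CoexpressionList(target=target, table=table, samples=samples)


def build_mixed_list(lists: list[CoexpressionList]) -> list[str]:
    """Union of per-target co-expression lists, ordered by first appearance."""
    if not lists:
        raise ValueError("at least one co-expression list is required")
    seen: dict[str, None] = {}
    for cl in lists:
        for g in cl.genes:
            seen.setdefault(g, None)
    return list(seen)


def fisher_enrich(
    query,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Right-tailed Fisher exact test of each gene set against the query.

    The 2x2 table crosses query membership with set membership over the
    universe; the reported p is the hypergeometric upper tail
    ``P(overlap >= observed)``.  Sets are intersected with the universe
    first.  Results are sorted by ascending p with a significance flag at
    ``alpha``.
    """
    query = list(dict.fromkeys(query))
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query list")
    stray = [g for g in query if g not in universe]
    if stray:
        raise ValueError(f"query genes outside the universe: {stray[:5]}...")
    q = set(query)
    M = len(universe)
    rows = []
    for name, members in collection.sets.items():
        s = set(members) & universe
        overlap = sorted(q & s)
        x = len(overlap)
        # upper tail P(X >= x), X ~ Hypergeom(M, |set|, |query|)
        p = float(stats.hypergeom.sf(x - 1, M, len(s), len(q))) if s else 1.0
        rows.append((name, x, len(s), p, ",".join(overlap)))
    out = pd.DataFrame(
        rows, columns=["term", "overlap", "set_size", "p", "overlap_genes"]
    )
    out = out.sort_values("p", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["significant"] = out["p"] < alpha
    return out


def _significant_ranks(enrichment: pd.DataFrame) -> dict[str, int]:
    sig = enrichment[enrichment["significant"]]
    return dict(zip(sig["term"], sig["rank"]))


def rank_algorithm_I(
    mixed: pd.DataFrame,
    individuals: dict[str, pd.DataFrame],
    top: int = 10,
) -> pd.DataFrame:
    """Top mixed-list terms annotated with their per-target positions.

    Rows are the ``top`` significant terms of the mixed-list enrichment,
    by ascending p.  For each target gene the term's rank within that
    target's significant results is reported with a marker: "top10" when
    within the top ``top``, "outside" when significant but lower-ranked,
    "absent" when not significant for that target.  The summary column
    counts targets where the term lands within the top positions.
    """
    import warnings

    sig_mixed = mixed[mixed["significant"]]
    if sig_mixed.empty:
        warnings.warn("no significant mixed-list terms; empty table", stacklevel=2)
        cols = ["term", "mixed_p", "mixed_rank"]
        cols += [f"{t}_pos" for t in individuals] + [f"{t}_marker" for t in individuals]
        return pd.DataFrame(columns=cols + ["n_targets_top"])
    if len(sig_mixed) < top:
        warnings.warn(
            f"only {len(sig_mixed)} significant mixed terms (< {top}); using all",
            stacklevel=2,
        )
    sel = sig_mixed.head(top)
    ind_ranks = {t: _significant_ranks(df) for t, df in individuals.items()}

    rows = []
    for _, row in sel.iterrows():
        entry = {
            "term": row["term"],
            "mixed_p": row["p"],
            "mixed_rank": int(row["rank"]),
        }
        n_top = 0
        for t in individuals:
            pos = ind_ranks[t].get(row["term"])
            if pos is None:
                entry[f"{t}_pos"], entry[f"{t}_marker"] = pd.NA, "absent"
            elif pos <= top:
                entry[f"{t}_pos"], entry[f"{t}_marker"] = pos, "top10"
                n_top += 1
            else:
                entry[f"{t}_pos"], entry[f"{t}_marker"] = pos, "outside"
        entry["n_targets_top"] = n_top
        rows.append(entry)
    return pd.DataFrame(rows)


def rank_algorithm_II(
    mixed: pd.DataFrame,
    individuals: dict[str, pd.DataFrame],
    top: int = 10,
) -> pd.DataFrame:
    """Mixed-significant terms ranked by per-target overlap count.

    Candidate terms must be significant in the mixed-list enrichment
    (mandatory gate).  The overlap count is the number of targets in whose
    significant results the term appears; terms are ordered by overlap
    count descending (5/5 beats 4/5 regardless of p) and, within equal
    counts, by ascending mixed p.  The first ``top`` rows are returned.
    """
    import warnings

    sig_mixed = mixed[mixed["significant"]]
    if sig_mixed.empty:
        warnings.warn("no significant mixed-list terms; empty table", stacklevel=2)
        return pd.DataFrame(
            columns=["term", "mixed_p", "mixed_rank", "overlap_count", "targets"]
        )
    ind_sig = {t: set(df.loc[df["significant"], "term"]) for t, df in individuals.items()}
    rows = []
    for _, row in sig_mixed.iterrows():
        hit_targets = [t for t in individuals if row["term"] in ind_sig[t]]
        rows.append(
            {
                "term": row["term"],
                "mixed_p": row["p"],
                "mixed_rank": int(row["rank"]),
                "overlap_count": len(hit_targets),
                "targets": ",".join(hit_targets),
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["overlap_count", "mixed_p"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out.head(top)
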