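"""Signature-similarity scoring against an expression compendium.

Given a cohort, the signature profile is the per-gene median of the log2
relative expression across patients.  The profile is aligned by Pearson
correlation against every condition of a user-supplied compendium
(conditions x genes of log2 expression, with a per-condition array count);
conditions are ranked by a relative-similarity index, a positive rescaling
of the correlation (r divided by the mean r over included conditions) so
that values above 1 flag above-average resemblance.  The module also
extracts top-N co-expression lists for a target gene and symbol-level
overlaps between two such lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix

__all__ = [
    "Compendium",
    "SimilarityRanking",
    "CoexpressionList",
    "signature_profile",
    "rank_conditions",
    "coexpression_top_n",
    "list_overlap",
]


@dataclass
class Compendium:
    """Conditions x genes log2-expression profiles with array counts.

    Conditions backed by fewer than ``min_arrays`` arrays are excluded from
    ranking (flagged at construction).
    """

    profiles: pd.DataFrame
    n_arrays: pd.Series
    min_arrays: int = 15

    def __post_init__(self) -> None:
        if not self.profiles.index.equals(self.n_arrays.index):
            raise ValueError("profiles and n_arrays must share the condition index")
        self.excluded_small = list(self.profiles.index[self.n_arrays < self.min_arrays])

    @property
    def eligible(self) -> pd.DataFrame:
        return self.profiles.loc[self.n_arrays >= self.min_arrays]

    @classmethod
    def from_tsv(cls, path, min_arrays: int = 15) -> "Compendium":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "n_arrays" not in df.columns:
            raise ValueError("compendium TSV needs an 'n_arrays' column")
        n_arrays = df["n_arrays"].astype(int)
        return cls(profiles=df.drop(columns="n_arrays"), n_arrays=n_arrays,
                   min_arrays=min_arrays)


def signature_profile(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene median of the log2 expression across the cohort.

    All-missing genes are excluded with a warning.
    """
    if expr.scale != "log2":
        raise ValueError("signature_profile expects a log2-scale matrix")
    med = expr.values.median(axis=0, skipna=True)
    dead = med.isna()
    if dead.any():
        warnings.warn(
            f"gene(s) with no observed values excluded: {list(med.index[dead])}",
            stacklevel=2,
        )
        med = med[~dead]
    med.name = "signature_profile"
    return med


@dataclass
class SimilarityRanking:
    """Per-condition Pearson r and relative similarity, ranked descending."""

    table: pd.DataFrame  # columns: r, rel_similarity, rank, n_genes, n_arrays
    excluded: list  # conditions dropped (too few arrays or shared genes)

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.head(k)


def rank_conditions(
    profile: pd.Series, compendium: Compendium, top_k: int = 10
) -> SimilarityRanking:
    """Align the signature profile against every eligible condition.

    r is the Pearson correlation over the genes shared between profile and
    condition (conditions sharing < 3 genes are excluded and logged); the
    relative-similarity index is r / mean(r over included conditions), a
    positive rescaling that preserves the r ranking.
    """
    rows = []
    excluded = list(compendium.excluded_small)
    for cond, row in compendium.eligible.iterrows():
        vals = row.dropna()
        shared = profile.index.intersection(vals.index)
        if len(shared) < 3:
            excluded.append(cond)
            continue
        x = profile[shared].to_numpy(dtype=float)
        y = vals[shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            excluded.append(cond)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"condition": cond, "r": r, "n_genes": len(shared),
                     "n_arrays": int(compendium.n_arrays[cond])})
    if not rows:
        raise ValueError("no condition shares enough genes with the profile")
    tbl = pd.DataFrame(rows).set_index("condition")
    mean_r = tbl["r"].mean()
    if abs(mean_r) < 1e-12:
        warnings.warn(
            "mean correlation ~0; relative similarity undefined, reporting r only",
            stacklevel=2,
        )
        tbl["rel_similarity"] = np.nan
    else:
        tbl["rel_similarity"] = tbl["r"] / mean_r
    tbl = tbl.sort_values("r", ascending=False)
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return SimilarityRanking(table=tbl.head(top_k) if top_k else tbl,
                             excluded=excluded)


@dataclass
class CoexpressionList:
    target: str
    table: pd.DataFrame  # columns: gene, r  (descending r, target excluded)

    @property
    def genes(self) -> list:
        return list(self.table["gene"])


def coexpression_top_n(
    samples: pd.DataFrame | ExpressionMatrix, target: str, n: int = 200
) -> CoexpressionList:
    """Top-n co-expressed genes with ``target`` across a samples x genes
    matrix, ranked by descending Pearson correlation (target excluded)."""
    df = samples.values if isinstance(samples, ExpressionMatrix) else samples
    if target not in df.columns:
        raise KeyError(f"target gene {target!r} not in matrix")
    if df.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    x = df[target].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"target gene {target!r} is constant")
    arr = df.to_numpy(dtype=float)
    xc = x - x.mean()
    ac = arr - arr.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (ac**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ ac) / denom
    tbl = pd.DataFrame({"gene": df.columns, "r": r})
    tbl = tbl[tbl["gene"] != target].dropna(subset=["r"])
    tbl = tbl.sort_values("r", ascending=False, kind="stable").head(n)
    return CoexpressionList(target=target, table=tbl.reset_index(drop=True))


def _collapse_symbols(names) -> set:
    """Case-normalized symbols; probe suffixes after '|' are dropped so
    multiple probes of one gene collapse to a single symbol.  Names without
    a symbol part (pure probe ids) are kept verbatim (upper-cased)."""
    out = set()
    for name in names:
        s = str(name).strip()
        if "|" in s:
            s = s.split("|", 1)[0].strip()
        out.add(s.upper())
    return out


def list_overlap(list_a, list_b) -> tuple[set, int]:
    """Case-normalized symbol intersection of two gene lists.

    Accepts plain iterables of names or :class:`CoexpressionList` objects.
    Returns (intersection set, count).
    """
    a = list_a.genes if isinstance(list_a, CoexpressionList) else list(list_a)
    b = list_b.genes if isinstance(list_b, CoexpressionList) else list(list_b)
    inter = _collapse_symbols(a) & _collapse_symbols(b)
    return inter, len(inter)
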