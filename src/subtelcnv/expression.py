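"""Two-group expression analysis and the dosage significance filter.

Counts-per-million normalisation, log2 fold changes on group mean CPM, a
two-group test (exact label-permutation test by default, or a
negative-binomial Wald test for p-values below the permutation floor), and
the published decision rule -- significant means p < 0.01 *and* fold
change > 2 over-expressed -- applied to differential-expression tables,
including the packaged cassette-gene table fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountMatrix:
    """Genes x samples integer counts with a two-group sample design."""

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.groups.index) != list(self.counts.columns):
            raise ValueError("groups index must match count columns")
        if self.groups.nunique() != 2:
            raise ValueError("need exactly two groups")

    @property
    def group_names(self) -> tuple[str, str]:
        seen = list(dict.fromkeys(self.groups))
        return seen[0], seen[1]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_columns(self, name: str) -> list[str]:
        return list(self.groups.index[self.groups == name])


def normalize_cpm(counts: pd.DataFrame,
                  library_sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        bad = list(library_sizes.index[library_sizes <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts / library_sizes * 1e6


def log_fold_change(cpm: pd.DataFrame, groups: pd.Series,
                    pseudocount: float = 0.5) -> pd.Series:
    """Per-gene log2 fold change of group-2 over group-1 mean CPM, with a
    pseudocount for stability at zero."""
    g1, g2 = list(dict.fromkeys(groups))
    m1 = cpm[groups.index[groups == g1]].mean(axis=1)
    m2 = cpm[groups.index[groups == g2]].mean(axis=1)
    return np.log2((m2 + pseudocount) / (m1 + pseudocount))


def _permutation_pvalues(logcpm: np.ndarray, is_g2: np.ndarray,
                         alternative: str) -> np.ndarray:
    n = len(is_g2)
    k = int(is_g2.sum())
    combos = np.zeros((comb(n, k), n), dtype=bool)
    for r, cols in enumerate(combinations(range(n), k)):
        combos[r, list(cols)] = True
    # statistic per permutation and gene: mean(group2) - mean(group1)
    w = combos / k - (~combos) / (n - k)
    T = w @ logcpm.T                       # (n_perm, n_genes)
    obs = T[np.flatnonzero((combos == is_g2).all(axis=1))[0]]
    # ties must count as hits; absorb float-summation jitter across rows
    tol = 1e-9
    if alternative == "greater":
        hits = (T >= obs - tol).sum(axis=0)
    elif alternative == "less":
        hits = (T <= obs + tol).sum(axis=0)
    elif alternative == "two-sided":
        hits = (np.abs(T) >= np.abs(obs) - tol).sum(axis=0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return hits / len(combos)


def _nb_wald_pvalues(counts: np.ndarray, is_g2: np.ndarray,
                     library_sizes: np.ndarray, alternative: str) -> np.ndarray:
    norm = counts / library_sizes * library_sizes.mean()
    x1, x2 = norm[:, ~is_g2], norm[:, is_g2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.nanmean(np.stack([
            np.clip((v1 - m1) / m1 ** 2, 0, None),
            np.clip((v2 - m2) / m2 ** 2, 0, None)]), axis=0)
    phi = np.nan_to_num(phi)
    eps = 0.5
    est = np.log((m2 + eps) / (m1 + eps))
    var = (1 / (m1 + eps) + phi) / x1.shape[1] + \
          (1 / (m2 + eps) + phi) / x2.shape[1]
    z = est / np.sqrt(var)
    if alternative == "greater":
        return stats.norm.sf(z)
    if alternative == "less":
        return stats.norm.cdf(z)
    if alternative == "two-sided":
        return 2 * stats.norm.sf(np.abs(z))
    raise ValueError(f"unknown alternative {alternative!r}")


def two_group_test(cm: CountMatrix, method: str = "permutation",
                   alternative: str = "greater") -> pd.Series:
    """Per-gene p-values for group-2 over-expression.

    ``permutation``: exact test over all group-label assignments (12,870
    for 8 vs 8) of the difference in mean log-CPM; its smallest attainable
    p is 1/#assignments.  ``nb_wald``: Wald test on log group means with
    method-of-moments dispersion, for effects past the permutation floor.
    """
    g1, g2 = cm.group_names
    for g in (g1, g2):
        if len(cm.group_columns(g)) < 2:
            raise ValueError(f"group {g}: need >= 2 samples")
    is_g2 = (cm.groups == g2).to_numpy()
    if method == "permutation":
        cpm = normalize_cpm(cm.counts)
        logcpm = np.log2(cpm.to_numpy() + 0.5)
        p = _permutation_pvalues(logcpm, is_g2, alternative)
    elif method == "nb_wald":
        p = _nb_wald_pvalues(cm.counts.to_numpy(), is_g2,
                             cm.library_sizes.to_numpy(), alternative)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(p, index=cm.counts.index, name="pvalue")


# ------------------------------------------------------------ DE tables

@dataclass(frozen=True)
class DERow:
    gene_id: str
    label: str
    region: str                  # "A" | "B" | "other"
    logfc: Optional[float]
    pvalue: Optional[float]

    @property
    def missing(self) -> bool:
        return self.logfc is None or self.pvalue is None


@dataclass(frozen=True)
class FilterParams:
    alpha: float = 0.01
    fold_change_min: float = 2.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must be > 1")


def _region_of(label: str) -> str:
    if label == "EPSPS" or label.startswith("A"):
        return "A"
    if label.startswith("B"):
        return "B"
    return "other"


def parse_de_table(path) -> list[DERow]:
    """Parse a differential-expression table; '-' statistics mark genes
    filtered during testing (kept as missing rows)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id_gs", "label", "logfc", "pvalue"):
        if col not in df.columns:
            raise ValueError(f"DE table missing column {col!r}")
    rows = []
    for _, r in df.iterrows():
        vals = {}
        for col in ("logfc", "pvalue"):
            raw = str(r[col]).strip()
            if raw in ("-", "", "nan", "NA"):
                vals[col] = None
                continue
            try:
                vals[col] = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"row {r['label']}: malformed {col} value {raw!r}") from exc
        if vals["pvalue"] is not None and not 0 < vals["pvalue"] <= 1:
            raise ValueError(f"row {r['label']}: p-value out of (0, 1]")
        rows.append(DERow(str(r["gene_id_gs"]), str(r["label"]),
                          _region_of(str(r["label"])),
                          vals["logfc"], vals["pvalue"]))
    return rows


def significance_filter(rows: Sequence[DERow],
                        params: FilterParams = FilterParams(),
                        tested_only: bool = False):
    """Apply the over-expression decision rule (p < alpha and fold change
    above the minimum) and count significant genes per region.

    Returns (flags by label, {region: (n_significant, n_total)});
    missing rows count as not significant and stay in the denominator
    unless ``tested_only``.
    """
    flags: dict[str, bool] = {}
    counts: dict[str, list[int]] = {}
    for row in rows:
        sig = (not row.missing and row.pvalue < params.alpha
               and 2.0 ** row.logfc > params.fold_change_min)
        flags[row.label] = sig
        if row.missing and tested_only:
            continue
        n = counts.setdefault(row.region, [0, 0])
        n[0] += int(sig)
        n[1] += 1
    return flags, {k: (v[0], v[1]) for k, v in counts.items()}
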