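"""Connecting binding-site calls to regulation: matched comparisons,
site-count strata, translational-repression calls and the associated tests.

Targets (genes with at least one retained CLIP cluster) are compared to
nontargets on mRNA / RPF / TE fold-change ECDFs with two-tailed
Mann-Whitney U tests (exact enumeration for small groups, midrank normal
approximation otherwise), split into 1 / 2 / 3 / 4+ binding-site strata, and
the most TE-repressed decile of targets is cross-tabulated against carrying
multiple recognition elements (Pearson chi-square).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STRATA = ("1", "2", "3", "4+")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group A: number of (a, b) pairs with a > b, ties counting 1/2."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], exact_limit: int = 64
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration over all C(n1+n2, n1) group assignments when
    ``n1 * n2 <= exact_limit`` (correct under ties as well); otherwise the
    tie-corrected normal approximation. The two-tailed exact p is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    if n1 * n2 <= exact_limit:
        pooled = np.concatenate([a, b])
        idx = np.arange(n1 + n2)
        n_le = n_ge = total = 0
        for comb in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            n_le += u <= u_obs + 1e-12
            n_ge += u >= u_obs - 1e-12
            total += 1
        p = min(1.0, 2.0 * min(n_le / total, n_ge / total))
        return u_obs, p
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def ecdf(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Sorted values and the cumulative fractions 1/n..1."""
    x = np.sort(np.asarray(list(values), dtype=float))
    return x, np.arange(1, len(x) + 1) / len(x)


@dataclass
class StratumComparison:
    """Two-group ECDF comparison of one fold-change metric."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    ecdf_a: tuple[np.ndarray, np.ndarray]
    ecdf_b: tuple[np.ndarray, np.ndarray]

    @property
    def median_shift(self) -> float:
        return float(np.median(self.ecdf_a[0]) - np.median(self.ecdf_b[0]))


def ecdf_compare(
    values_a: Sequence[float], values_b: Sequence[float],
    label_a: str = "A", label_b: str = "B",
) -> StratumComparison:
    """ECDFs of two groups plus the two-tailed Mann-Whitney U test."""
    u, p = mann_whitney_u(values_a, values_b)
    return StratumComparison(
        label_a, label_b, len(list(values_a)), len(list(values_b)),
        u, p, ecdf(values_a), ecdf(values_b),
    )


@dataclass
class MatchedSubsets:
    """Target/nontarget subsets matched on 3'UTR-length distribution."""

    target_ids: list[str]
    nontarget_ids: list[str]
    ks_distance: float


def match_by_utr_length(
    target_lengths: pd.Series,
    nontarget_lengths: pd.Series,
    n: int = 500,
    seed: int = 0,
) -> MatchedSubsets:
    """Greedy nearest-neighbor matching on log10(3'UTR length), without
    replacement; reports the residual two-sample KS distance.

    ``target_lengths`` / ``nontarget_lengths`` are Series of 3'UTR lengths
    indexed by gene id.
    """
    if len(target_lengths) < n or len(nontarget_lengths) < n:
        raise ValueError(f"need at least n={n} genes in each pool")
    rng = np.random.default_rng(seed)
    t_ids = rng.choice(target_lengths.index.to_numpy(), size=n, replace=False)
    t_log = np.log10(np.maximum(target_lengths.loc[t_ids].to_numpy(float), 1.0))
    nt_ids = nontarget_lengths.index.to_numpy()
    nt_log = np.log10(np.maximum(nontarget_lengths.to_numpy(float), 1.0))
    order = np.argsort(nt_log, kind="stable")
    nt_ids, nt_log = nt_ids[order], nt_log[order]
    used = np.zeros(len(nt_ids), dtype=bool)
    chosen: list[int] = []
    for x in t_log:
        j = int(np.searchsorted(nt_log, x))
        left, right = j - 1, j
        while True:
            cand = []
            if left >= 0 and not used[left]:
                cand.append((abs(nt_log[left] - x), left))
            if right < len(nt_ids) and not used[right]:
                cand.append((abs(nt_log[right] - x), right))
            if cand:
                _, k = min(cand)
                used[k] = True
                chosen.append(k)
                break
            if left >= 0 and used[left]:
                left -= 1
            if right < len(nt_ids) and used[right]:
                right += 1
            if left < 0 and right >= len(nt_ids):
                raise ValueError("nontarget pool exhausted")
    matched_nt = nt_ids[chosen]
    ks = stats.ks_2samp(
        target_lengths.loc[t_ids].to_numpy(float),
        nontarget_lengths.loc[matched_nt].to_numpy(float),
    ).statistic
    return MatchedSubsets(list(map(str, t_ids)), list(map(str, matched_nt)), float(ks))


def _stratum_labels(annotations: pd.DataFrame, genes: pd.Index) -> pd.Series:
    """Stratum per gene: nontarget / 1 / 2 / 3 / 4+."""
    n_sites = annotations.set_index("transcript_id")["n_sites"] if "transcript_id" in annotations else annotations["n_sites"]
    lab = pd.Series("nontarget", index=genes, dtype=object)
    common = genes.intersection(n_sites.index)
    counts = n_sites.loc[common]
    lab.loc[common[counts >= 4]] = "4+"
    for k in (1, 2, 3):
        lab.loc[common[counts == k]] = str(k)
    lab.loc[common[counts == 0]] = "nontarget"
    return lab


def stratify_by_site_count(
    annotations: pd.DataFrame,
    fold_changes: pd.DataFrame,
    metrics: Sequence[str] = ("mrna_log2fc", "rpf_log2fc", "te_log2fc"),
    pairs: Sequence[tuple[str, str]] | None = None,
) -> dict[str, object]:
    """ECDF comparisons of fold-change metrics across binding-site-count
    strata (nontarget, 1, 2, 3, 4+).

    Returns ``{"comparisons": frame, "medians": frame, "ecdfs": {...}}``;
    empty strata are skipped with a log message. ``pairs`` defaults to every
    stratum against nontargets plus 4+ against 1.
    """
    lab = _stratum_labels(annotations, fold_changes.index)
    groups = {
        s: fold_changes.index[lab == s] for s in ("nontarget",) + STRATA
        if (lab == s).any()
    }
    for s in ("nontarget",) + STRATA:
        if s not in groups:
            logger.info("stratum %s is empty; skipped", s)
    if pairs is None:
        pairs = [(s, "nontarget") for s in STRATA] + [("4+", "1")]
    rows, ecdfs, med_rows = [], {}, []
    for metric in metrics:
        vals = fold_changes[metric]
        for s, ids in groups.items():
            v = vals.loc[ids].dropna()
            ecdfs[(metric, s)] = ecdf(v)
            med_rows.append({"metric": metric, "stratum": s, "n": len(v),
                             "median": float(np.median(v)) if len(v) else np.nan})
        for s_a, s_b in pairs:
            if s_a not in groups or s_b not in groups:
                continue
            va = vals.loc[groups[s_a]].dropna()
            vb = vals.loc[groups[s_b]].dropna()
            if len(va) == 0 or len(vb) == 0:
                continue
            u, p = mann_whitney_u(va, vb)
            rows.append(
                {"metric": metric, "stratum_a": s_a, "stratum_b": s_b,
                 "n_a": len(va), "n_b": len(vb), "U": u, "p": p}
            )
    return {
        "comparisons": pd.DataFrame(rows),
        "medians": pd.DataFrame(med_rows),
        "ecdfs": ecdfs,
    }


def call_translational_repression(
    fold_changes: pd.DataFrame,
    target_ids: Sequence[str],
    fraction: float = 0.10,
) -> list[str]:
    """The floor(fraction * n_targets) targets with the most negative TE
    change; deterministic tie-break by permutation p (ascending) then gene
    id."""
    sub = fold_changes.loc[fold_changes.index.intersection(list(target_ids))]
    sub = sub[sub["te_log2fc"].notna()]
    k = math.floor(fraction * len(sub))
    tie = sub["te_p"] if "te_p" in sub else pd.Series(0.0, index=sub.index)
    order = sub.assign(_p=tie.fillna(1.0), _g=sub.index.astype(str)).sort_values(
        ["te_log2fc", "_p", "_g"], kind="stable"
    )
    return list(order.index[:k].astype(str))


@dataclass
class ChiSquareResult:
    table: np.ndarray  # rows: repressed yes/no; cols: multiple yes/no
    statistic: float
    p_value: float
    expected: np.ndarray
    warning: str | None


def chi_square_2x2(table: np.ndarray, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, Sum (O-E)^2 / E, no continuity
    correction by default (Yates optional); warns when an expected cell is
    below 5."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if n == 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("table margins must be positive")
    expected = row @ col / n
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    warning = "expected cell < 5" if (expected < 5).any() else None
    return ChiSquareResult(obs, statistic, p, expected, warning)


def multi_element_association(
    repressed_ids: Sequence[str],
    annotations: pd.DataFrame,
    multiple_by: str = "kinds",
    yates: bool = False,
) -> ChiSquareResult:
    """2x2 association between translational repression and carrying multiple
    recognition elements.

    ``multiple_by='kinds'`` counts a target as "multiple" when it carries >= 2
    distinct element kinds; ``'sites'`` when it has >= 2 binding sites.
    """
    ann = annotations.set_index("transcript_id") if "transcript_id" in annotations else annotations
    repressed = set(map(str, repressed_ids))
    if multiple_by == "kinds":
        multiple = ann["element_kinds"].fillna("").map(lambda s: len([k for k in str(s).split(",") if k]) >= 2)
    elif multiple_by == "sites":
        multiple = ann["n_sites"] >= 2
    else:
        raise ValueError("multiple_by must be 'kinds' or 'sites'")
    is_rep = ann.index.astype(str).isin(repressed)
    table = np.array(
        [
            [int((is_rep & multiple).sum()), int((is_rep & ~multiple).sum())],
            [int((~is_rep & multiple).sum()), int((~is_rep & ~multiple).sum())],
        ]
    )
    res = chi_square_2x2(table, yates=yates)
    if res.warning:
        logger.warning("chi-square: %s", res.warning)
    return res


def element_kind_vs_regulation(
    annotations: pd.DataFrame,
    fold_changes: pd.DataFrame,
    metrics: Sequence[str] = ("mrna_log2fc", "rpf_log2fc", "te_log2fc"),
    min_genes: int = 5,
) -> pd.DataFrame:
    """Pairwise fold-change comparisons between element kinds.

    A target belongs to the group of every kind it carries. Kinds with fewer
    than ``min_genes`` genes are still reported but flagged.
    """
    ann = annotations.set_index("transcript_id") if "transcript_id" in annotations else annotations
    kind_members: dict[str, list[str]] = {}
    for tid, kinds in ann["element_kinds"].items():
        for k in str(kinds).split(","):
            if k:
                kind_members.setdefault(k, []).append(str(tid))
    rows = []
    kinds = sorted(kind_members)
    for metric in metrics:
        vals = fold_changes[metric]
        for ka, kb in combinations(kinds, 2):
            va = vals.loc[vals.index.intersection(kind_members[ka])].dropna()
            vb = vals.loc[vals.index.intersection(kind_members[kb])].dropna()
            if len(va) == 0 or len(vb) == 0:
                continue
            u, p = mann_whitney_u(va, vb)
            rows.append(
                {
                    "metric": metric, "kind_a": ka, "kind_b": kb,
                    "n_a": len(va), "n_b": len(vb), "U": u, "p": p,
                    "flagged": len(va) < min_genes or len(vb) < min_genes,
                }
            )
    return pd.DataFrame(
        rows, columns=["metric", "kind_a", "kind_b", "n_a", "n_b", "U", "p", "flagged"]
    )
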