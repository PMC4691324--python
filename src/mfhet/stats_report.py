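"""Statistical tests used across the pipeline, plus report assembly.

All tests are two-tailed and return a :class:`TestResult` recording whether
the exact or the asymptotic branch was used.  Exactness cutoffs: Spearman
p-value by full permutation enumeration for n <= 10; Wilcoxon signed-rank
and rank-sum by exact distribution for total n <= 25; Fisher's exact test
always exact for 2x2 and by fixed-margin enumeration for r x k tables with
total <= 50 (chi-square approximation above).  Zero differences are dropped
before the signed-rank test.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "rank_sum",
    "kruskal_wallis",
    "fisher_exact_2xk",
    "assemble_report",
    "SPEARMAN_EXACT_MAX_N",
    "RANK_EXACT_MAX_N",
    "FISHER_EXACT_MAX_TOTAL",
]

SPEARMAN_EXACT_MAX_N = 10
RANK_EXACT_MAX_N = 25
FISHER_EXACT_MAX_TOTAL = 50


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    method_detail: str
    two_tailed: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def _ranks(x) -> np.ndarray:
    return sps.rankdata(np.asarray(x, dtype=float))


@functools.lru_cache(maxsize=2)
def _permutation_array(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) int8 array, built
    recursively with vectorised assignment (n <= 10)."""
    if n == 1:
        return np.zeros((1, 1), dtype=np.int8)
    sub = _permutation_array(n - 1)
    m = sub.shape[0]
    out = np.empty((m * n, n), dtype=np.int8)
    for i in range(n):
        rest = np.delete(np.arange(n, dtype=np.int8), i)
        out[i * m : (i + 1) * m, 0] = i
        out[i * m : (i + 1) * m, 1:] = rest[sub]
    return out


def spearman_rho(pairs: Sequence[tuple[float, float]]) -> TestResult:
    """Spearman rank correlation with average-rank tie handling.

    p-value by exhaustive permutation for n <= 10 (exact under the null of
    independence), otherwise the t-distribution approximation.
    """
    pairs = list(pairs)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >=3 pairs for Spearman, have {n}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx, ry = _ranks(x), _ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        # enumerate all pairings; ranks may tie, so evaluate the full
        # correlation (not just the rank-product sum) per permutation
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        perms = _permutation_array(n)
        hits = 0
        for chunk in np.array_split(perms, max(1, len(perms) // 200_000)):
            rhos = (ry_c[chunk] @ rx_c) / denom
            hits += int(np.count_nonzero(np.abs(rhos) >= abs(rho) - 1e-12))
        p = hits / len(perms)
        detail = "exact permutation"
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
        p = min(1.0, p)
        detail = "t approximation"
    return TestResult("spearman", rho, p, n, detail)


def wilcoxon_signed_rank(diffs: Sequence[float]) -> TestResult:
    """Paired signed-rank test on the differences; zeros dropped first.

    All-zero input (no shift anywhere) returns p = 1 by convention.
    """
    d = np.asarray(list(diffs), dtype=float)
    if d.size == 0:
        raise ValueError("empty differences")
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return TestResult("wilcoxon-signed-rank", 0.0, 1.0, 0, "all differences zero")
    exact = n <= RANK_EXACT_MAX_N and len(np.unique(np.abs(d))) == n
    if exact:
        res = sps.wilcoxon(d, method="exact", alternative="two-sided")
        detail = "exact"
    else:
        res = sps.wilcoxon(
            d, method="approx", correction=True, alternative="two-sided"
        )
        detail = "normal approximation, continuity corrected"
    return TestResult(
        "wilcoxon-signed-rank", float(res.statistic), float(res.pvalue), n, detail
    )


def rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney) test."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum requires two non-empty samples")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    n = int(x.size + y.size)
    if n <= RANK_EXACT_MAX_N and not ties:
        res = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        detail = "exact"
    else:
        res = sps.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
        detail = "normal approximation, tie corrected"
    return TestResult(
        "wilcoxon-rank-sum", float(res.statistic), float(res.pvalue), n, detail
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test across >= 2 groups (chi-square approximation,
    tie corrected)."""
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if any(g.size == 0 for g in groups) or len(groups) < 2:
        raise ValueError("kruskal_wallis requires >=2 non-empty groups")
    n = int(sum(g.size for g in groups))
    if all(np.all(g == groups[0][0]) for g in groups):
        # identical constant groups: no evidence of shift
        return TestResult("kruskal-wallis", 0.0, 1.0, n, "degenerate (constant)")
    res = sps.kruskal(*groups)
    return TestResult(
        "kruskal-wallis",
        float(res.statistic),
        float(res.pvalue),
        n,
        "chi-square approximation",
    )


def _fisher_rxk_exact(table: np.ndarray) -> float:
    """Exact conditional test for an r x k table: sum of probabilities of
    all tables with the observed margins whose probability does not exceed
    the observed table's (the standard two-sided Fisher construction)."""
    from math import lgamma

    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    r, k = table.shape

    # log P(T) = [sum_i log(R_i!) + sum_j log(C_j!) - log(N!)] - sum_ij log(t_ij!)
    base = sum(lgamma(ri + 1) for ri in rows) + sum(
        lgamma(cj + 1) for cj in cols
    ) - lgamma(n + 1)

    def logp(t: np.ndarray) -> float:
        return base - sum(lgamma(int(v) + 1) for v in t.ravel())

    obs_lp = logp(table)
    total = 0.0
    # enumerate tables row by row, tracking remaining column sums
    def rec(row_idx: int, remaining_cols: tuple, acc: list):
        nonlocal total
        if row_idx == r - 1:
            t = np.array(acc + [list(remaining_cols)])
            if (t >= 0).all():
                lp = logp(t)
                if lp <= obs_lp + 1e-9:
                    total += float(np.exp(lp))
            return
        target = int(rows[row_idx])

        def fill(col_idx: int, left: int, row_acc: list):
            if col_idx == k - 1:
                if 0 <= left <= remaining_cols[col_idx]:
                    rec(
                        row_idx + 1,
                        tuple(
                            rc - v
                            for rc, v in zip(remaining_cols, row_acc + [left])
                        ),
                        acc + [row_acc + [left]],
                    )
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                fill(col_idx + 1, left - v, row_acc + [v])

        fill(0, target, [])

    rec(0, tuple(int(c) for c in cols), [])
    return min(1.0, total)


def fisher_exact_2xk(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test on an r x k contingency table.

    2x2 tables use the standard hypergeometric two-sided test; larger
    tables with total <= 50 use exact fixed-margin enumeration; above that
    the chi-square approximation is reported instead.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    n = int(t.sum())
    if n == 0:
        raise ValueError("empty contingency table")
    if t.shape == (2, 2):
        odds, p = sps.fisher_exact(t, alternative="two-sided")
        return TestResult("fisher-exact", float(odds), float(p), n, "exact (2x2)")
    if n <= FISHER_EXACT_MAX_TOTAL:
        p = _fisher_rxk_exact(t)
        return TestResult(
            "fisher-exact", float("nan"), p, n, "exact (fixed-margin enumeration)"
        )
    chi2, p, _, _ = sps.chi2_contingency(t)
    return TestResult("chi-square", float(chi2), float(p), n, "chi-square approximation")


# ---------------------------------------------------------------------------
# cohort report assembly


class MissingSectionError(RuntimeError):
    """A required report section's inputs are absent."""


def assemble_report(
    outdir: str | Path,
    group_summary: dict | None = None,
    confirmation_summary: dict | None = None,
    concordance: dict | None = None,
    af_comparison: dict | None = None,
    association_table: pd.DataFrame | None = None,
    oncogenicity_summary: dict | None = None,
    cn_summary: dict | None = None,
    strict: bool = False,
) -> Path:
    """Write the cohort-level report: a TSV per section plus summary.md.

    Sections whose inputs were not supplied are noted as skipped; with
    ``strict=True`` missing sections raise :class:`MissingSectionError`
    listing every absent section instead.  Output is deterministic for
    identical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# Cohort heterogeneity report", ""]
    missing: list[str] = []

    def fmt(v) -> str:
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    def section(name: str, payload, writer) -> None:
        if payload is None:
            missing.append(name)
            lines.append(f"## {name}\n\n(section skipped: inputs not provided)\n")
            return
        lines.append(f"## {name}\n")
        writer(payload)
        lines.append("")

    def dict_writer(fname):
        def write(d: dict):
            flat = {
                k: v
                for k, v in d.items()
                if not isinstance(v, (dict, list, tuple))
            }
            pd.DataFrame([flat]).to_csv(outdir / fname, sep="\t", index=False)
            for k in sorted(d):
                lines.append(f"- {k}: {fmt(d[k])}")

        return write

    section("Heterogeneity groups", group_summary, dict_writer("groups.tsv"))
    section("Validation summary", confirmation_summary, dict_writer("confirmation.tsv"))
    section("Platform concordance", concordance, dict_writer("concordance.tsv"))
    section("Private vs common AF", af_comparison, dict_writer("af_comparison.tsv"))
    section("Oncogenicity", oncogenicity_summary, dict_writer("oncogenicity.tsv"))
    section("Copy number & rearrangements", cn_summary, dict_writer("cn_summary.tsv"))

    if association_table is not None:
        lines.append("## Covariate associations\n")
        association_table.to_csv(outdir / "associations.tsv", sep="\t", index=False)
        for row in association_table.itertuples(index=False):
            lines.append(
                f"- {row.covariate} ({row.comparison}, {row.test_used}): p = {fmt(row.p)}"
            )
        lines.append("")
    else:
        missing.append("Covariate associations")
        lines.append("## Covariate associations\n\n(section skipped: inputs not provided)\n")

    if strict and missing:
        raise MissingSectionError(f"missing report sections: {missing}")
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    return outdir / "summary.md"
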