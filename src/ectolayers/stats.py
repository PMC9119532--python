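"""Group-comparison statistics: Mann-Whitney U with Benjamini-Hochberg FDR,
exact contingency-table tests (Fisher 2x2 and Freeman-Halton 2xk), Pearson
chi-squared with Yates correction, and Spearman correlation.

Standard tests are delegated to scipy/statsmodels; the Freeman-Halton
exact test for 2xk tables and the exact permutation p-value for Spearman's
rho at small n are implemented here (no installed library provides them).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .imgio import MetricRecord, SampleSheet

log = logging.getLogger(__name__)

EXACT_MW_LIMIT = 16     # enumerate rank splits up to this pooled size
FISHER_ENUM_LIMIT = 500  # largest table total for exact enumeration


@dataclass
class ContingencyTable:
    """r x c non-negative integer counts with row/column labels."""

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.counts)
        if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
            t = t.astype(float)
            if np.any(t < 0) or np.any(t != np.round(t)):
                raise ValueError("counts must be non-negative integers")
        self.counts = np.asarray(np.round(t), dtype=np.int64)
        if (self.counts.sum(axis=1) == 0).any() or (self.counts.sum(axis=0) == 0).any():
            raise ValueError("table has an all-zero row or column")


@dataclass
class ComparisonResult:
    """One metric's two-group comparison."""

    metric_name: str
    n_x: int
    n_y: int
    median_x: float
    median_y: float
    u_stat: float
    p: float
    p_adj: float = float("nan")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The p-value is exact (full enumeration of rank assignments) when the
    pooled sample size is at most 16 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MW_LIMIT and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# exact contingency tests
# ---------------------------------------------------------------------------

def _log_table_prob(row0: np.ndarray, col_tot: np.ndarray,
                    row_tot: np.ndarray, n: int) -> np.ndarray:
    """Log multivariate hypergeometric probability of 2xk tables (vectorized
    over the first axis of row0)."""
    row1 = col_tot - row0
    const = (gammaln(row_tot[0] + 1) + gammaln(row_tot[1] + 1)
             + gammaln(col_tot + 1).sum() - gammaln(n + 1))
    return const - gammaln(row0 + 1).sum(axis=-1) - gammaln(row1 + 1).sum(axis=-1)


def fisher_exact(table: ContingencyTable, monte_carlo_draws: int | None = None,
                 seed: int = 0) -> float:
    """Exact conditional test for a 2xk table (Freeman-Halton for k > 2).

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (tolerance 1e-7 on the comparison).  For 2x2 tables this is the
    classical two-sided Fisher rule.  Tables with total > 500 require the
    seeded Monte Carlo mode (``monte_carlo_draws``).
    """
    t = table.counts
    if t.shape[0] != 2:
        raise ValueError("only 2xk tables are supported")
    row_tot = t.sum(axis=1)
    col_tot = t.sum(axis=0)
    n = int(t.sum())
    if n > FISHER_ENUM_LIMIT and monte_carlo_draws is None:
        raise ValueError(
            f"table total {n} exceeds the exact enumeration bound "
            f"({FISHER_ENUM_LIMIT}); pass monte_carlo_draws (e.g. 10**6) for "
            "the seeded Monte Carlo mode")
    lp_obs = float(_log_table_prob(t[0].astype(float), col_tot, row_tot, n))
    if monte_carlo_draws is not None and n > FISHER_ENUM_LIMIT:
        return _fisher_monte_carlo(t, lp_obs, monte_carlo_draws, seed)

    k = t.shape[1]
    # enumerate first rows column by column, respecting margins
    grid_size = np.prod([col_tot[j] + 1.0 for j in range(k - 1)])
    if grid_size > 5e7:
        raise ValueError(
            "margins too large for dense enumeration; pass monte_carlo_draws")
    grids = np.meshgrid(*[np.arange(col_tot[j] + 1) for j in range(k - 1)],
                        indexing="ij")
    first = np.stack([g.ravel() for g in grids], axis=-1)
    last = row_tot[0] - first.sum(axis=1)
    ok = (last >= 0) & (last <= col_tot[k - 1])
    rows0 = np.column_stack([first[ok], last[ok]]).astype(float)
    lps = _log_table_prob(rows0, col_tot, row_tot, n)
    probs = np.exp(lps)
    return float(np.minimum(probs[lps <= lp_obs + 1e-7].sum(), 1.0))


def _fisher_monte_carlo(t: np.ndarray, lp_obs: float, draws: int,
                        seed: int) -> float:
    rng = np.random.default_rng(seed)
    row_tot = t.sum(axis=1)
    col_tot = t.sum(axis=0)
    n = int(t.sum())
    pool = np.repeat(np.arange(t.shape[1]), col_tot)
    hits = 0
    batch = 20_000
    done = 0
    while done < draws:
        b = min(batch, draws - done)
        rows0 = np.empty((b, t.shape[1]))
        for i in range(b):
            take = rng.permutation(pool)[: row_tot[0]]
            rows0[i] = np.bincount(take, minlength=t.shape[1])
        lps = _log_table_prob(rows0, col_tot, row_tot, n)
        hits += int(np.sum(lps <= lp_obs + 1e-7))
        done += b
    return (hits + 1) / (draws + 1)


def chi2_test(table: ContingencyTable, continuity: str = "auto"
              ) -> tuple[float, int, float]:
    """Pearson chi-squared test; Yates continuity correction for 2x2 tables.

    ``continuity``: "auto" applies the Yates correction to 2x2 tables only,
    "on"/"off" force it.  Returns (statistic, dof, p).
    """
    t = table.counts
    if continuity == "auto":
        corr = t.shape == (2, 2)
    elif continuity in ("on", "off"):
        corr = continuity == "on"
    else:
        raise ValueError("continuity must be one of auto|on|off")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=corr)
    return float(stat), int(dof), float(p)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

SPEARMAN_EXACT_LIMIT = 10


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of tie-averaged ranks.  For n <= 10 the
    p-value is exact, from full enumeration of the n! rank permutations of
    one variable; for larger n the t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector; rho undefined")
    if n > SPEARMAN_EXACT_LIMIT:
        res = sps.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    # exact permutation null of |rho|
    rx_c = rx - rx.mean()
    denom = math.sqrt(np.sum(rx_c ** 2) * np.sum((ry - ry.mean()) ** 2))
    obs = abs(np.sum(rx_c * (ry - ry.mean())))
    hits = 0
    total = 0
    it = itertools.permutations(ry - ry.mean())
    while True:
        chunk = np.array(list(itertools.islice(it, 200_000)))
        if chunk.size == 0:
            break
        s = np.abs(chunk @ rx_c)
        hits += int(np.sum(s >= obs - 1e-12 * max(denom, 1.0)))
        total += len(chunk)
    return rho, hits / total


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

def compare_groups(records: list[MetricRecord], sheet: SampleSheet,
                   metric_set: list[str] | None = None,
                   min_fraction_present: float = 0.5) -> list[ComparisonResult]:
    """Mann-Whitney per metric between the two groups, BH-adjusted jointly.

    ``metric_set`` selects which metrics enter the comparison (and the BH
    family); by default every metric present in the records is used.
    Metrics missing for more than half of the samples are excluded with a
    warning.  Results are sorted by unadjusted p.
    """
    df = pd.DataFrame(
        [(r.sample_id, r.metric_name, r.value) for r in records],
        columns=["sample_id", "metric_name", "value"],
    )
    groups = sheet.frame.set_index("sample_id")["group"]
    df = df[df.sample_id.isin(groups.index)]
    df["group"] = df.sample_id.map(groups)
    names = metric_set or sorted(df.metric_name.unique())
    n_samples = sheet.frame.sample_id.nunique()

    results = []
    for name in names:
        sub = df[(df.metric_name == name) & np.isfinite(df.value)]
        if len(sub) < min_fraction_present * n_samples:
            log.warning("metric %s present for %d/%d samples; excluded",
                        name, len(sub), n_samples)
            continue
        x = sub.loc[sub.group == "DMPA", "value"].to_numpy()
        y = sub.loc[sub.group == "control", "value"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            log.warning("metric %s has a group with < 2 samples; excluded", name)
            continue
        u, p = mann_whitney_u(x, y)
        results.append(ComparisonResult(
            metric_name=name, n_x=len(x), n_y=len(y),
            median_x=float(np.median(x)), median_y=float(np.median(y)),
            u_stat=u, p=p))
    if results:
        padj = bh_adjust([r.p for r in results])
        for r, pa in zip(results, padj):
            r.p_adj = float(pa)
    results.sort(key=lambda r: (r.p, r.metric_name))
    return results


def results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.metric_name, r.n_x, r.n_y, r.median_x, r.median_y, r.u_stat,
          r.p, r.p_adj) for r in results],
        columns=["metric", "n_dmpa", "n_control", "median_dmpa",
                 "median_control", "U", "p", "p_adj"],
    )
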