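"""Per-cytosine differential-methylation testing between two cohorts.

Replicate counts are pooled within each cohort and every retained site is
tested with a two-sided Fisher exact test on the 2x2 table (cohorts x
methylated/unmethylated). P-values are corrected genome-wide by
Benjamini-Hochberg, and a site is called differentially methylated when
q < q_max AND |difference| >= min_diff percentage points (both thresholds
from the regional-calling definition used throughout the package:
q < 0.01 and >= 15 points by default, inclusive on the 15).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DesignError

log = logging.getLogger("methylseg")

SITE_KEY = ["chrom", "pos", "strand", "context"]

#: relative tie tolerance for the two-sided Fisher rule (tables whose point
#: probability is within this factor of the observed one count as ties); the
#: convention used by R's fisher.test.
_TIE_EPS = 1e-7


@dataclass(frozen=True)
class ThresholdConfig:
    """Calling thresholds.

    q_max: corrected-p cutoff (0.01 default; 0.05 in the gametic profile).
    min_diff: minimum |methylation difference| in percentage points, inclusive.
    min_coverage: minimum pooled coverage required in BOTH cohorts.
    min_sites: minimum differential sites per region.
    max_gap: maximum distance in bp between consecutive differential sites
        of a region (measured between site start coordinates).
    """

    q_max: float = 0.01
    min_diff: float = 15.0
    min_coverage: int = 10
    min_sites: int = 4
    max_gap: int = 1_000

    def __post_init__(self):
        problems = []
        if not (0 < self.q_max <= 1):
            problems.append(f"q_max={self.q_max} not in (0, 1]")
        if not (0 < self.min_diff <= 100):
            problems.append(f"min_diff={self.min_diff} not in (0, 100]")
        if self.min_coverage <= 0:
            problems.append(f"min_coverage={self.min_coverage} not positive")
        if self.min_sites <= 0:
            problems.append(f"min_sites={self.min_sites} not positive")
        if self.max_gap <= 0:
            problems.append(f"max_gap={self.max_gap} not positive")
        if problems:
            raise ConfigError("; ".join(problems))


def pool_replicates(samples_by_group: Mapping[str, Sequence[pd.DataFrame]],
                    min_coverage: int = 10) -> pd.DataFrame:
    """Pool replicate cytosine tables within each of two cohorts.

    Sites missing from a replicate contribute zero counts. Only sites whose
    pooled coverage reaches ``min_coverage`` in BOTH cohorts are retained.
    Returns one row per retained site with columns meth_a/unmeth_a (first
    group in mapping order) and meth_b/unmeth_b, sorted by (chrom, pos).
    """
    groups = list(samples_by_group)
    if len(groups) != 2:
        raise DesignError(f"exactly two cohorts required, got {groups}")
    pooled = {}
    for label in groups:
        tables = list(samples_by_group[label])
        if not tables:
            raise DesignError(f"cohort {label!r} has no replicates")
        pooled[label] = (
            pd.concat(tables, ignore_index=True)
            .groupby(SITE_KEY, as_index=False)[["meth", "unmeth"]]
            .sum()
        )
    a, b = groups
    merged = pooled[a].merge(pooled[b], on=SITE_KEY, how="outer",
                             suffixes=("_a", "_b")).fillna(0)
    for col in ["meth_a", "unmeth_a", "meth_b", "unmeth_b"]:
        merged[col] = merged[col].astype(np.int64)
    cov_a = merged["meth_a"] + merged["unmeth_a"]
    cov_b = merged["meth_b"] + merged["unmeth_b"]
    keep = (cov_a >= min_coverage) & (cov_b >= min_coverage)
    log.info("pool_replicates(%s vs %s): %d of %d sites retained at coverage >= %d",
             a, b, int(keep.sum()), len(merged), min_coverage)
    return (merged[keep]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True))


def _lchoose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(a_meth, a_unmeth, b_meth, b_unmeth,
                           chunk: int = 4096) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for arrays of 2x2 tables.

    For each table the hypergeometric point probabilities over the full
    support are enumerated and those not exceeding the observed one (to
    within a 1e-7 relative tie tolerance) are summed.
    """
    a = np.atleast_1d(np.asarray(a_meth, dtype=np.int64))
    b = np.atleast_1d(np.asarray(a_unmeth, dtype=np.int64))
    c = np.atleast_1d(np.asarray(b_meth, dtype=np.int64))
    d = np.atleast_1d(np.asarray(b_unmeth, dtype=np.int64))
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("counts must be non-negative")
    if np.any((a + b == 0) | (c + d == 0)):
        raise ValueError("both cohorts need coverage > 0 at every tested site")
    out = np.empty(a.shape[0], dtype=float)
    for lo_i in range(0, a.shape[0], chunk):
        sl = slice(lo_i, lo_i + chunk)
        out[sl] = _fisher_chunk(a[sl], b[sl], c[sl], d[sl])
    return out


def _fisher_chunk(a, b, c, d):
    m = a + b  # cohort A coverage
    n = c + d  # cohort B coverage
    big_k = a + c  # methylated margin
    big_n = m + n
    lo = np.maximum(0, big_k - n)
    hi = np.minimum(big_k, m)
    width = int((hi - lo).max()) + 1
    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    kk = np.where(valid, k, 0)
    log_norm = _lchoose(big_n, big_k)
    logpmf = (_lchoose(m[:, None], kk)
              + _lchoose(n[:, None], big_k[:, None] - kk)
              - log_norm[:, None])
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    pobs = np.exp(_lchoose(m, a) + _lchoose(n, c) - log_norm)
    p = (pmf * (pmf <= pobs[:, None] * (1 + _TIE_EPS))).sum(axis=1)
    return np.clip(p, 0.0, 1.0)


def test_site(a_meth: int, a_unmeth: int, b_meth: int, b_unmeth: int
              ) -> tuple[float, float]:
    """Two-sided Fisher exact p and methylation difference (pct points,
    cohort B minus cohort A) for a single site."""
    p = float(fisher_exact_two_sided([a_meth], [a_unmeth], [b_meth], [b_unmeth])[0])
    pct_a = 100.0 * a_meth / (a_meth + a_unmeth)
    pct_b = 100.0 * b_meth / (b_meth + b_unmeth)
    return p, pct_b - pct_a


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up corrected values (q >= p, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dm_sites(grouped_sites: pd.DataFrame,
                  thresholds: ThresholdConfig | None = None) -> pd.DataFrame:
    """Test every pooled site and flag differential ones.

    The BH correction runs over ALL tested sites. Returns the input site keys
    with pct_a, pct_b, diff (pct_b - pct_a), p, q, direction and is_dm.
    """
    thresholds = thresholds or ThresholdConfig()
    if len(grouped_sites) == 0:
        log.warning("call_dm_sites: no tested sites")
        return pd.DataFrame(columns=SITE_KEY + ["pct_a", "pct_b", "diff", "p", "q",
                                                "direction", "is_dm"])
    out = grouped_sites[SITE_KEY].copy()
    cov_a = grouped_sites["meth_a"] + grouped_sites["unmeth_a"]
    cov_b = grouped_sites["meth_b"] + grouped_sites["unmeth_b"]
    out["pct_a"] = 100.0 * grouped_sites["meth_a"] / cov_a
    out["pct_b"] = 100.0 * grouped_sites["meth_b"] / cov_b
    out["diff"] = out["pct_b"] - out["pct_a"]
    out["p"] = fisher_exact_two_sided(grouped_sites["meth_a"], grouped_sites["unmeth_a"],
                                      grouped_sites["meth_b"], grouped_sites["unmeth_b"])
    out["q"] = adjust_bh(out["p"].to_numpy())
    out["direction"] = np.where(out["diff"] > 0, "hyper", "hypo")
    out["is_dm"] = (out["q"] < thresholds.q_max) & (out["diff"].abs() >= thresholds.min_diff)
    log.info("call_dm_sites: %d of %d sites differential (q<%g, |diff|>=%g)",
             int(out["is_dm"].sum()), len(out), thresholds.q_max, thresholds.min_diff)
    return out
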