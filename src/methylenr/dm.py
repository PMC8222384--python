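"""Per-cytosine differential methylation testing.

The workflow mirrors the standard count-based RRBS analysis: coverage
filtering (minimum read depth, per-sample upper-percentile cap), a
"unite" step retaining sites covered in at least three samples of every
group, a per-site chi-squared likelihood-ratio test of a binomial
logistic model of methylation on group membership, SLIM/BH multiple
testing correction, and strict q-value / methylation-difference
thresholds for the final calls.

For a single binary group covariate the logistic-regression MLE has a
closed form — the fitted proportion of every sample is its group's
pooled methylated fraction — so the likelihood-ratio statistic is
computed vectorised as a binomial deviance difference.  This is
numerically identical to fitting the GLM per site and reduces to the
classical 2x2 G-test for one-sample-per-group designs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .io import CytosineRecord

SITE_COLUMNS = ["chrom", "pos", "strand", "context"]


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coverage filtering


def filter_by_coverage(
    records: list[CytosineRecord],
    min_cov: int = 10,
    upper_percentile: float = 99.9,
) -> list[CytosineRecord]:
    """Apply the depth filters to one sample's records.

    Sites with total coverage below ``min_cov`` (inclusive retention at
    exactly ``min_cov``) are removed; sites above this sample's
    ``upper_percentile`` of coverage are removed (PCR-duplicate guard).
    ``upper_percentile=100`` disables the upper filter.  The percentile
    is computed per sample over the records given.
    """
    if not records:
        return []
    totals = np.array([r.total for r in records], dtype=float)
    keep = totals >= min_cov
    if upper_percentile < 100:
        cutoff = np.percentile(totals, upper_percentile)
        keep &= totals <= cutoff
    return [r for r, k in zip(records, keep) if k]


# ---------------------------------------------------------------------------
# the united count matrix


@dataclass
class CytosineCountMatrix:
    """United per-cytosine counts across samples.

    ``meth`` and ``total`` are (n_sites, n_samples) float arrays with
    NaN marking a sample in which the site was not (sufficiently)
    covered — absent, not zero.
    """

    sites: pd.DataFrame  # columns chrom, pos, strand, context
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]
    groups: dict[str, str]  # sample -> group label

    def __post_init__(self) -> None:
        if self.meth.shape != self.total.shape:
            raise ValueError("meth/total shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("matrix shape does not match sites x samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return np.array(idx)

    def site_keys(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.sites[SITE_COLUMNS])

    def subset_sites(self, mask: np.ndarray) -> "CytosineCountMatrix":
        return CytosineCountMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            meth=self.meth[mask],
            total=self.total[mask],
            samples=list(self.samples),
            groups=dict(self.groups),
        )


def _records_to_site_table(records: list[CytosineRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "strand": [r.strand for r in records],
            "context": [r.context for r in records],
            "meth": [float(r.meth_count) for r in records],
            "total": [float(r.total) for r in records],
        }
    )


def unite(
    per_sample: dict[str, list[CytosineRecord]],
    groups: dict[str, str],
    min_per_group: int = 3,
) -> CytosineCountMatrix:
    """Join per-sample records on site, keeping sites covered in at
    least ``min_per_group`` samples of every group.

    Missing sample entries are stored as NaN (absent), never as zero.
    """
    group_sizes = Counter(groups[s] for s in per_sample)
    if len(group_sizes) < 2:
        raise ConfigurationError("unite requires at least two groups")
    for g, n in group_sizes.items():
        if n < min_per_group:
            raise ConfigurationError(
                f"group {g!r} has {n} samples, fewer than min_per_group={min_per_group}"
            )

    samples = list(per_sample)
    frames = []
    for s in samples:
        df = _records_to_site_table(per_sample[s])
        df = df.set_index(SITE_COLUMNS)
        frames.append(df)
    meth = pd.concat([f["meth"] for f in frames], axis=1, keys=samples)
    total = pd.concat([f["total"] for f in frames], axis=1, keys=samples)

    covered = total.notna()
    keep = pd.Series(True, index=total.index)
    for g in group_sizes:
        cols = [s for s in samples if groups[s] == g]
        keep &= covered[cols].sum(axis=1) >= min_per_group
    meth, total = meth.loc[keep], total.loc[keep]

    sites = meth.index.to_frame(index=False)
    sites = sites.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    order = pd.MultiIndex.from_frame(sites)
    meth = meth.reindex(order)
    total = total.reindex(order)
    return CytosineCountMatrix(
        sites=sites,
        meth=meth.to_numpy(dtype=float),
        total=total.to_numpy(dtype=float),
        samples=samples,
        groups={s: groups[s] for s in samples},
    )


# ---------------------------------------------------------------------------
# the per-site test


def _binomial_loglik(meth: np.ndarray, total: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Row sums of the binomial log-likelihood kernel (NaN-safe)."""
    m = np.nan_to_num(meth)
    t = np.nan_to_num(total)
    return np.nansum(xlogy(m, p) + xlogy(t - m, 1.0 - p), axis=1)


def test_diffmeth(
    matrix: CytosineCountMatrix, group1: str, group2: str
) -> pd.DataFrame:
    """Per-site chi-squared likelihood-ratio test of the group effect.

    Fits, per site, the binomial logistic model of methylation
    proportion on group membership (sample counts as trials) and tests
    the group term with a 1-df likelihood-ratio chi-squared test.
    Returns a frame with ``meth_diff`` (percentage points,
    group2 - group1, pooled fractions) and ``pvalue``; q-values are
    filled downstream.
    """
    i1 = matrix.sample_indices(group1)
    i2 = matrix.sample_indices(group2)
    m1, t1 = matrix.meth[:, i1], matrix.total[:, i1]
    m2, t2 = matrix.meth[:, i2], matrix.total[:, i2]

    T1 = np.nansum(t1, axis=1)
    T2 = np.nansum(t2, axis=1)
    if np.any(T1 == 0) or np.any(T2 == 0):
        raise ValueError(
            "site with zero total coverage in a group: matrix was not united"
        )
    M1 = np.nansum(m1, axis=1)
    M2 = np.nansum(m2, axis=1)
    p1 = M1 / T1
    p2 = M2 / T2
    p0 = (M1 + M2) / (T1 + T2)

    # group-wise MLE equals pooled fractions; LRT is the deviance difference
    ll_full = _binomial_loglik(m1, t1, p1[:, None]) + _binomial_loglik(
        m2, t2, p2[:, None]
    )
    ll_null = _binomial_loglik(m1, t1, p0[:, None]) + _binomial_loglik(
        m2, t2, p0[:, None]
    )
    g_stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pvalue = stats.chi2.sf(g_stat, df=1)

    out = matrix.sites[SITE_COLUMNS].copy()
    out["meth_diff"] = 100.0 * (p2 - p1)
    out["statistic"] = g_stat
    out["pvalue"] = pvalue
    out["qvalue"] = np.nan
    out["significant"] = False
    out["direction"] = "none"
    return out


# ---------------------------------------------------------------------------
# multiple testing correction


def estimate_pi0_slim(
    pvalues: np.ndarray,
    lambda_min: float = 0.01,
    lambda_max: float = 0.95,
    n_windows: int = 10,
    grid_size: int = 100,
) -> float:
    """Sliding-linear-model estimate of the null proportion pi0.

    The survival curve S(lambda) = frac(p > lambda) of a p-value mixture
    is asymptotically linear with slope -pi0 wherever the alternative
    density has vanished.  Overlapping windows of a lambda grid are each
    fitted by least squares; the window with the best linear fit
    supplies the slope, and pi0 is its negation clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 100:
        return 1.0  # too few tests to estimate a mixture; be conservative
    lam = np.linspace(lambda_min, lambda_max, grid_size)
    surv = 1.0 - np.searchsorted(np.sort(p), lam, side="right") / p.size

    win_len = max(grid_size // 4, 5)
    starts = np.linspace(0, grid_size - win_len, n_windows).astype(int)
    best_mse, best_slope = np.inf, -1.0
    for s in starts:
        x = lam[s : s + win_len]
        y = surv[s : s + win_len]
        slope, intercept = np.polyfit(x, y, 1)
        mse = float(np.mean((y - (slope * x + intercept)) ** 2))
        if mse < best_mse:
            best_mse, best_slope = mse, slope
    return float(np.clip(-best_slope, 1e-3, 1.0))


def adjust_qvalues(pvalues, method: str = "slim") -> np.ndarray:
    """q-values via SLIM (pi0-scaled Benjamini-Hochberg) or plain BH.

    Both are monotone in p and clipped to [0, 1]; SLIM with pi0 = 1
    coincides with BH exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return bh
    if method != "slim":
        raise ValueError(f"unknown adjustment method {method!r}")
    pi0 = estimate_pi0_slim(p)
    return np.clip(pi0 * bh, 0.0, 1.0)


# ---------------------------------------------------------------------------
# calling


def call_dm(
    results: pd.DataFrame,
    q_threshold: float = 0.001,
    diff_threshold: float = 25.0,
) -> pd.DataFrame:
    """Flag significant sites: q < q_threshold AND |diff| > diff_threshold.

    Both inequalities are strict; direction is the sign of the
    difference at significant sites, "none" elsewhere.
    """
    out = results.copy()
    sig = (out["qvalue"] < q_threshold) & (out["meth_diff"].abs() > diff_threshold)
    out["significant"] = sig.to_numpy()
    direction = np.where(
        ~sig, "none", np.where(out["meth_diff"] > 0, "hyper", "hypo")
    )
    out["direction"] = direction
    return out


def dm_counts(results: pd.DataFrame) -> dict[str, int]:
    sig = results[results["significant"]]
    return {
        "n_tested": int(len(results)),
        "n_significant": int(len(sig)),
        "n_hyper": int((sig["direction"] == "hyper").sum()),
        "n_hypo": int((sig["direction"] == "hypo").sum()),
    }


# ---------------------------------------------------------------------------
# region calling (beta-binomial Wald)


def _group_wald_terms(meth: np.ndarray, total: np.ndarray):
    """Pooled mean, method-of-moments intra-class correlation, and
    variance of the pooled-mean estimate, per site, for one group."""
    T = np.nansum(total, axis=1)
    M = np.nansum(meth, axis=1)
    mu = M / T
    n_obs = np.sum(~np.isnan(total), axis=1).astype(float)
    p_hat = meth / total  # NaN where absent
    resid2 = (p_hat - mu[:, None]) ** 2
    S = np.nansum(total * resid2, axis=1)
    v = mu * (1.0 - mu)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (S / np.where(v > 0, v, np.nan) - (n_obs - 1)) / np.maximum(
            T - n_obs, 1.0
        )
    rho = np.clip(np.nan_to_num(rho), 0.0, 0.99)
    infl = np.nansum(total * (1.0 + (total - 1.0) * rho[:, None]), axis=1)
    var_mu = v * infl / T**2
    return mu, var_mu


@dataclass
class DMRegion:
    chrom: str
    start: int  # 1-based first cytosine
    end: int  # 1-based last cytosine
    n_cytosines: int
    mean_diff: float
    stat: float
    pvalue: float
    adjusted_p: float = np.nan


def call_dmrs(
    matrix: CytosineCountMatrix,
    group1: str,
    group2: str,
    max_gap: int = 1000,
    min_cpgs: int = 3,
    diff_threshold: float = 25.0,
    site_alpha: float = 0.01,
    adjusted_p_threshold: float = 0.05,
) -> list[DMRegion]:
    """Differentially methylated regions from per-site beta-binomial
    Wald statistics.

    Per site and group, the methylation mean and dispersion are
    estimated by the method of moments; the Wald statistic tests the
    mean difference.  Qualifying sites (Wald p < ``site_alpha`` and
    |difference| > ``diff_threshold``) within ``max_gap`` bp of each
    other are merged; regions need at least ``min_cpgs`` cytosines and
    |mean difference| > ``diff_threshold``.  Region p-values combine the
    member Wald z-scores (Stouffer) and are BH-adjusted; regions passing
    ``adjusted_p_threshold`` are returned.  No kernel smoothing is
    applied.
    """
    i1 = matrix.sample_indices(group1)
    i2 = matrix.sample_indices(group2)
    mu1, var1 = _group_wald_terms(matrix.meth[:, i1], matrix.total[:, i1])
    mu2, var2 = _group_wald_terms(matrix.meth[:, i2], matrix.total[:, i2])
    diff = 100.0 * (mu2 - mu1)
    se = np.sqrt(var1 + var2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (mu2 - mu1) / se
    z = np.nan_to_num(z)
    site_p = 2.0 * stats.norm.sf(np.abs(z))

    qual = (site_p < site_alpha) & (np.abs(diff) > diff_threshold)
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()

    candidates: list[DMRegion] = []
    idx = np.flatnonzero(qual)
    if idx.size:
        runs: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            j = runs[-1][-1]
            if chroms[i] == chroms[j] and pos[i] - pos[j] <= max_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            if len(run) < min_cpgs:
                continue
            run = np.array(run)
            mean_diff = float(np.mean(diff[run]))
            if abs(mean_diff) <= diff_threshold:
                continue
            stouffer = float(np.sum(z[run]) / np.sqrt(len(run)))
            p = float(2.0 * stats.norm.sf(abs(stouffer)))
            candidates.append(
                DMRegion(
                    chrom=str(chroms[run[0]]),
                    start=int(pos[run[0]]),
                    end=int(pos[run[-1]]),
                    n_cytosines=int(len(run)),
                    mean_diff=mean_diff,
                    stat=stouffer,
                    pvalue=p,
                )
            )
    if not candidates:
        return []
    adj = multipletests([r.pvalue for r in candidates], method="fdr_bh")[1]
    out = []
    for r, a in zip(candidates, adj):
        r.adjusted_p = float(a)
        if r.adjusted_p < adjusted_p_threshold:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# global methylation


def global_methylation(
    per_sample: dict[str, list[CytosineRecord]], min_cov: int = 10
) -> dict[str, float]:
    """Per-sample mean methylation percentage over the sites covered by
    at least ``min_cov`` reads in *every* sample (unweighted mean of
    per-site percentages)."""
    samples = list(per_sample)
    frames = {}
    for s in samples:
        df = _records_to_site_table(per_sample[s]).set_index(SITE_COLUMNS)
        frames[s] = df
    totals = pd.concat([frames[s]["total"] for s in samples], axis=1, keys=samples)
    meths = pd.concat([frames[s]["meth"] for s in samples], axis=1, keys=samples)
    keep = (totals >= min_cov).all(axis=1)
    totals, meths = totals.loc[keep], meths.loc[keep]
    pct = 100.0 * meths / totals
    return {s: float(pct[s].mean()) for s in samples}
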