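"""Direction-aware counteraction analysis.

A cytosine is *counteracted* when it changes significantly with aging
(aged-STD vs young-STD) and significantly in the opposite direction
with environmental enrichment (aged-ENR vs aged-STD).  The module
classifies every site of the shared test universe, verifies restoration
to young methylation levels, and runs the two published negative
controls: a random-sampling overlap control and a split-half control in
which the aged-STD group is divided into independent discovery and
comparison subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dm
from .dm import SITE_COLUMNS, CytosineCountMatrix

CLASSES = ["counteracted", "same_direction", "age_only", "enr_only", "unaffected"]


def percentage(count: int, denominator: int) -> float:
    """Share of a set, as a percentage rounded to two decimals."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * count / denominator, 2)


def hypergeom_overlap_p(overlap: int, set1: int, set2: int, universe: int) -> float:
    """One-sided (upper tail) hypergeometric p for an overlap of two
    subsets of a shared universe: P(X >= overlap)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set1, set2))


@dataclass
class CounteractionReport:
    table: pd.DataFrame  # site keys + class, directions, diffs
    summary: dict = field(default_factory=dict)

    def sites_in_class(self, cls: str) -> pd.DataFrame:
        return self.table[self.table["class"] == cls]


def classify_counteraction(
    age_dm: pd.DataFrame, enr_dm: pd.DataFrame
) -> CounteractionReport:
    """Classify every shared site by its aging/enrichment response.

    ``age_dm`` is the called result table of aged-STD vs young-STD,
    ``enr_dm`` of aged-ENR vs aged-STD; both must carry ``significant``
    and ``direction`` columns from :func:`methylenr.dm.call_dm` and must
    share a site universe (sites present in only one comparison are
    classified from the available evidence and flagged ``partial``).

    Overlap significance is a one-sided hypergeometric test of the two
    significant sets against the shared universe; counteracted
    percentages are reported per context and per aging-direction
    stratum.
    """
    a = age_dm.set_index(SITE_COLUMNS)
    e = enr_dm.set_index(SITE_COLUMNS)
    shared = a.index.intersection(e.index)
    if len(shared) == 0:
        raise ValueError(
            "age and enrichment results share no sites: run both comparisons "
            "on the same united universe"
        )
    only_a = a.index.difference(e.index)
    only_e = e.index.difference(a.index)

    a_s = a.loc[shared]
    e_s = e.loc[shared]
    age_sig = a_s["significant"].to_numpy()
    enr_sig = e_s["significant"].to_numpy()
    age_dir = a_s["direction"].to_numpy()
    enr_dir = e_s["direction"].to_numpy()

    cls = np.full(len(shared), "unaffected", dtype=object)
    cls[age_sig & ~enr_sig] = "age_only"
    cls[~age_sig & enr_sig] = "enr_only"
    both = age_sig & enr_sig
    cls[both & (age_dir != enr_dir)] = "counteracted"
    cls[both & (age_dir == enr_dir)] = "same_direction"

    table = pd.DataFrame(
        {
            "class": cls,
            "age_direction": age_dir,
            "enr_direction": enr_dir,
            "age_diff": a_s["meth_diff"].to_numpy(),
            "enr_diff": e_s["meth_diff"].to_numpy(),
            "partial": False,
        },
        index=shared,
    )
    # sites seen in only one comparison: classified from available evidence
    partial_frames = []
    for idx_set, frame, which in ((only_a, a, "age"), (only_e, e, "enr")):
        if len(idx_set) == 0:
            continue
        sub = frame.loc[idx_set]
        sig = sub["significant"].to_numpy(dtype=bool)
        partial_frames.append(
            pd.DataFrame(
                {
                    "class": np.where(sig, f"{which}_only", "unaffected"),
                    "age_direction": sub["direction"].to_numpy()
                    if which == "age"
                    else "none",
                    "enr_direction": sub["direction"].to_numpy()
                    if which == "enr"
                    else "none",
                    "age_diff": sub["meth_diff"].to_numpy()
                    if which == "age"
                    else np.nan,
                    "enr_diff": sub["meth_diff"].to_numpy()
                    if which == "enr"
                    else np.nan,
                    "partial": True,
                },
                index=idx_set,
            )
        )
    if partial_frames:
        table = pd.concat([table, *partial_frames])
    table.index.names = SITE_COLUMNS
    table = table.reset_index()  # context becomes an ordinary column

    shared_tab = table[~table["partial"]]
    n_universe = len(shared_tab)
    n_age = int((shared_tab["class"].isin(["counteracted", "same_direction", "age_only"])).sum())
    n_enr = int((shared_tab["class"].isin(["counteracted", "same_direction", "enr_only"])).sum())
    n_both = int((shared_tab["class"].isin(["counteracted", "same_direction"])).sum())
    n_count = int((shared_tab["class"] == "counteracted").sum())

    summary: dict = {
        "n_universe": n_universe,
        "n_age_dm": n_age,
        "n_enr_dm": n_enr,
        "n_overlap": n_both,
        "n_counteracted": n_count,
        "pct_age_dm_counteracted": percentage(n_count, n_age),
        "overlap_p": hypergeom_overlap_p(n_both, n_age, n_enr, n_universe),
        "class_counts": {
            c: int((shared_tab["class"] == c).sum()) for c in CLASSES
        },
    }
    # per context and per aging-direction stratum
    by_context = {}
    for ctx, sub in shared_tab.groupby("context"):
        n_age_ctx = int(sub["class"].isin(
            ["counteracted", "same_direction", "age_only"]).sum())
        n_cnt_ctx = int((sub["class"] == "counteracted").sum())
        strata = {}
        for d in ("hypo", "hyper"):
            stratum = sub[sub["age_direction"] == d]
            n_age_d = int(stratum["class"].isin(
                ["counteracted", "same_direction", "age_only"]).sum())
            n_cnt_d = int((stratum["class"] == "counteracted").sum())
            strata[d] = {
                "n_age_dm": n_age_d,
                "n_counteracted": n_cnt_d,
                "pct_counteracted": percentage(n_cnt_d, n_age_d),
            }
        by_context[ctx] = {
            "n_age_dm": n_age_ctx,
            "n_counteracted": n_cnt_ctx,
            "pct_counteracted": percentage(n_cnt_ctx, n_age_ctx),
            "by_age_direction": strata,
        }
    summary["by_context"] = by_context
    return CounteractionReport(table=table, summary=summary)


def check_restoration(
    matrix: CytosineCountMatrix,
    counteracted_sites: pd.DataFrame,
    young_group: str,
    aged_enr_group: str,
    q_threshold: float = 0.001,
    diff_threshold: float = 25.0,
    adjust: str = "slim",
) -> dict:
    """Fraction of counteracted sites restored to young levels.

    Runs the per-site test young-STD vs aged-ENR restricted to the
    counteracted sites and reports the fraction that is NOT
    significantly different (restored).  Returns NaN for an empty set.
    """
    if len(counteracted_sites) == 0:
        return {"n_sites": 0, "restoration_fraction": float("nan")}
    keys = pd.MultiIndex.from_frame(counteracted_sites[SITE_COLUMNS])
    mask = matrix.site_keys().isin(keys)
    sub = matrix.subset_sites(np.asarray(mask))
    res = dm.test_diffmeth(sub, young_group, aged_enr_group)
    res["qvalue"] = dm.adjust_qvalues(res["pvalue"].to_numpy(), method=adjust)
    res = dm.call_dm(res, q_threshold=q_threshold, diff_threshold=diff_threshold)
    n = len(res)
    n_restored = int((~res["significant"]).sum())
    return {
        "n_sites": n,
        "n_restored": n_restored,
        "restoration_fraction": n_restored / n,
    }


@dataclass
class ControlResult:
    observed_fraction: float
    resampled_fractions: np.ndarray
    n_resamples: int
    seed: int

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.resampled_fractions))

    @property
    def empirical_p(self) -> float:
        """Fraction of resamples at least as extreme as the observation,
        with the add-one convention (never exactly zero)."""
        ge = int(np.sum(self.resampled_fractions >= self.observed_fraction))
        return (ge + 1) / (self.n_resamples + 1)


def random_sampling_control(
    enr_dm_count: int,
    universe: pd.DataFrame | int,
    age_dm: pd.DataFrame,
    observed_fraction: float,
    n_resamples: int = 100,
    seed: int = 0,
) -> ControlResult:
    """Chance-overlap control: draw ``enr_dm_count`` sites uniformly
    without replacement from the universe and measure the fraction
    falling in the age-affected set (direction-blind).

    ``universe`` may be the united site table or simply its size with
    ``age_dm`` giving the age-affected site count — the overlap of a
    uniform draw depends only on the two set sizes.
    """
    n_universe = universe if isinstance(universe, int) else len(universe)
    n_age = age_dm if isinstance(age_dm, int) else len(age_dm)
    if enr_dm_count > n_universe:
        raise ValueError("cannot sample more sites than the universe holds")
    rng = np.random.default_rng(seed)
    # overlap of a uniform without-replacement draw is hypergeometric
    overlaps = rng.hypergeometric(n_age, n_universe - n_age, enr_dm_count,
                                  size=n_resamples)
    fractions = overlaps / enr_dm_count
    return ControlResult(
        observed_fraction=observed_fraction,
        resampled_fractions=fractions,
        n_resamples=n_resamples,
        seed=seed,
    )


def split_half_control(
    per_sample: dict,
    groups: dict[str, str],
    young_group: str = "young_std",
    aged_std_group: str = "aged_std",
    aged_enr_group: str = "aged_enr",
    subset_size: int = 3,
    seed: int = 0,
    q_threshold: float = 0.001,
    diff_threshold: float = 25.0,
    min_per_group: int = 3,
    adjust: str = "slim",
) -> dict:
    """Split-half independence control.

    The aged-STD samples are split at random into a discovery subset
    (compared with young-STD to define age effects) and a disjoint
    comparison subset (compared with aged-ENR to define enrichment
    effects); the counteraction classifier then runs on the two
    independent result sets and the hypergeometric overlap p is
    returned.  Requires at least ``2 * subset_size`` aged-STD samples.
    """
    aged_std = [s for s in per_sample if groups[s] == aged_std_group]
    if len(aged_std) < 2 * subset_size:
        raise ValueError(
            f"need >= {2 * subset_size} {aged_std_group} samples, have {len(aged_std)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(aged_std))
    discovery = [aged_std[i] for i in perm[:subset_size]]
    comparison = [aged_std[i] for i in perm[subset_size : 2 * subset_size]]

    young = [s for s in per_sample if groups[s] == young_group]
    aged_enr = [s for s in per_sample if groups[s] == aged_enr_group]

    def _run(g1_samples, g1, g2_samples, g2):
        sub = {s: per_sample[s] for s in g1_samples + g2_samples}
        gmap = {s: g1 for s in g1_samples} | {s: g2 for s in g2_samples}
        mat = dm.unite(sub, gmap, min_per_group=min_per_group)
        res = dm.test_diffmeth(mat, g1, g2)
        res["qvalue"] = dm.adjust_qvalues(res["pvalue"].to_numpy(), method=adjust)
        return dm.call_dm(res, q_threshold=q_threshold, diff_threshold=diff_threshold)

    age_res = _run(young, "young", discovery, "aged_discovery")
    enr_res = _run(comparison, "aged_comparison", aged_enr, "aged_enr")
    report = classify_counteraction(age_res, enr_res)
    return {
        "overlap_p": report.summary["overlap_p"],
        "n_counteracted": report.summary["n_counteracted"],
        "summary": report.summary,
        "discovery_samples": discovery,
        "comparison_samples": comparison,
    }


def distribution_summary(
    matrix: CytosineCountMatrix,
    sites: pd.DataFrame,
    group_names: list[str] | None = None,
) -> dict:
    """Methylation-percentage distributions at a site set, per group.

    Per site and group: mean of per-sample percentages (samples missing
    the site are skipped).  Per group: the median over sites — the
    headline summary of how enrichment restores aged methylation
    towards young levels.
    """
    keys = pd.MultiIndex.from_frame(sites[SITE_COLUMNS])
    mask = np.asarray(matrix.site_keys().isin(keys))
    sub = matrix.subset_sites(mask)
    if group_names is None:
        group_names = sorted(set(matrix.groups.values()))
    out = {}
    with np.errstate(invalid="ignore"):
        pct = 100.0 * sub.meth / sub.total
    for g in group_names:
        cols = sub.sample_indices(g)
        site_means = np.nanmean(pct[:, cols], axis=1)
        out[g] = {
            "per_site_mean_pct": site_means,
            "median": float(np.median(site_means)) if site_means.size else float("nan"),
        }
    return out
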