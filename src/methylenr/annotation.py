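"""Genomic feature annotation and enrichment statistics.

Builds a feature catalog from supplied interval sets (CpG islands,
exons, introns, enhancers, super-enhancers) plus derived classes:
shores (2 kb flanks of islands, islands excluded), promoters (TSS
+/- 1 kb) and intergenic (complement of gene bodies and promoters).
Feature classes are tested independently — a cytosine may belong to
several — and enrichment of a differentially methylated set against the
covered background is fitted as a logistic regression of "is dm" on
"in feature", whose exponentiated coefficient is the odds ratio.
Gene-set over-representation is the one-sided (upper tail)
hypergeometric test on the background universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureInterval, GeneRecord, GeneSet

SHORE_WIDTH = 2000  # bp each side of a CpG island
PROMOTER_HALF_WIDTH = 1000  # bp each side of the TSS


# ---------------------------------------------------------------------------
# interval algebra on sorted, merged arrays (per chromosome)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def _subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    """a minus b, both merged-sorted; linear sweep."""
    out = []
    bi = 0
    for s, e in a:
        cur = s
        while bi < len(b) and b[bi][1] <= cur:
            bi += 1
        j = bi
        while j < len(b) and b[j][0] < e:
            bs, be = b[j]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            j += 1
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


class _IntervalSet:
    """Merged intervals per chromosome with O(log n) point membership."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.intervals = {c: _merge(iv) for c, iv in intervals.items()}
        for c, iv in self.intervals.items():
            self._starts[c] = np.array([s for s, _ in iv], dtype=np.int64)
            self._ends[c] = np.array([e for _, e in iv], dtype=np.int64)

    @classmethod
    def from_features(cls, features: list[FeatureInterval]) -> "_IntervalSet":
        d: dict[str, list[tuple[int, int]]] = {}
        for f in features:
            d.setdefault(f.chrom, []).append((f.start, f.end))
        return cls(d)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Membership of 1-based positions: pos in (start, end]."""
        out = np.zeros(len(pos), dtype=bool)
        for c in np.unique(chrom):
            sel = chrom == c
            starts = self._starts.get(c)
            if starts is None or starts.size == 0:
                continue
            ends = self._ends[c]
            p = pos[sel]
            # interval index whose start is the last one < pos
            i = np.searchsorted(starts, p, side="left") - 1
            ok = (i >= 0) & (p <= ends[np.clip(i, 0, None)])
            out[sel] = ok
        return out

    def total_span(self) -> int:
        return sum(int(e - s) for iv in self.intervals.values() for s, e in iv)


@dataclass
class FeatureCatalog:
    """Interval sets per feature class, with membership queries."""

    sets: dict[str, _IntervalSet]
    genes: list[GeneRecord] = field(default_factory=list)

    def classify(self, chrom: np.ndarray, pos: np.ndarray) -> pd.DataFrame:
        """Boolean membership matrix (sites x feature classes)."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        return pd.DataFrame(
            {name: s.contains(chrom, pos) for name, s in self.sets.items()}
        )

    @property
    def feature_classes(self) -> list[str]:
        return list(self.sets)


def build_catalog(
    islands: list[FeatureInterval],
    exons: list[FeatureInterval],
    introns: list[FeatureInterval],
    enhancers: list[FeatureInterval],
    super_enhancers: list[FeatureInterval],
    genes: list[GeneRecord],
) -> FeatureCatalog:
    """Assemble the catalog; derive shores, promoters and intergenic.

    Shores are the 2 kb flanks of every CpG island with any island
    overlap removed and clipped at position 0; promoters span TSS
    +/- 1 kb (2 kb + 1 position); intergenic is the complement of gene
    bodies (exons + introns) and promoters.
    """
    island_set = _IntervalSet.from_features(islands)

    shore_raw: dict[str, list[tuple[int, int]]] = {}
    for c, ivs in island_set.intervals.items():
        for s, e in ivs:
            shore_raw.setdefault(c, []).append((max(0, s - SHORE_WIDTH), s))
            shore_raw.setdefault(c, []).append((e, e + SHORE_WIDTH))
    shores = {
        c: _subtract(_merge(iv), island_set.intervals.get(c, []))
        for c, iv in shore_raw.items()
    }

    promoter_raw: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        # TSS at 1-based t covers 1-based t-1000 .. t+1000 -> BED [t-1001, t+1000)
        promoter_raw.setdefault(g.chrom, []).append(
            (max(0, g.tss_pos - PROMOTER_HALF_WIDTH - 1), g.tss_pos + PROMOTER_HALF_WIDTH)
        )

    exon_set = _IntervalSet.from_features(exons)
    intron_set = _IntervalSet.from_features(introns)
    promoter_set = _IntervalSet(promoter_raw)

    # intergenic: complement of gene bodies and promoters over the span
    # covered by any supplied interval (open-ended complement per chrom)
    genic: dict[str, list[tuple[int, int]]] = {}
    all_chroms = set()
    for s in (exon_set, intron_set, promoter_set, island_set):
        all_chroms.update(s.intervals)
    for f in enhancers + super_enhancers:
        all_chroms.add(f.chrom)
    span_end: dict[str, int] = {c: 0 for c in all_chroms}
    for iset in (exon_set, intron_set, promoter_set, island_set):
        for c, ivs in iset.intervals.items():
            if ivs:
                span_end[c] = max(span_end[c], ivs[-1][1])
    for f in enhancers + super_enhancers:
        span_end[f.chrom] = max(span_end[f.chrom], f.end)
    for c in all_chroms:
        body = _merge(
            exon_set.intervals.get(c, [])
            + intron_set.intervals.get(c, [])
            + promoter_set.intervals.get(c, [])
        )
        # extend the complement comfortably past every known interval
        genic[c] = _subtract([(0, span_end[c] + 10_000_000)], body)

    return FeatureCatalog(
        sets={
            "cpg_island": island_set,
            "shore": _IntervalSet(shores),
            "promoter": promoter_set,
            "enhancer": _IntervalSet.from_features(enhancers),
            "super_enhancer": _IntervalSet.from_features(super_enhancers),
            "exon": exon_set,
            "intron": intron_set,
            "intergenic": _IntervalSet(genic),
        },
        genes=genes,
    )


# ---------------------------------------------------------------------------
# feature enrichment (logistic regression)


def feature_enrichment(
    dm_sites: pd.DataFrame,
    background_sites: pd.DataFrame,
    catalog: FeatureCatalog,
) -> pd.DataFrame:
    """Per-feature-class enrichment of dm sites within the background.

    For every class a logistic regression of the binary outcome "site
    is differentially methylated" on the binary predictor "site lies in
    the feature" is fitted over the background (which contains the dm
    sites); log2 of the exponentiated coefficient is reported with a
    one-sided p-value (direction carried by the sign) and FDR adjustment
    across classes.  A zero margin yields an infinite odds ratio, which
    is flagged, with a Haldane-corrected estimate alongside.
    """
    bg_keys = pd.MultiIndex.from_frame(
        background_sites[["chrom", "pos"]].astype({"pos": np.int64})
    )
    dm_keys = pd.MultiIndex.from_frame(
        dm_sites[["chrom", "pos"]].astype({"pos": np.int64})
    )
    if not dm_keys.isin(bg_keys).all():
        raise ValueError("dm sites must be a subset of the background sites")

    is_dm = np.asarray(bg_keys.isin(dm_keys))
    membership = catalog.classify(
        background_sites["chrom"].to_numpy(), background_sites["pos"].to_numpy()
    )

    rows = []
    for cls in catalog.feature_classes:
        in_feat = membership[cls].to_numpy()
        a = int(np.sum(is_dm & in_feat))  # dm in feature
        b = int(np.sum(is_dm & ~in_feat))
        c = int(np.sum(~is_dm & in_feat))
        d = int(np.sum(~is_dm & ~in_feat))
        flagged = min(a, b, c, d) == 0
        hald = np.log2(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
        if flagged:
            if a * d > 0 and b * c == 0:
                log2_or, p = np.inf, 0.0
            elif b * c > 0 and a * d == 0:
                log2_or, p = -np.inf, 0.0
            else:
                log2_or, p = np.nan, 1.0
        else:
            X = sm.add_constant(in_feat.astype(float))
            fit = sm.GLM(is_dm.astype(float), X, family=sm.families.Binomial()).fit()
            coef = fit.params[1]
            log2_or = coef / np.log(2.0)
            zval = fit.tvalues[1]
            p = float(stats.norm.sf(abs(zval)))  # one-sided; sign in log2_or
        rows.append(
            {
                "feature_class": cls,
                "count_dm_in": a,
                "count_dm_out": b,
                "count_bg_in": c,
                "count_bg_out": d,
                "log2_odds_ratio": float(log2_or),
                "log2_odds_ratio_haldane": float(hald),
                "pvalue": float(p),
                "zero_margin": flagged,
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# gene annotation


def annotate_nearest_tss(
    sites: pd.DataFrame, genes: list[GeneRecord]
) -> pd.DataFrame:
    """Map every site to the gene with the nearest TSS.

    Absolute distance wins; exact ties prefer the gene for which the
    site lies upstream on the gene's strand, then lexicographic
    gene_id, and are flagged.
    """
    if not genes:
        raise ValueError("empty gene table")
    gene_df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss_pos for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).sort_values(["chrom", "tss", "gene_id"], kind="mergesort")

    out_gene = np.empty(len(sites), dtype=object)
    out_dist = np.zeros(len(sites), dtype=np.int64)
    out_tie = np.zeros(len(sites), dtype=bool)
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()

    for c in np.unique(chroms):
        g = gene_df[gene_df["chrom"] == c]
        if g.empty:  # fall back to all genes on other chromosomes? no: unmapped
            sel = chroms == c
            out_gene[sel] = None
            continue
        tss = g["tss"].to_numpy()
        ids = g["gene_id"].to_numpy()
        strands = g["strand"].to_numpy()
        sel = np.flatnonzero(chroms == c)
        for i in sel:
            p = pos[i]
            dists = np.abs(tss - p)
            dmin = dists.min()
            cand = np.flatnonzero(dists == dmin)
            tie = len(cand) > 1
            if tie:
                # prefer the gene where the site is upstream of the TSS
                # on the gene's strand, then lexicographic id
                def rank(j):
                    upstream = (p < tss[j]) if strands[j] == "+" else (p > tss[j])
                    return (0 if upstream else 1, ids[j])

                cand = sorted(cand, key=rank)
            j = cand[0]
            out_gene[i] = ids[j]
            out_dist[i] = dmin
            out_tie[i] = tie

    res = sites.copy()
    res["gene_id"] = out_gene
    res["tss_distance"] = out_dist
    res["tss_tie"] = out_tie
    return res


def call_dm_genes(
    annotated_dm_sites: pd.DataFrame, min_sites: int = 4
) -> pd.DataFrame:
    """Genes with at least ``min_sites`` annotated dm cytosines
    (CpG and CpH counted together); the threshold is inclusive."""
    counts = (
        annotated_dm_sites.dropna(subset=["gene_id"])
        .groupby("gene_id")
        .size()
        .rename("n_dm_cytosines")
        .reset_index()
    )
    return counts[counts["n_dm_cytosines"] >= min_sites].reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene-set over-representation


def hypergeom_test(q: int, m: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p: probability of at least ``q``
    successes when drawing ``k`` from ``m`` successes and ``n``
    failures — P(X >= q)."""
    return float(stats.hypergeom.sf(q - 1, m + n, m, k))


def geneset_enrichment(
    query_genes: set[str] | list[str],
    background_genes: set[str] | list[str],
    gene_sets: list[GeneSet],
) -> pd.DataFrame:
    """One-sided over-representation of each gene set in the query.

    q = |query ∩ set|, m = |background ∩ set|, n = |background \\ set|,
    k = |query|; FDR across sets.
    """
    query = set(query_genes)
    background = set(background_genes)
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    rows = []
    for gs in gene_sets:
        members = gs.members & background
        q = len(query & members)
        m = len(members)
        n = len(background) - m
        k = len(query)
        rows.append(
            {
                "set_name": gs.name,
                "n_query_in_set": q,
                "n_set_in_background": m,
                "n_query": k,
                "pvalue": hypergeom_test(q, m, n, k),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def gene_direction(annotated_dm_sites: pd.DataFrame) -> pd.DataFrame:
    """Dominant dm direction per gene (majority of its dm cytosines);
    exact ties are labelled "mixed"."""
    def dominant(sub):
        counts = sub["direction"].value_counts()
        hyper = counts.get("hyper", 0)
        hypo = counts.get("hypo", 0)
        if hyper > hypo:
            return "hyper"
        if hypo > hyper:
            return "hypo"
        return "mixed"

    return (
        annotated_dm_sites.dropna(subset=["gene_id"])
        .groupby("gene_id")
        .apply(dominant, include_groups=False)
        .rename("direction")
        .reset_index()
    )
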