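"""End-to-end orchestration: counts -> dm calls -> counteraction ->
annotation/enrichment -> motifs, with run metadata and a JSON summary.

The canonical comparisons of the four-group design are
``age``: aged-STD vs young-STD (the aging effect) and
``enr``: aged-ENR vs aged-STD (the enrichment effect in aged animals);
counteraction is their direction-aware intersection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, counteraction, dm, motifs
from . import io as mio

log = logging.getLogger("methylenr")


@dataclass
class RunConfig:
    """Pipeline-level thresholds; defaults are the study's published
    analysis constants."""

    min_cov: int = 10
    upper_percentile: float = 99.9
    min_per_group: int = 3
    q_threshold: float = 0.001
    diff_threshold: float = 25.0
    adjust: str = "slim"
    gene_min_sites: int = 4
    motif_min_score: float = 0.90
    n_resamples: int = 100
    seed: int = 0
    contexts: tuple = ("CpG", "CpH")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contexts"] = list(self.contexts)
        return d


def load_fixture_counts(fixture_dir: str | Path) -> tuple[dict, dict[str, str]]:
    """Read per-sample coverage files from a fixture directory whose
    sample names encode the group (``<group>_<i>.cov.tsv``)."""
    counts_dir = Path(fixture_dir) / "counts"
    if not counts_dir.is_dir():
        raise FileNotFoundError(f"missing counts directory: {counts_dir}")
    per_sample, groups = {}, {}
    for path in sorted(counts_dir.glob("*.cov.tsv")):
        sample = path.name[: -len(".cov.tsv")]
        group = sample.rsplit("_", 1)[0]
        per_sample[sample] = mio.read_coverage_file(path)
        groups[sample] = group
    if not per_sample:
        raise FileNotFoundError(f"no *.cov.tsv files in {counts_dir}")
    return per_sample, groups


def _dm_comparison(
    per_sample: dict,
    groups: dict[str, str],
    group1: str,
    group2: str,
    context: str,
    cfg: RunConfig,
):
    """Filter, unite and test one two-group comparison in one context."""
    selected = {
        s: dm.filter_by_coverage(
            [r for r in recs if r.context == context],
            min_cov=cfg.min_cov,
            upper_percentile=cfg.upper_percentile,
        )
        for s, recs in per_sample.items()
        if groups[s] in (group1, group2)
    }
    matrix = dm.unite(
        selected,
        {s: groups[s] for s in selected},
        min_per_group=cfg.min_per_group,
    )
    res = dm.test_diffmeth(matrix, group1, group2)
    res["qvalue"] = dm.adjust_qvalues(res["pvalue"].to_numpy(), method=cfg.adjust)
    res = dm.call_dm(
        res, q_threshold=cfg.q_threshold, diff_threshold=cfg.diff_threshold
    )
    return matrix, res


def run_full(
    fixture_dir: str | Path,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
    controls: tuple = ("random", "split"),
) -> dict:
    """Run the whole analysis on a fixture-layout directory.

    Writes per-context dm tables, the counteraction report, enrichment
    tables and ``summary.json``; returns the summary dict.  The run is
    deterministic for a fixed config and seed.
    """
    cfg = cfg or RunConfig()
    fixture_dir = Path(fixture_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for required in ("counts", "genes.tsv"):
        if not (fixture_dir / required).exists():
            raise FileNotFoundError(f"missing input: {fixture_dir / required}")

    per_sample, groups = load_fixture_counts(fixture_dir)
    genes = mio.read_gene_table(fixture_dir / "genes.tsv")
    feature_dir = fixture_dir / "features"

    def _read_feats(name, cls):
        p = feature_dir / f"{name}.bed"
        return mio.read_bed(p, cls) if p.exists() else []

    catalog = annotation.build_catalog(
        islands=_read_feats("cpg_islands", "cpg_island"),
        exons=_read_feats("exons", "exon"),
        introns=_read_feats("introns", "intron"),
        enhancers=_read_feats("enhancers", "enhancer"),
        super_enhancers=_read_feats("super_enhancers", "super_enhancer"),
        genes=genes,
    )

    summary: dict = {"config": cfg.to_dict(), "contexts": {}}
    all_dm_annotated = []
    background_ids: set[str] = set()
    dm_ids: set[str] = set()
    counteraction_tables = {}

    for context in cfg.contexts:
        ctx_summary: dict = {}
        age_matrix, age_res = _dm_comparison(
            per_sample, groups, "young_std", "aged_std", context, cfg
        )
        enr_matrix, enr_res = _dm_comparison(
            per_sample, groups, "aged_std", "aged_enr", context, cfg
        )
        log.info(
            "%s: united %d (age) / %d (enr) sites",
            context, age_matrix.n_sites, enr_matrix.n_sites,
        )
        mio.write_dm_table(age_res, out / f"dm_age_{context}.tsv")
        mio.write_dm_table(enr_res, out / f"dm_enr_{context}.tsv")
        ctx_summary["age_dm"] = dm.dm_counts(age_res)
        ctx_summary["enr_dm"] = dm.dm_counts(enr_res)

        report = counteraction.classify_counteraction(age_res, enr_res)
        ctx_summary["counteraction"] = report.summary
        counteraction_tables[context] = report.table
        report.table.to_csv(
            out / f"counteraction_{context}.tsv", sep="\t", index=False
        )

        counteracted = report.table[report.table["class"] == "counteracted"]
        # restoration needs all four groups in one united matrix
        full_matrix = dm.unite(
            {
                s: dm.filter_by_coverage(
                    [r for r in recs if r.context == context],
                    min_cov=cfg.min_cov,
                    upper_percentile=cfg.upper_percentile,
                )
                for s, recs in per_sample.items()
            },
            groups,
            min_per_group=cfg.min_per_group,
        )
        ctx_summary["restoration"] = {
            k: v
            for k, v in counteraction.check_restoration(
                full_matrix,
                counteracted,
                "young_std",
                "aged_enr",
                q_threshold=cfg.q_threshold,
                diff_threshold=cfg.diff_threshold,
                adjust=cfg.adjust,
            ).items()
        }
        dist = counteraction.distribution_summary(
            full_matrix, counteracted,
            ["young_std", "young_enr", "aged_std", "aged_enr"],
        ) if len(counteracted) else {}
        ctx_summary["medians"] = {g: d["median"] for g, d in dist.items()}

        if "random" in controls and ctx_summary["enr_dm"]["n_significant"] > 0:
            ctrl = counteraction.random_sampling_control(
                enr_dm_count=report.summary["n_enr_dm"],
                universe=report.summary["n_universe"],
                age_dm=report.summary["n_age_dm"],
                observed_fraction=(
                    report.summary["n_overlap"] / report.summary["n_enr_dm"]
                    if report.summary["n_enr_dm"] else float("nan")
                ),
                n_resamples=cfg.n_resamples,
                seed=cfg.seed,
            )
            ctx_summary["random_control"] = {
                "observed_fraction": ctrl.observed_fraction,
                "mean_resampled_fraction": ctrl.mean_fraction,
                "empirical_p": ctrl.empirical_p,
                "n_resamples": ctrl.n_resamples,
            }
        if "split" in controls:
            ctx_records = {
                s: [r for r in recs if r.context == context]
                for s, recs in per_sample.items()
            }
            n_aged_std = sum(1 for s in groups if groups[s] == "aged_std")
            if n_aged_std >= 6:
                split = counteraction.split_half_control(
                    {
                        s: dm.filter_by_coverage(
                            recs, cfg.min_cov, cfg.upper_percentile
                        )
                        for s, recs in ctx_records.items()
                    },
                    groups,
                    seed=cfg.seed,
                    q_threshold=cfg.q_threshold,
                    diff_threshold=cfg.diff_threshold,
                    min_per_group=cfg.min_per_group,
                    adjust=cfg.adjust,
                )
                ctx_summary["split_half_control"] = {
                    "overlap_p": split["overlap_p"],
                    "n_counteracted": split["n_counteracted"],
                }

        # feature enrichment of counteracted sites vs the united background
        bg = age_res[["chrom", "pos"]]
        dm_sites = counteracted[["chrom", "pos"]]
        if len(dm_sites):
            enr_table = annotation.feature_enrichment(dm_sites, bg, catalog)
            enr_table.to_csv(
                out / f"feature_enrichment_{context}.tsv", sep="\t", index=False
            )
            ctx_summary["feature_enrichment"] = enr_table[
                ["feature_class", "log2_odds_ratio", "pvalue", "adjusted_p"]
            ].to_dict(orient="records")

        ann = annotation.annotate_nearest_tss(
            counteracted.rename(columns={"age_direction": "direction"}), genes
        )
        all_dm_annotated.append(ann)
        background_ids.update(
            f"{c}:{p}:{s}"
            for c, p, s in zip(age_res["chrom"], age_res["pos"], age_res["strand"])
        )
        dm_ids.update(
            f"{c}:{p}:{s}"
            for c, p, s in zip(
                counteracted["chrom"], counteracted["pos"], counteracted["strand"]
            )
        )
        summary["contexts"][context] = ctx_summary

    # gene-level: CpG and CpH dm cytosines counted together
    annotated = (
        pd.concat(all_dm_annotated, ignore_index=True)
        if all_dm_annotated
        else pd.DataFrame(columns=["gene_id"])
    )
    dm_genes = annotation.call_dm_genes(annotated, min_sites=cfg.gene_min_sites)
    dm_genes.to_csv(out / "dm_genes.tsv", sep="\t", index=False)
    summary["n_dm_genes"] = int(len(dm_genes))

    gmt_path = fixture_dir / "gene_sets.gmt"
    if gmt_path.exists() and len(dm_genes):
        gene_sets = mio.read_gmt(gmt_path)
        background_genes = {g.gene_id for g in genes}
        gs = annotation.geneset_enrichment(
            set(dm_genes["gene_id"]) & background_genes,
            background_genes,
            gene_sets,
        )
        gs.to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)
        summary["geneset_enrichment"] = gs.to_dict(orient="records")

    pwm_path = fixture_dir / "mecp2_synthetic.pwm"
    fasta_path = fixture_dir / "windows.fa"
    if pwm_path.exists() and fasta_path.exists():
        pwm = motifs.read_pwm(pwm_path)
        windows = motifs.read_window_fasta(fasta_path)
        hits = motifs.scan_sites(windows, pwm, min_score_frac=cfg.motif_min_score)
        bg_with_windows = background_ids & set(windows)
        test = motifs.motif_test([hits], dm_ids & bg_with_windows, bg_with_windows)
        test.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
        summary["motif_enrichment"] = test.to_dict(orient="records")
        if "CpG" in counteraction_tables:
            tab = counteraction_tables["CpG"].copy()
            tab["site_id"] = (
                tab["chrom"].astype(str)
                + ":" + tab["pos"].astype(str)
                + ":" + tab["strand"].astype(str)
            )
            summary["motif_direction_breakdown"] = motifs.target_direction_breakdown(
                hits, tab
            )

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def report(results_dir: str | Path) -> str:
    """Human-readable digest of a results directory."""
    results_dir = Path(results_dir)
    summary_path = results_dir / "summary.json"
    if not summary_path.exists():
        return f"incomplete results directory: missing {summary_path}"
    with open(summary_path) as fh:
        summary = json.load(fh)
    lines = ["methylenr run summary", "====================="]
    for context, ctx in summary.get("contexts", {}).items():
        lines.append(f"\n[{context}]")
        age = ctx.get("age_dm", {})
        enr = ctx.get("enr_dm", {})
        lines.append(
            f"  aging dm sites: {age.get('n_significant', 0)} of "
            f"{age.get('n_tested', 0)} tested "
            f"({age.get('n_hypo', 0)} hypo / {age.get('n_hyper', 0)} hyper)"
        )
        lines.append(
            f"  enrichment dm sites: {enr.get('n_significant', 0)} "
            f"({enr.get('n_hypo', 0)} hypo / {enr.get('n_hyper', 0)} hyper)"
        )
        c = ctx.get("counteraction", {})
        n_cnt = c.get("n_counteracted", 0)
        n_age = c.get("n_age_dm", 0)
        pct = counteraction.percentage(n_cnt, n_age) if n_age else float("nan")
        lines.append(
            f"  counteracted: {n_cnt} of {n_age} age-dm sites ({pct}%)"
        )
        med = ctx.get("medians", {})
        if med:
            lines.append(
                "  medians (%): "
                + ", ".join(f"{g}={m:.2f}" for g, m in med.items())
            )
        rest = ctx.get("restoration", {})
        if rest.get("n_sites"):
            lines.append(
                f"  restored to young levels: "
                f"{100 * rest['restoration_fraction']:.2f}% of counteracted sites"
            )
        for key, label in (
            ("random_control", "random-sampling control"),
            ("split_half_control", "split-half control"),
        ):
            if key in ctx:
                lines.append(f"  {label}: {ctx[key]}")
    lines.append(f"\ndifferentially methylated genes: {summary.get('n_dm_genes', 0)}")
    for row in summary.get("motif_enrichment", []):
        lines.append(
            f"motif {row['motif']}: q = {row['qvalue']:.3g} "
            f"({row['n_dm_with_hit']}/{row['n_dm']} dm sites with hit)"
        )
    return "\n".join(lines)
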