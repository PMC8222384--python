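"""Synthetic RRBS data with planted aging and enrichment effects.

The generator emulates the statistical structure of a four-group RRBS
aging/enrichment study: bimodal CpG methylation, near-zero CpH
methylation, overdispersed (negative-binomial) coverage, aging effects
that are predominantly hypomethylating at CpGs and hypermethylating at
CpHs, and environmental-enrichment counteraction restoring a
configurable fraction of age-affected sites to their young level.
Sites live on two synthetic chromosomes tiled with genes, CpG islands,
enhancers and super-enhancers so feature- and motif-enrichment analyses
can be exercised with known ground truth and no external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .io import CytosineRecord, FeatureInterval, GeneRecord, GeneSet
from .motifs import PWM

GROUP_NAMES = ["young_std", "young_enr", "aged_std", "aged_enr"]

# deliberately sharp synthetic test matrix (not a biological Mecp2
# motif): CpG-centred consensus so only near-exact matches score >= 90%
SYNTHETIC_MECP2_CONSENSUS = "TTCGCGAA"


def synthetic_mecp2_pwm(sharpness: float = 0.991) -> PWM:
    """A synthetic CpG-centred PWM labelled as a stand-in test matrix.

    Columns put probability ``sharpness`` on the consensus base, the
    rest spread evenly, so at a 0.90 min-max match threshold only the
    exact consensus scores as a hit.
    """
    probs = np.full((4, len(SYNTHETIC_MECP2_CONSENSUS)), (1 - sharpness) / 3)
    for j, b in enumerate(SYNTHETIC_MECP2_CONSENSUS):
        probs["ACGT".index(b), j] = sharpness
    return PWM(name="Mecp2_synthetic", probs=probs)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the study design
    (group sizes 5/5/7/7, overdispersed coverage around 30x, 78% of
    CpG aging effects hypomethylating, 74% of CpH aging effects
    hypermethylating)."""

    n_cpg: int = 20_000
    n_cph: int = 4_000
    group_sizes: dict = field(
        default_factory=lambda: {
            "young_std": 5,
            "young_enr": 5,
            "aged_std": 7,
            "aged_enr": 7,
        }
    )
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    # CpG baseline: bimodal Beta mixture; CpH baseline: near zero
    cpg_mix_weight_high: float = 0.9
    cpg_beta_high: tuple = (8.0, 2.0)
    cpg_beta_low: tuple = (2.0, 8.0)
    cph_beta: tuple = (1.0, 50.0)
    frac_age_dm: float = 0.05
    frac_age_hypo_cpg: float = 0.78
    frac_age_hyper_cph: float = 0.74
    frac_counteracted: float = 0.32
    effect_size: float = 0.35
    enhancer_enrichment_factor: float = 1.0
    motif_enrichment_factor: float = 1.0
    motif_background_rate: float = 0.03
    motif_window_halfwidth: int = 25
    site_spacing: float = 75.0  # mean bp between consecutive sites
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_age_dm",
            "frac_age_hypo_cpg",
            "frac_age_hyper_cph",
            "frac_counteracted",
            "cpg_mix_weight_high",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.effect_size < 1.0:
            raise ValueError("effect_size must lie in (0, 1)")
        if set(self.group_sizes) != set(GROUP_NAMES):
            raise ValueError(f"group_sizes must have keys {GROUP_NAMES}")
        for g, n in self.group_sizes.items():
            if n < 3:
                raise ValueError(
                    f"group {g!r} needs >= 3 samples (unite rule), got {n}"
                )
        if self.enhancer_enrichment_factor < 1:
            raise ValueError("enhancer_enrichment_factor must be >= 1")
        if self.motif_enrichment_factor < 1:
            raise ValueError("motif_enrichment_factor must be >= 1")

    def samples(self) -> list[str]:
        return [
            f"{g}_{i + 1}" for g in GROUP_NAMES for i in range(self.group_sizes[g])
        ]

    def groups(self) -> dict[str, str]:
        return {
            f"{g}_{i + 1}": g
            for g in GROUP_NAMES
            for i in range(self.group_sizes[g])
        }


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    ground_truth: pd.DataFrame
    per_sample: dict  # sample -> list[CytosineRecord]
    islands: list
    exons: list
    introns: list
    enhancers: list
    super_enhancers: list
    genes: list
    gene_sets: list
    pwm: PWM
    windows: dict  # site_id -> sequence
    n_clamped: int

    @property
    def groups(self) -> dict[str, str]:
        return self.config.groups()


# ---------------------------------------------------------------------------
# genome layout

_GENE_PITCH = 8000  # bp between gene starts
_GENE_BODY = 2000
_EXON = 300  # two terminal exons of the 3-part gene model
_ENHANCER_LEN = 500
_ENHANCER_OFFSET = 5000  # within each pitch, intergenic space
_ISLAND_LEN = 500


def _build_layout(chrom_lengths: dict[str, int]):
    """Deterministic feature tiling: one gene per 8 kb pitch (exon-
    intron-exon body of 2 kb), a CpG island over every second gene's
    TSS, an enhancer midway through each intergenic gap, every tenth
    enhancer widened into a super-enhancer."""
    islands, exons, introns, enhancers, supers, genes = [], [], [], [], [], []
    gi = 0
    for chrom, L in chrom_lengths.items():
        for start in range(1000, L - _GENE_PITCH, _GENE_PITCH):
            gi += 1
            strand = "+" if gi % 2 else "-"
            if strand == "+":
                tss = start + 1  # 1-based
                body = (start, start + _GENE_BODY)
            else:
                tss = start + _GENE_BODY
                body = (start, start + _GENE_BODY)
            genes.append(
                GeneRecord(
                    gene_id=f"G{gi:05d}",
                    gene_name=f"Gene{gi}",
                    chrom=chrom,
                    tss_pos=tss,
                    strand=strand,
                    biotype="protein_coding" if gi % 5 else "lncRNA",
                )
            )
            exons.append(FeatureInterval(chrom, body[0], body[0] + _EXON, "exon"))
            exons.append(FeatureInterval(chrom, body[1] - _EXON, body[1], "exon"))
            introns.append(
                FeatureInterval(chrom, body[0] + _EXON, body[1] - _EXON, "intron")
            )
            if gi % 2 == 0:
                isl_mid = tss - 1
                islands.append(
                    FeatureInterval(
                        chrom,
                        max(0, isl_mid - _ISLAND_LEN // 2),
                        isl_mid + _ISLAND_LEN // 2,
                        "cpg_island",
                    )
                )
            enh_start = start + _ENHANCER_OFFSET
            if gi % 10 == 0:
                supers.append(
                    FeatureInterval(
                        chrom, enh_start, enh_start + 4 * _ENHANCER_LEN,
                        "super_enhancer",
                    )
                )
            else:
                enhancers.append(
                    FeatureInterval(
                        chrom, enh_start, enh_start + _ENHANCER_LEN, "enhancer"
                    )
                )
    return islands, exons, introns, enhancers, supers, genes


def _in_intervals(pos: np.ndarray, intervals: list, chrom: str) -> np.ndarray:
    ivs = sorted((f.start, f.end) for f in intervals if f.chrom == chrom)
    if not ivs:
        return np.zeros(pos.size, dtype=bool)
    starts = np.array([s for s, _ in ivs])
    ends = np.array([e for _, e in ivs])
    i = np.searchsorted(starts, pos, side="left") - 1
    return (i >= 0) & (pos <= ends[np.clip(i, 0, None)])


# ---------------------------------------------------------------------------
# core generator


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw the full synthetic dataset.

    Per-site group means: both young groups sit at the baseline level;
    aged-STD carries the planted aging shift at age-affected sites;
    aged-ENR equals the baseline at counteracted sites and the aged-STD
    level elsewhere.  Per sample, coverage is negative-binomial and the
    methylated count binomial at the group's site level.  Shifts that
    would leave [0.01, 0.99] are clamped and counted.  Deterministic
    under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_cpg + config.n_cph

    # --- genome layout and site placement
    n_per_chrom = {
        "chrS1": n_total - n_total // 2,
        "chrS2": n_total // 2,
    }
    chrom_lengths = {
        c: int(max(n * config.site_spacing, 3 * _GENE_PITCH))
        for c, n in n_per_chrom.items()
    }
    islands, exons, introns, enhancers, supers, genes = _build_layout(chrom_lengths)

    chroms_arr, pos_arr = [], []
    for c, n in n_per_chrom.items():
        pos = np.sort(
            rng.choice(np.arange(1, chrom_lengths[c] + 1), size=n, replace=False)
        )
        chroms_arr.append(np.full(n, c, dtype=object))
        pos_arr.append(pos)
    chrom = np.concatenate(chroms_arr)
    pos = np.concatenate(pos_arr)
    context = np.array(
        ["CpG"] * config.n_cpg + ["CpH"] * config.n_cph, dtype=object
    )
    rng.shuffle(context)
    strand = rng.choice(np.array(["+", "-"]), size=n_total)

    in_enh = np.zeros(n_total, dtype=bool)
    for c in n_per_chrom:
        sel = chrom == c
        in_enh[sel] = _in_intervals(pos[sel], enhancers, c)

    # --- baseline methylation levels
    is_cpg = context == "CpG"
    baseline = np.empty(n_total)
    hi = rng.random(n_total) < config.cpg_mix_weight_high
    a_hi, b_hi = config.cpg_beta_high
    a_lo, b_lo = config.cpg_beta_low
    baseline[is_cpg & hi] = rng.beta(a_hi, b_hi, size=int((is_cpg & hi).sum()))
    baseline[is_cpg & ~hi] = rng.beta(a_lo, b_lo, size=int((is_cpg & ~hi).sum()))
    a_h, b_h = config.cph_beta
    baseline[~is_cpg] = rng.beta(a_h, b_h, size=int((~is_cpg).sum()))

    # --- plant aging effects, optionally concentrated in enhancers
    age_dm = np.zeros(n_total, dtype=bool)
    direction = np.full(n_total, "none", dtype=object)
    for ctx, frac_first_dir, first_dir in (
        ("CpG", config.frac_age_hypo_cpg, "hypo"),
        ("CpH", config.frac_age_hyper_cph, "hyper"),
    ):
        ctx_idx = np.flatnonzero(context == ctx)
        n_dm = int(round(config.frac_age_dm * ctx_idx.size))
        if n_dm == 0:
            continue
        w = np.where(in_enh[ctx_idx], config.enhancer_enrichment_factor, 1.0)
        chosen = rng.choice(ctx_idx, size=n_dm, replace=False, p=w / w.sum())
        age_dm[chosen] = True
        # direction assignment honours headroom: methylation can only be
        # lost where it exists, gained where there is room
        margin = 0.02
        n_first = int(round(frac_first_dir * n_dm))
        if first_dir == "hypo":
            eligible = baseline[chosen] >= config.effect_size + margin
        else:
            eligible = baseline[chosen] <= 1.0 - config.effect_size - margin
        elig_idx = chosen[eligible]
        rng.shuffle(elig_idx)
        first_set = elig_idx[:n_first]
        direction[first_set] = first_dir
        other = "hyper" if first_dir == "hypo" else "hypo"
        rest = np.setdiff1d(chosen, first_set)
        direction[rest] = other

    shift = np.where(
        direction == "hypo", -config.effect_size,
        np.where(direction == "hyper", config.effect_size, 0.0),
    )
    aged_std = baseline + shift
    clamped = (aged_std < 0.01) | (aged_std > 0.99)
    n_clamped = int((clamped & age_dm).sum())
    aged_std = np.clip(aged_std, 0.01, 0.99)
    aged_std = np.where(age_dm, aged_std, baseline)

    counteracted = np.zeros(n_total, dtype=bool)
    dm_idx = np.flatnonzero(age_dm)
    n_count = int(round(config.frac_counteracted * dm_idx.size))
    if n_count:
        counteracted[rng.choice(dm_idx, size=n_count, replace=False)] = True
    aged_enr = np.where(counteracted, baseline, aged_std)

    # --- gene assignment (nearest TSS, vectorised)
    gene_id = np.empty(n_total, dtype=object)
    for c in n_per_chrom:
        g = [x for x in genes if x.chrom == c]
        tss = np.array([x.tss_pos for x in g])
        ids = np.array([x.gene_id for x in g], dtype=object)
        order = np.argsort(tss)
        tss, ids = tss[order], ids[order]
        sel = chrom == c
        p = pos[sel]
        j = np.clip(np.searchsorted(tss, p), 1, len(tss) - 1)
        left, right = tss[j - 1], tss[j]
        nearest = np.where(np.abs(p - left) <= np.abs(p - right), j - 1, j)
        gene_id[sel] = ids[nearest]

    site_id = np.array(
        [f"{c}:{p}:{s}" for c, p, s in zip(chrom, pos, strand)], dtype=object
    )
    gt = pd.DataFrame(
        {
            "site_id": site_id,
            "chrom": chrom,
            "pos": pos,
            "strand": strand,
            "context": context,
            "baseline_level": baseline,
            "aged_std_level": aged_std,
            "aged_enr_level": aged_enr,
            "age_dm": age_dm,
            "direction": direction,
            "counteracted": counteracted,
            "in_enhancer": in_enh,
            "gene_id": gene_id,
        }
    )

    # --- per-sample counts
    levels = {
        "young_std": baseline,
        "young_enr": baseline,
        "aged_std": aged_std,
        "aged_enr": aged_enr,
    }
    nb_n = config.coverage_dispersion
    nb_p = nb_n / (nb_n + config.coverage_mean)
    per_sample: dict[str, list[CytosineRecord]] = {}
    for g in GROUP_NAMES:
        for i in range(config.group_sizes[g]):
            cov = rng.negative_binomial(nb_n, nb_p, size=n_total)
            meth = rng.binomial(cov, levels[g])
            unmeth = cov - meth
            per_sample[f"{g}_{i + 1}"] = [
                CytosineRecord(
                    chrom=chrom[k],
                    pos=int(pos[k]),
                    strand=strand[k],
                    context=context[k],
                    meth_count=int(meth[k]),
                    unmeth_count=int(unmeth[k]),
                )
                for k in range(n_total)
            ]

    # --- motif windows
    pwm = synthetic_mecp2_pwm()
    windows, motif_planted = place_motifs(
        gt,
        pwm,
        config.motif_enrichment_factor,
        background_rate=config.motif_background_rate,
        window_halfwidth=config.motif_window_halfwidth,
        rng=rng,
    )
    gt["motif_planted"] = motif_planted

    # --- gene sets: the planted counteraction targets plus decoys
    target_genes = frozenset(gt.loc[gt["counteracted"], "gene_id"].dropna())
    all_gene_ids = [g.gene_id for g in genes]
    gene_sets = [
        GeneSet(
            name="counteraction_targets_synthetic",
            members=target_genes,
            source="planted",
        )
    ]
    for k in range(3):
        size = min(30, len(all_gene_ids))
        members = frozenset(rng.choice(all_gene_ids, size=size, replace=False))
        gene_sets.append(
            GeneSet(name=f"random_set_{k + 1}", members=members, source="decoy")
        )

    return SimulatedDataset(
        config=config,
        ground_truth=gt,
        per_sample=per_sample,
        islands=islands,
        exons=exons,
        introns=introns,
        enhancers=enhancers,
        super_enhancers=supers,
        genes=genes,
        gene_sets=gene_sets,
        pwm=pwm,
        windows=windows,
        n_clamped=n_clamped,
    )


def place_motifs(
    ground_truth: pd.DataFrame,
    pwm: PWM,
    enrichment_factor: float,
    background_rate: float = 0.03,
    window_halfwidth: int = 25,
    rng: np.random.Generator | None = None,
):
    """Generate sequence windows, planting the motif consensus.

    Every site receives a random window; the consensus is embedded at
    ``background_rate`` in background sites and at ``enrichment_factor``
    times that rate in the target stratum — counteracted CpGs that were
    hypomethylated with aging.  Returns (windows dict, planted flags).
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    n = len(ground_truth)
    width = 2 * window_halfwidth + 1
    target = (
        (ground_truth["context"] == "CpG")
        & ground_truth["counteracted"]
        & (ground_truth["direction"] == "hypo")
    ).to_numpy()
    rate = np.where(target, min(enrichment_factor * background_rate, 1.0),
                    background_rate)
    planted = rng.random(n) < rate
    base_arr = np.array(list("ACGT"))
    seq_idx = rng.integers(0, 4, size=(n, width))
    offsets = rng.integers(0, width - pwm.length + 1, size=n)
    consensus = pwm.consensus
    windows: dict[str, str] = {}
    ids = ground_truth["site_id"].to_numpy()
    for i in range(n):
        chars = base_arr[seq_idx[i]]
        if planted[i]:
            off = offsets[i]
            chars[off : off + pwm.length] = list(consensus)
        windows[str(ids[i])] = "".join(chars)
    return windows, planted


GROUND_TRUTH_COLUMNS = [
    "site_id", "chrom", "pos", "strand", "context", "baseline_level",
    "aged_std_level", "aged_enr_level", "age_dm", "direction",
    "counteracted", "in_enhancer", "gene_id", "motif_planted",
]


def emit_fixture(
    config: SimulationConfig, out_dir: str | Path, overwrite: bool = False
) -> SimulatedDataset:
    """Write the full fixture to disk in the pipeline's input dialects.

    Layout: counts/<sample>.cov.tsv, features/*.bed, genes.tsv,
    mecp2_synthetic.pwm, windows.fa, gene_sets.gmt, ground_truth.tsv
    and config.yaml (the reproducibility record).  Refuses a non-empty
    directory unless ``overwrite`` is set.  Byte-identical under a
    fixed seed.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")
    (out / "counts").mkdir(parents=True, exist_ok=True)
    (out / "features").mkdir(exist_ok=True)

    ds = simulate_dataset(config)
    for sample, records in ds.per_sample.items():
        mio.write_coverage_file(records, out / "counts" / f"{sample}.cov.tsv")
    for name, feats in (
        ("cpg_islands", ds.islands),
        ("exons", ds.exons),
        ("introns", ds.introns),
        ("enhancers", ds.enhancers),
        ("super_enhancers", ds.super_enhancers),
    ):
        mio.write_bed(feats, out / "features" / f"{name}.bed")
    mio.write_gene_table(ds.genes, out / "genes.tsv")
    mio.write_gmt(ds.gene_sets, out / "gene_sets.gmt")
    from .motifs import write_pwm

    write_pwm(ds.pwm, out / "mecp2_synthetic.pwm")
    with open(out / "windows.fa", "w") as fh:
        for sid, seq in ds.windows.items():
            fh.write(f">{sid}\n{seq}\n")
    ds.ground_truth[GROUND_TRUTH_COLUMNS].to_csv(
        out / "ground_truth.tsv", sep="\t", index=False, float_format="%.6f"
    )
    cfg = dataclasses.asdict(config)
    cfg["n_clamped"] = ds.n_clamped
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return ds
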