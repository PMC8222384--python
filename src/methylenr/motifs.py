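"""Position-weight-matrix scanning and motif enrichment.

Sequence windows centred on cytosines are scored against a PWM on both
strands at every offset; a window is a hit when its best score, min-max
rescaled to [0, 1], reaches the match-score threshold (default 0.90,
the convention of standard motif-matching tools).  Enrichment of hits
among differentially methylated cytosines is an upper-tail
hypergeometric test against the covered background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import hypergeom_test

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """A position weight matrix over {A, C, G, T}.

    ``probs`` has shape (4, L), rows in A, C, G, T order, columns
    summing to 1.  Scores are log-odds against a background base
    composition (uniform by default) after adding a pseudocount.
    """

    name: str
    probs: np.ndarray
    pseudocount: float = 1e-3
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        if self.probs.shape[1] < 4:
            raise ValueError("PWM must be at least 4 positions long")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        p = self.probs + self.pseudocount
        p /= p.sum(axis=0, keepdims=True)
        self.log_odds = np.log2(p / self.background[:, None])

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def rescale(self, score: float) -> float:
        """Min-max rescale a raw log-odds score to [0, 1]."""
        return (score - self.min_score) / (self.max_score - self.min_score)


def read_pwm(path: str | Path) -> PWM:
    """Read a PWM as a name header line (">name" or "name") followed by
    four whitespace-separated rows of per-position probabilities in
    A, C, G, T order."""
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if len(lines) < 5:
        raise ValueError(f"{path}: expected a name line plus 4 matrix rows")
    name = lines[0].lstrip(">").strip()
    rows = [np.array([float(x) for x in ln.split()]) for ln in lines[1:5]]
    if len({r.size for r in rows}) != 1:
        raise ValueError(f"{path}: matrix rows differ in length")
    return PWM(name=name, probs=np.vstack(rows))


def write_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for row in pwm.probs:
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_window_fasta(path: str | Path) -> dict[str, str]:
    """Sequence windows keyed by site id (FASTA record id)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def _encode(seq: str) -> np.ndarray:
    """Base indices; unknown characters map to -1."""
    return np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)


def score_window(seq: str, pwm: PWM) -> float:
    """Best raw log-odds score over every offset on both strands.

    Unknown bases (N) contribute the column minimum, so degenerate
    windows can never reach a high match threshold.  Returns -inf when
    the window is shorter than the motif.
    """
    best = -np.inf
    L = pwm.length
    col_min = pwm.log_odds.min(axis=0)
    cols = np.arange(L)
    for s in (seq.upper(), seq.upper().translate(_COMPLEMENT)[::-1]):
        enc = _encode(s)
        if enc.size < L:
            continue
        offsets = np.lib.stride_tricks.sliding_window_view(enc, L)
        known = offsets >= 0
        scores = np.where(
            known, pwm.log_odds[np.clip(offsets, 0, None), cols], col_min
        ).sum(axis=1)
        best = max(best, float(scores.max()))
    return best


@dataclass
class MotifHitTable:
    motif_name: str
    hits: pd.Series  # site id -> bool
    scores: pd.Series  # site id -> best rescaled score
    min_score_frac: float
    too_short: list[str] = field(default_factory=list)

    def hit_ids(self) -> set[str]:
        return set(self.hits.index[self.hits])


def scan_sites(
    windows: dict[str, str],
    pwm: PWM,
    min_score_frac: float = 0.90,
) -> MotifHitTable:
    """Scan sequence windows for PWM matches.

    A window is a hit when its best score over all offsets and both
    strands, rescaled from [min_possible, max_possible] to [0, 1],
    is at least ``min_score_frac``.  Windows shorter than the motif
    are flagged and never hit.
    """
    ids, hit, scores, short = [], [], [], []
    for site_id, seq in windows.items():
        ids.append(site_id)
        if len(seq) < pwm.length:
            short.append(site_id)
            hit.append(False)
            scores.append(float("-inf"))
            continue
        frac = pwm.rescale(score_window(seq, pwm))
        scores.append(frac)
        hit.append(frac >= min_score_frac)
    return MotifHitTable(
        motif_name=pwm.name,
        hits=pd.Series(hit, index=ids),
        scores=pd.Series(scores, index=ids),
        min_score_frac=min_score_frac,
        too_short=short,
    )


def motif_test(
    hit_tables: list[MotifHitTable],
    dm_ids: set[str],
    background_ids: set[str],
) -> pd.DataFrame:
    """Hypergeometric motif enrichment among dm cytosines.

    Per motif: q = dm sites with a hit, m = background sites with a
    hit, n = background sites without, k = |dm|; FDR across motifs.
    """
    if not dm_ids <= background_ids:
        raise ValueError("dm sites must be a subset of the background")
    rows = []
    for tab in hit_tables:
        hit_ids = tab.hit_ids() & background_ids
        q = len(hit_ids & dm_ids)
        m = len(hit_ids)
        n = len(background_ids) - m
        k = len(dm_ids)
        rows.append(
            {
                "motif": tab.motif_name,
                "n_dm_with_hit": q,
                "n_background_with_hit": m,
                "n_dm": k,
                "pvalue": hypergeom_test(q, m, n, k),
            }
        )
    out = pd.DataFrame(rows)
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def target_direction_breakdown(
    hit_table: MotifHitTable,
    counteraction_table: pd.DataFrame,
    site_id_column: str = "site_id",
) -> dict:
    """Among motif-hit counteracted cytosines, counts per
    (aging direction x enrichment direction) stratum, plus a one-sided
    hypergeometric test of whether the hypomethylated-with-aging
    stratum is over-represented among the hits relative to all
    counteracted cytosines."""
    tab = counteraction_table[counteraction_table["class"] == "counteracted"]
    hit_ids = hit_table.hit_ids()
    in_hit = tab[site_id_column].isin(hit_ids)
    strata = (
        tab[in_hit]
        .groupby(["age_direction", "enr_direction"], observed=True)
        .size()
        .to_dict()
    )
    n_hits = int(in_hit.sum())
    result = {
        "strata": {f"{a}_aging/{e}_enr": int(v) for (a, e), v in strata.items()},
        "n_counteracted_with_hit": n_hits,
        "n_counteracted": int(len(tab)),
    }
    if n_hits == 0:
        result["hypo_aging_p"] = None
        return result
    hypo_all = int((tab["age_direction"] == "hypo").sum())
    hypo_hit = int((tab[in_hit]["age_direction"] == "hypo").sum())
    result["hypo_aging_fraction_in_hits"] = hypo_hit / n_hits
    result["hypo_aging_p"] = hypergeom_test(
        hypo_hit, hypo_all, len(tab) - hypo_all, n_hits
    )
    return result
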