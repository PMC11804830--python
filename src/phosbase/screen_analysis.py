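"""Minimal pooled-screen count analysis.

This is a deliberately small, self-contained stand-in for full screen
analysis suites such as MAGeCK/MAGeCKFlute: control-based size factors,
per-guide log2 fold changes, site-level aggregation against a
control-permutation null with Benjamini-Hochberg correction, an
essential-gene depletion QC, and per-position editing quantification from
amplicon reads.  Users comparing against published hit counts from MAGeCK
should expect differences; the normalization principle (size factors from
intergenic and non-targeting controls only) is shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTROL_CLASSES_FOR_NORM = ("intergenic", "non_targeting")


def control_size_factors(
    counts: pd.DataFrame, classes: pd.Series, control_classes=CONTROL_CLASSES_FOR_NORM
) -> pd.Series:
    """Median-of-ratios size factors estimated from control guides only.

    ``counts`` is guides x samples (non-negative integers); ``classes`` maps
    guide_id -> class label.  The geometric-mean reference and the median of
    ratios are computed over control guides with nonzero reference.
    """
    classes = classes.reindex(counts.index)
    mask = classes.isin(control_classes)
    if not mask.any():
        raise ValueError(
            "no control guides found; supply class labels including "
            f"{control_classes} to estimate size factors"
        )
    ctrl = counts.loc[mask].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_ref = np.log(ctrl).mean(axis=1)
    finite = np.isfinite(log_ref)
    if not finite.any():
        raise ValueError("all control guides contain a zero count")
    ratios = ctrl[finite] / np.exp(log_ref[finite])[:, None]
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor; check control counts")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def guide_log2fc(
    counts: pd.DataFrame,
    classes: pd.Series,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 1.0,
    size_factors: pd.Series | None = None,
) -> pd.Series:
    """Per-guide log2((a/sf_a + pc) / (b/sf_b + pc)); finite for zero counts."""
    for s in (sample_a, sample_b):
        if s not in counts.columns:
            raise KeyError(f"sample {s!r} not in count matrix")
    if size_factors is None:
        size_factors = control_size_factors(counts, classes)
    a = counts[sample_a] / size_factors[sample_a] + pseudocount
    b = counts[sample_b] / size_factors[sample_b] + pseudocount
    return pd.Series(np.log2(a / b), index=counts.index, name="log2fc")


@dataclass
class SiteStat:
    """Site-level enrichment statistic from guide aggregation."""

    site_id: str
    n_guides: int
    log2fc: float  # median of member guides
    p_value: float
    fdr: float
    direction: str  # "up" | "down"


def aggregate_to_sites(
    guide_stats: pd.Series,
    site_of_guide: pd.Series,
    control_guides: pd.Series | list,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median-aggregate guide log2FCs per site with a permutation null.

    For every site the score is the median log2FC of its guides; the null
    draws size-matched guide sets from the control guides ``n_perm`` times
    and the two-sided p-value is ``(1 + #{|null| >= |obs|}) / (n_perm + 1)``,
    BH-adjusted across sites.  Sites with zero guides are skipped.
    """
    rng = np.random.default_rng(seed)
    ctrl = guide_stats.loc[list(control_guides)].to_numpy(dtype=float)
    if ctrl.size == 0:
        raise ValueError("no control guides for the permutation null")

    site_of_guide = site_of_guide.reindex(guide_stats.index)
    groups = guide_stats.groupby(site_of_guide)
    obs = {site: vals.to_numpy(float) for site, vals in groups if len(vals) > 0}

    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({len(v) for v in obs.values()}):
        draws = rng.choice(ctrl, size=(n_perm, size), replace=True)
        null_by_size[size] = np.abs(np.median(draws, axis=1))

    records = []
    for site, vals in sorted(obs.items()):
        score = float(np.median(vals))
        null = null_by_size[len(vals)]
        p = (1.0 + np.count_nonzero(null >= abs(score))) / (n_perm + 1.0)
        records.append(
            {
                "site_id": site,
                "n_guides": len(vals),
                "log2fc": score,
                "p_value": p,
                "direction": "up" if score >= 0 else "down",
            }
        )
    df = pd.DataFrame(records)
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.loc[
        :, ["site_id", "n_guides", "log2fc", "p_value", "fdr", "direction"]
    ]


def essential_depletion_qc(
    guide_stats: pd.Series,
    classes: pd.Series,
    alpha: float = 0.05,
) -> dict:
    """Rank-sum QC: are essential-splice guides depleted vs controls?

    Compares the log2FC distribution of the ``essential_splice`` class
    against intergenic + non-targeting controls (Mann-Whitney U, one-sided
    'less').  PASS requires significant depletion at ``alpha``.  Returns a
    report dict with the p-value, the median-difference effect size, and a
    status of PASS / FAIL / ``not evaluable``.
    """
    classes = classes.reindex(guide_stats.index)
    ess = guide_stats[classes == "essential_splice"]
    ctrl = guide_stats[classes.isin(CONTROL_CLASSES_FOR_NORM)]
    if ess.empty or ctrl.empty:
        return {
            "status": "not evaluable",
            "reason": "essential_splice or control class missing",
        }
    res = stats.mannwhitneyu(ess, ctrl, alternative="less")
    effect = float(ess.median() - ctrl.median())
    depleted = res.pvalue < alpha and effect < 0
    return {
        "status": "PASS" if depleted else "FAIL",
        "p_value": float(res.pvalue),
        "median_log2fc_essential": float(ess.median()),
        "median_log2fc_controls": float(ctrl.median()),
        "effect_size": effect,
        "n_essential": int(len(ess)),
        "n_controls": int(len(ctrl)),
    }


def quantify_editing(
    reads: list[str],
    window_positions: list[int],
    ref_seq: str,
    source_base: str = "A",
    product_base: str = "G",
) -> dict[int, float]:
    """Per-position edited fraction from aligned amplicon reads.

    ``reads`` are equal-length strings aligned to ``ref_seq`` (gap/N-free
    positions only are counted); for every window position carrying the
    source base in the reference, returns the fraction of covering reads
    with the product base.
    """
    if not reads:
        raise ValueError("need at least one read covering the window")
    out: dict[int, float] = {}
    for pos in window_positions:
        if ref_seq[pos] != source_base:
            continue
        covered = edited = 0
        for read in reads:
            base = read[pos]
            if base in "ACGT":
                covered += 1
                if base == product_base:
                    edited += 1
        out[pos] = edited / covered if covered else float("nan")
    return out
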