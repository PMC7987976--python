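"""Percentile-ranking hit caller.

For each guide and timepoint group the mean and standard deviation are taken
over all samples in the group (zeros included), while the group count k is
the number of samples where the guide is present (> 0); SEM = sd / sqrt(k).
Each lung sample's z-score is the normalized count minus the control-group
mean, divided by its group's SEM. Per sample, guides at or above the
nearest-rank 98th percentile of defined z-scores form that sample's set, and
hits are guides recurring in at least ``min_samples`` sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from guidescreen.counts import CountMatrix


class PercentileError(ValueError):
    pass


@dataclass
class GroupStats:
    """Per-guide per-group summary statistics.

    Each attribute is a DataFrame indexed by guide_id with one column per
    group label: ``mean``/``sd`` over all samples in the group, ``k`` the
    number of samples with value > 0, ``sem`` = sd / sqrt(k) (NaN when k=0).
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    k: pd.DataFrame
    sem: pd.DataFrame
    group_sizes: dict[str, int]


@dataclass
class ZMatrix:
    """Per-guide, per-lung-sample z-scores with a defined-entry mask."""

    z: pd.DataFrame  # NaN where undefined
    sample_groups: dict[str, str]

    @property
    def defined(self) -> pd.DataFrame:
        return self.z.notna()


def compute_group_stats(
    cm: CountMatrix,
    groups: dict[str, list[str]],
    moments_over_present_only: bool = False,
    ddof: int = 1,
) -> GroupStats:
    """Compute mean, sd, group count and SEM per guide per group.

    ``groups`` maps group label -> sample ids. By default moments use all
    samples in the group (zeros included); ``moments_over_present_only``
    restricts them to samples with value > 0.
    """
    means, sds, ks, sems = {}, {}, {}, {}
    sizes = {}
    for label, sample_ids in groups.items():
        missing = [s for s in sample_ids if s not in cm.values.columns]
        if missing:
            raise PercentileError(f"group {label!r}: samples absent from matrix: {missing}")
        if len(sample_ids) < 2:
            raise PercentileError(f"group {label!r} has < 2 samples")
        sub = cm.values[sample_ids]
        k = (sub > 0).sum(axis=1)
        if moments_over_present_only:
            masked = sub.where(sub > 0)
            mu = masked.mean(axis=1)
            sd = masked.std(axis=1, ddof=ddof)
        else:
            mu = sub.mean(axis=1)
            sd = sub.std(axis=1, ddof=ddof)
        with np.errstate(divide="ignore", invalid="ignore"):
            sem = sd / np.sqrt(k.replace(0, np.nan))
        means[label], sds[label], ks[label], sems[label] = mu, sd, k, sem
        sizes[label] = len(sample_ids)
    return GroupStats(
        pd.DataFrame(means), pd.DataFrame(sds), pd.DataFrame(ks), pd.DataFrame(sems), sizes
    )


def compute_zscores(
    cm: CountMatrix, stats: GroupStats, control: str, lung_groups: list[str] | None = None
) -> ZMatrix:
    """z_{g,s} = (n_{g,s} - mean_ctrl_g) / sem_{group(s),g}.

    Entries with SEM of 0 or NaN (degenerate or absent guides) are masked,
    never infinite.
    """
    if control not in stats.mean.columns:
        raise PercentileError(f"control group {control!r} missing from stats")
    if lung_groups is None:
        lung_groups = [g for g in stats.mean.columns if g != control]
    ctrl_mean = stats.mean[control]
    cols = {}
    groups = {}
    for label in lung_groups:
        sem = stats.sem[label].replace(0.0, np.nan)
        for s in cm.samples_in_group(label):
            cols[s] = (cm.values[s] - ctrl_mean) / sem
            groups[s] = label
    return ZMatrix(pd.DataFrame(cols), groups)


def nearest_rank_threshold(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the smallest value with >= pct% of the
    (finite) values at or below it."""
    if not 0 < pct < 100:
        raise PercentileError("pct must be in (0, 100)")
    v = np.sort(values[np.isfinite(values)])
    if len(v) == 0:
        raise PercentileError("no defined values")
    rank = math.ceil(pct / 100.0 * len(v))  # 1-based
    return float(v[rank - 1])


def percentile_sets(zm: ZMatrix, pct: float = 98.0) -> dict[str, set[str]]:
    """Per sample, the set of guides with z >= the nearest-rank ``pct``-th
    percentile of that sample's defined z-scores. Ties share membership."""
    sets: dict[str, set[str]] = {}
    for s in zm.z.columns:
        col = zm.z[s]
        defined = col.dropna()
        if defined.empty:
            sets[s] = set()
            continue
        thr = nearest_rank_threshold(defined.to_numpy(), pct)
        sets[s] = set(defined.index[defined >= thr])
    return sets


def recurrence(
    sets: dict[str, set[str]],
    zm: ZMatrix | None = None,
    genes: pd.Series | None = None,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Cross-sample recurrence of percentile-set membership.

    Returns the guide-level hit table: one row per guide appearing in at
    least ``min_samples`` sample sets, sorted by (n_samples desc, max_z desc,
    guide_id), with member sample ids semicolon-joined.
    """
    membership: dict[str, list[str]] = {}
    for sid in sorted(sets):
        for gid in sets[sid]:
            membership.setdefault(gid, []).append(sid)
    rows = []
    for gid, samples in membership.items():
        max_z = float(zm.z.loc[gid, samples].max()) if zm is not None else np.nan
        rows.append(
            dict(
                guide_id=gid,
                gene="" if genes is None else genes.get(gid, ""),
                n_samples=len(samples),
                max_z=max_z,
                member_samples=";".join(sorted(samples)),
            )
        )
    table = pd.DataFrame(
        rows, columns=["guide_id", "gene", "n_samples", "max_z", "member_samples"]
    )
    table = table[table["n_samples"] >= min_samples]
    table = table.sort_values(
        ["n_samples", "max_z", "guide_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return table


def gene_recurrence(hit_table: pd.DataFrame, all_membership: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate the guide hit table per gene: best guide recurrence and the
    number of distinct guides ever appearing in any sample's percentile set."""
    if hit_table.empty:
        return pd.DataFrame(columns=["gene", "best_guide_recurrence", "n_guides_in_sets", "best_guide"])
    rows = []
    for gene, sub in hit_table.groupby("gene"):
        best = sub.iloc[0]
        rows.append(
            dict(
                gene=gene,
                best_guide_recurrence=int(sub["n_samples"].max()),
                n_guides_in_sets=int(sub["guide_id"].nunique()),
                best_guide=best["guide_id"],
            )
        )
    out = pd.DataFrame(rows).sort_values(
        ["best_guide_recurrence", "n_guides_in_sets", "gene"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    return out


def call_percentile_hits(
    cm: CountMatrix,
    control: str = "cells_500x",
    hit_group: str = "lung_19d",
    pct: float = 98.0,
    min_samples: int = 2,
    moments_over_present_only: bool = False,
) -> dict:
    """End-to-end percentile method on a normalized matrix.

    z-scores are computed for every non-control group (the early timepoint is
    diagnostic), but hit calling uses ``hit_group`` only. Returns a dict with
    stats, zmatrix, per-sample sets, guide hit table and gene table.
    """
    group_map: dict[str, list[str]] = {}
    for s, g in cm.sample_groups.items():
        if s in cm.values.columns:
            group_map.setdefault(g, []).append(s)
    if control not in group_map:
        raise PercentileError(f"control group {control!r} not present")
    stats = compute_group_stats(cm, group_map, moments_over_present_only)
    zm = compute_zscores(cm, stats, control)
    hit_samples = [s for s, g in zm.sample_groups.items() if g == hit_group]
    sets = percentile_sets(ZMatrix(zm.z[hit_samples], {s: hit_group for s in hit_samples}), pct)
    hits = recurrence(sets, zm, cm.genes, min_samples)
    return dict(
        stats=stats,
        zmatrix=zm,
        sets=sets,
        hit_table=hits,
        gene_table=gene_recurrence(hits),
    )
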