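"""Site-level aggregation and analyses.

The central statistic is the site stoichiometry

    S = (1/N) * sum_n Theta(P_n - 0.5),    Theta(x) = 1 iff x >= 0,

i.e. the fraction of reads covering a site whose read-level modification
probability reaches the 0.5 threshold (a read at exactly P = 0.5 counts as
modified). Sites below a minimum coverage are suppressed. On top of this
sit the standard analyses: mapq filtering, condition comparison by 2-D
binning, titration slope recovery, chromosome-scale binned profiles, peak
proximity matching, and per-group (isoform) stoichiometry.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "site_stoichiometry",
    "group_stoichiometry",
    "filter_reads",
    "ConditionComparison",
    "compare_conditions",
    "TitrationResult",
    "titration_slope",
    "BinnedProfile",
    "chromosome_profile",
    "ProximityResult",
    "proximity_match",
]

SITE_KEY = ["contig", "position", "strand"]


def _aggregate(calls: pd.DataFrame, keys, threshold: float, min_coverage: int) -> pd.DataFrame:
    g = calls.groupby(keys, sort=True)
    out = g.agg(
        motif=("motif", "first"),
        coverage=("prob", "size"),
        n_modified=("prob", lambda p: int((p >= threshold).sum())),
    ).reset_index()
    out["stoichiometry"] = out["n_modified"] / out["coverage"]
    out = out[out["coverage"] >= min_coverage].reset_index(drop=True)
    return out.drop(columns=["n_modified"])


def site_stoichiometry(
    calls: pd.DataFrame, threshold: float = 0.5, min_coverage: int = 50
) -> pd.DataFrame:
    """Aggregate read-level calls into per-site stoichiometry records.

    ``calls`` needs columns contig, position, strand, motif, prob (one row
    per read-site observation). Returns one row per (contig, position,
    strand) with coverage N and stoichiometry S; sites with N below
    ``min_coverage`` are suppressed.
    """
    if "motif" not in calls.columns:
        calls = calls.assign(motif="NNANN")
    return _aggregate(calls, SITE_KEY, threshold, min_coverage)


def group_stoichiometry(
    calls: pd.DataFrame, threshold: float = 0.5, min_coverage: int = 50
) -> pd.DataFrame:
    """Per-group (e.g. per-transcript) stoichiometry at each site.

    Same aggregation and filters as :func:`site_stoichiometry`, applied
    within each ``group_id``. A group below the coverage floor is
    suppressed even where the pooled site would pass.
    """
    if "group_id" not in calls.columns:
        raise ValueError("calls must carry a group_id column")
    if "motif" not in calls.columns:
        calls = calls.assign(motif="NNANN")
    return _aggregate(calls, ["group_id", *SITE_KEY], threshold, min_coverage)


def filter_reads(alignments: pd.DataFrame, min_mapq: int = 50) -> pd.DataFrame:
    """Drop alignment records with mapq below ``min_mapq``.

    The boundary is retained: mapq == min_mapq passes. Records with missing
    mapq are removed and counted in a warning.
    """
    if "mapq" not in alignments.columns:
        raise ValueError("alignment records must carry a mapq column")
    mapq = pd.to_numeric(alignments["mapq"], errors="coerce")
    missing = int(mapq.isna().sum())
    if missing:
        warnings.warn(f"{missing} records without mapq removed")
    return alignments[mapq >= min_mapq].reset_index(drop=True)


@dataclass
class ConditionComparison:
    """Joint 2-D histogram of site stoichiometries under two conditions."""

    hist: np.ndarray  # shape (n_bins, n_bins), counts; rows = condition A
    edges: np.ndarray
    shared: pd.DataFrame  # matched sites with columns s_a, s_b
    n_only_a: int
    n_only_b: int


def compare_conditions(
    sites_a: pd.DataFrame, sites_b: pd.DataFrame, bin_width: float = 0.05
) -> ConditionComparison:
    """Compare per-site stoichiometry between two conditions.

    Sites are matched on (contig, position, strand); the joint histogram of
    (S_A, S_B) uses bins of ``bin_width`` on [0, 1] (S = 1 falls in the last
    bin). Bin counts sum to the number of shared sites.
    """
    merged = sites_a.merge(
        sites_b, on=SITE_KEY, suffixes=("_a", "_b"), how="inner"
    ).rename(columns={"stoichiometry_a": "s_a", "stoichiometry_b": "s_b"})
    if merged.empty:
        raise ValueError("no shared sites between the two conditions")
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _, _ = np.histogram2d(merged["s_a"], merged["s_b"], bins=[edges, edges])
    return ConditionComparison(
        hist=hist.astype(int),
        edges=edges,
        shared=merged,
        n_only_a=len(sites_a) - len(merged),
        n_only_b=len(sites_b) - len(merged),
    )


@dataclass
class TitrationResult:
    """OLS fit of measured stoichiometry on reference stoichiometry."""

    slope: float
    stderr: float
    intercept: float
    n_sites: int
    f_wt: float | None = None


def titration_slope(s_measured, s_reference, f_wt: float | None = None) -> TitrationResult:
    """Ordinary-least-squares slope of measured S on reference S.

    An intercept is fitted (classifier false positives induce one); the
    slope is the reported statistic. For a WT/IVT mixture the expected
    slope is the WT fraction.
    """
    y = np.asarray(s_measured, dtype=float)
    x = np.asarray(s_reference, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two matched sites")
    if np.ptp(x) == 0:
        raise ValueError("reference stoichiometries have zero variance")
    fit = stats.linregress(x, y)
    return TitrationResult(
        slope=float(fit.slope),
        stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        n_sites=int(x.size),
        f_wt=f_wt,
    )


@dataclass
class BinnedProfile:
    """Per-bin median stoichiometry along a contig; NaN marks empty bins."""

    contig: str
    n_bins: int
    medians: np.ndarray
    edges: np.ndarray


def chromosome_profile(
    sites: pd.DataFrame, contig_length: int, n_bins: int = 10000
) -> BinnedProfile:
    """Bin a contig into ``n_bins`` intervals and take the median S per bin."""
    if (sites["position"] < 0).any() or (sites["position"] >= contig_length).any():
        raise ValueError("site positions must lie within the contig")
    contig = str(sites["contig"].iloc[0]) if len(sites) else ""
    bins = np.minimum(
        (sites["position"].to_numpy() * n_bins // contig_length).astype(int), n_bins - 1
    )
    medians = np.full(n_bins, np.nan)
    med = pd.Series(sites["stoichiometry"].to_numpy()).groupby(bins).median()
    medians[med.index.to_numpy()] = med.to_numpy()
    return BinnedProfile(
        contig=contig,
        n_bins=n_bins,
        medians=medians,
        edges=np.linspace(0, contig_length, n_bins + 1),
    )


@dataclass
class ProximityResult:
    """Fraction of high-S predicted sites with an orthogonal peak nearby."""

    fraction: float
    n_selected: int
    n_matched: int
    matched: pd.Series


def proximity_match(
    sites: pd.DataFrame,
    peaks: pd.DataFrame,
    max_dist: int = 5,
    s_min: float = 0.5,
) -> ProximityResult:
    """Match predicted sites against a peak list by genomic proximity.

    Considers predicted sites with S >= ``s_min``; a site matches when a
    peak on the same contig and strand lies within ``max_dist`` nt
    (inclusive). Returns the matched fraction (0 when nothing is selected
    or the peak list is empty).
    """
    sel = sites[sites["stoichiometry"] >= s_min].reset_index(drop=True)
    matched = pd.Series(False, index=sel.index)
    if len(sel) and len(peaks):
        for (contig, strand), grp in sel.groupby(["contig", "strand"]):
            p = peaks[(peaks["contig"] == contig) & (peaks["strand"] == strand)]
            if p.empty:
                continue
            ppos = np.sort(p["position"].to_numpy())
            spos = grp["position"].to_numpy()
            j = np.searchsorted(ppos, spos)
            left = np.abs(spos - ppos[np.clip(j - 1, 0, ppos.size - 1)])
            right = np.abs(ppos[np.clip(j, 0, ppos.size - 1)] - spos)
            matched.loc[grp.index] = np.minimum(left, right) <= max_dist
    n_sel, n_match = len(sel), int(matched.sum())
    return ProximityResult(
        fraction=(n_match / n_sel) if n_sel else 0.0,
        n_selected=n_sel,
        n_matched=n_match,
        matched=matched,
    )
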