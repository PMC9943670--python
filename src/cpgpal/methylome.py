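"""CpG methylation at motif sites, trajectory classes, accessibility, conservation.

Methylation is read from a strand-merged per-CpG report (chrom, 0-based
position of the plus-strand C, methylated count, unmethylated count), the
output format of standard bisulfite pipelines after CpG merging. For each
motif site two quantities are measured: the fraction at the motif's core CpG
(the central CpG of a palindromic element) and the mean fraction over all
CpGs in a window (default 100 bp) centered on the motif. A site counts as
methylated only at 100% core-CpG methylation — a deliberately strict rule;
partially methylated sites are not methylated under it. Sites with no
covered CpG are *undefined*, never silently 0.

Across ordered timepoints (reprogramming days), sites methylated at the
start are classified by their end state: ``remains_methylated`` or
``demethylated``. Accessibility uses mean per-base coverage in the same
window against a user threshold: sites closed at the start either ``opens``
or ``remains_closed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "CpgReport",
    "MethylationProfile",
    "TrajectoryClassification",
    "methylation_at_sites",
    "classify_methylated",
    "classify_trajectory",
    "classify_accessibility",
    "conservation_profile",
]

UNDEFINED = "undefined"


@dataclass(frozen=True)
class CpgReport:
    """Strand-merged per-CpG counts: one row per plus-strand C position."""

    table: pd.DataFrame  # columns: chrom, position, count_methylated, count_unmethylated

    def __post_init__(self) -> None:
        need = {"chrom", "position", "count_methylated", "count_unmethylated"}
        if not need <= set(self.table.columns):
            raise ValueError(f"CpG report needs columns {sorted(need)}")
        if (self.table[["count_methylated", "count_unmethylated"]] < 0).any().any():
            raise ValueError("counts must be >= 0")
        if self.table.duplicated(["chrom", "position"]).any():
            raise ValueError("duplicate CpG positions in report")


@dataclass(frozen=True)
class MethylationProfile:
    """Per-site core-CpG and window-mean methylation fractions.

    NaN marks sites without any covered CpG (undefined, distinct from 0).
    """

    table: pd.DataFrame  # index: site_id; columns: core_fraction, window_fraction,
    #                      core_coverage, window_coverage, n_window_cpgs
    window_bp: int


@dataclass(frozen=True)
class TrajectoryClassification:
    """Per-site start-state and end-state labels plus class counts."""

    table: pd.DataFrame  # index: site_id; columns: methylated_at_start, end_state
    counts: dict[str, int]


def methylation_at_sites(
    sites: Sequence[GenomicInterval],
    report: CpgReport,
    window_bp: int = 100,
    min_coverage: int = 1,
    site_ids: Sequence[str] | None = None,
) -> MethylationProfile:
    """Core-CpG and window-mean methylation for each motif site.

    The core value comes from the CpG whose C lies inside the central CpG
    dinucleotide of the motif (positions center-1 and center of the
    interval); the window mean averages the fractions of all CpGs whose
    position falls within ``window_bp / 2`` of the motif center. CpGs with
    coverage below ``min_coverage`` do not contribute; a site where nothing
    contributes is NaN (undefined).
    """
    if not sites:
        raise ValueError("sites must be non-empty")
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if site_ids is None:
        site_ids = [f"site_{i}" for i in range(len(sites))]

    rep = report.table
    cov = rep["count_methylated"] + rep["count_unmethylated"]
    usable = rep[cov >= min_coverage].copy()
    usable["coverage"] = cov[cov >= min_coverage]
    usable["fraction"] = usable["count_methylated"] / usable["coverage"]

    by_chrom = {
        chrom: grp.sort_values("position").reset_index(drop=True)
        for chrom, grp in usable.groupby("chrom")
    }

    half = window_bp / 2.0
    rows = []
    for sid, site in zip(site_ids, sites):
        grp = by_chrom.get(site.chrom)
        core_frac = core_cov = math.nan
        win_frac = math.nan
        win_cov = 0
        n_win = 0
        if grp is not None:
            pos = grp["position"].to_numpy()
            # core CpG: the C of the central dinucleotide on the plus strand
            core_left = site.start + len(site) // 2 - 1
            core_mask = (pos == core_left) | (pos == core_left + 1)
            if core_mask.any():
                row = grp[core_mask].iloc[0]
                core_frac = float(row["fraction"])
                core_cov = float(row["coverage"])
            lo = np.searchsorted(pos, site.center - half, side="left")
            hi = np.searchsorted(pos, site.center + half, side="right")
            if hi > lo:
                sel = grp.iloc[lo:hi]
                win_frac = float(sel["fraction"].mean())
                win_cov = int(sel["coverage"].sum())
                n_win = int(hi - lo)
        rows.append(
            {
                "site_id": sid,
                "core_fraction": core_frac,
                "window_fraction": win_frac,
                "core_coverage": core_cov,
                "window_coverage": win_cov,
                "n_window_cpgs": n_win,
            }
        )
    table = pd.DataFrame(rows).set_index("site_id")
    return MethylationProfile(table=table, window_bp=window_bp)


def classify_methylated(
    profile: MethylationProfile,
    rule: str = "full",
    threshold: float = 0.8,
    use_window: bool = False,
) -> pd.Series:
    """Binary methylation call per site; pandas nullable boolean.

    ``rule="full"`` (default): methylated iff the core-CpG fraction equals
    1.0 (within representation epsilon) — the strict 100% rule. A site with
    fraction 0.99 is *not* methylated. ``rule="threshold"``: fraction >=
    ``threshold``; intended for motifs without a core CpG, where
    ``use_window=True`` switches to the window mean. Undefined sites
    propagate as <NA>, never False.
    """
    col = "window_fraction" if use_window else "core_fraction"
    frac = profile.table[col]
    if rule == "full":
        calls = (frac - 1.0).abs() <= 1e-12
    elif rule == "threshold":
        calls = frac >= threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    calls = calls.astype("boolean")
    calls[frac.isna()] = pd.NA
    calls.name = "methylated"
    return calls


def classify_trajectory(
    profiles_by_timepoint: Mapping[str, MethylationProfile],
    rule: str = "full",
    threshold: float = 0.8,
    use_window: bool = False,
) -> TrajectoryClassification:
    """End-state classes for sites methylated at the first timepoint.

    Timepoints follow mapping order (insertion-ordered labels, e.g.
    day0..day8). A site is in the cohort if methylated at the first
    timepoint; its end state is ``remains_methylated`` if still methylated
    at the last timepoint, ``demethylated`` otherwise, and ``undefined`` if
    the last timepoint has no coverage for it.
    """
    labels = list(profiles_by_timepoint)
    if len(labels) < 2:
        raise ValueError("need at least 2 timepoints")
    first = classify_methylated(
        profiles_by_timepoint[labels[0]], rule=rule, threshold=threshold, use_window=use_window
    )
    last = classify_methylated(
        profiles_by_timepoint[labels[-1]], rule=rule, threshold=threshold, use_window=use_window
    )
    if not first.index.equals(last.index):
        raise ValueError("inconsistent site ids across timepoints")

    end_state = pd.Series("not_in_cohort", index=first.index, dtype=object)
    in_cohort = first.fillna(False).astype(bool)
    for sid in first.index[in_cohort]:
        if pd.isna(last.loc[sid]):
            end_state.loc[sid] = UNDEFINED
            logger.debug("site %s lost coverage at %s", sid, labels[-1])
        elif bool(last.loc[sid]):
            end_state.loc[sid] = "remains_methylated"
        else:
            end_state.loc[sid] = "demethylated"

    table = pd.DataFrame(
        {"methylated_at_start": first, "end_state": end_state}
    )
    counts = end_state[in_cohort].value_counts().to_dict()
    return TrajectoryClassification(table=table, counts=counts)


def _window_mean_coverage(
    track: Mapping[str, np.ndarray], site: GenomicInterval, window_bp: int
) -> float:
    arr = track.get(site.chrom)
    if arr is None:
        return math.nan
    half = window_bp // 2
    c = int(site.center)
    lo, hi = max(0, c - half), min(len(arr), c + half)
    if hi <= lo:
        return math.nan
    return float(np.mean(arr[lo:hi]))


def classify_accessibility(
    tracks_by_timepoint: Mapping[str, Mapping[str, np.ndarray]],
    sites: Sequence[GenomicInterval],
    open_threshold: float,
    window_bp: int = 100,
    site_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Open/closed state per site per timepoint plus a transition class.

    A site is open at a timepoint iff mean per-base coverage in the window
    is at least ``open_threshold``. Transition classes over ordered
    timepoints: ``opens`` (closed at start, open at end), ``remains_closed``,
    ``open_at_start``; sites on chromosomes absent from a track are
    ``undefined``.
    """
    if open_threshold <= 0:
        raise ValueError("open_threshold must be > 0")
    labels = list(tracks_by_timepoint)
    if len(labels) < 2:
        raise ValueError("need at least 2 timepoints")
    if site_ids is None:
        site_ids = [f"site_{i}" for i in range(len(sites))]

    states = pd.DataFrame(index=pd.Index(site_ids, name="site_id"), dtype=object)
    for label in labels:
        track = tracks_by_timepoint[label]
        means = [_window_mean_coverage(track, s, window_bp) for s in sites]
        states[label] = [
            UNDEFINED if math.isnan(m) else ("open" if m >= open_threshold else "closed")
            for m in means
        ]

    def transition(row: pd.Series) -> str:
        first, last = row[labels[0]], row[labels[-1]]
        if UNDEFINED in (first, last):
            return UNDEFINED
        if first == "open":
            return "open_at_start"
        return "opens" if last == "open" else "remains_closed"

    states["transition"] = states.apply(transition, axis=1)
    return states


def conservation_profile(
    track: Mapping[str, np.ndarray],
    sites: Sequence[GenomicInterval],
    flank_bp: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Position-wise mean conservation over motif-centered windows.

    Returns ``(profile, counts)`` of length ``motif + 2*flank_bp``:
    ``profile[j]`` is the mean track value at motif-relative position j over
    all sites contributing a value there, ``counts[j]`` how many did. Minus-
    strand sites are flipped so every window reads in motif orientation.
    Raises if no site overlaps the track at all.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if not sites:
        raise ValueError("sites must be non-empty")
    motif_len = len(sites[0])
    if any(len(s) != motif_len for s in sites):
        raise ValueError("all sites must have the same motif length")

    width = motif_len + 2 * flank_bp
    total = np.zeros(width)
    counts = np.zeros(width, dtype=int)
    for site in sites:
        arr = track.get(site.chrom)
        if arr is None:
            continue
        start = site.start - flank_bp
        for j in range(width):
            g = start + j
            if 0 <= g < len(arr) and np.isfinite(arr[g]):
                jj = width - 1 - j if site.strand == "-" else j
                total[jj] += arr[g]
                counts[jj] += 1
    if counts.sum() == 0:
        raise ValueError("no site overlaps the conservation track")
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return profile, counts
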