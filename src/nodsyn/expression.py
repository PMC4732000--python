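"""Fold-change expression classification and cross-species group overlaps.

Two boolean calls are made per gene, both with a strict fold-change
threshold (default > 2):

* **root-hair induced** — inoculated vs mock abundance exceeds the
  threshold at ANY paired time point (single-time-point induction counts);
* **nodule-preferential** — nodule abundance exceeds the threshold against
  the MAXIMUM over the other atlas tissues (the strictest reading of
  "preferential versus other tissues"; the mean is available as an option).

Fold-change is ``(treated + pc) / (control + pc)`` with a pseudocount
(default 1.0 abundance unit) guarding zero denominators; ``pc=0`` gives the
raw ratio for noiseless data.  Calls are lifted to ortholog groups by an
any-member rule per species, and cross-species sharing is summarized as a
full Venn partition with integer percentages (rounded half away from zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synteny import OrthologGroup

CATEGORY_RESTRICTED = "nodulation-restricted"
CATEGORY_BROAD = "broad"
CATEGORY_SILENT = "silent"


@dataclass
class ExpressionProfile:
    """Per-gene abundances: tissue atlas + paired inoculated/mock time course."""

    gene_id: str
    atlas: dict[str, float]
    roothair: dict[tuple[str, str], float]  # (timepoint, "IN"|"UN") -> abundance

    def __post_init__(self) -> None:
        for v in list(self.atlas.values()) + list(self.roothair.values()):
            if v < 0:
                raise ValueError(f"{self.gene_id}: abundances must be non-negative")

    def paired_timepoints(self) -> list[str]:
        tps = sorted({tp for tp, _ in self.roothair})
        return [tp for tp in tps
                if (tp, "IN") in self.roothair and (tp, "UN") in self.roothair]

    @classmethod
    def from_row(cls, gene_id: str, row: Mapping[str, float]) -> "ExpressionProfile":
        atlas: dict[str, float] = {}
        roothair: dict[tuple[str, str], float] = {}
        for col, val in row.items():
            if col.endswith("_IN") or col.endswith("_UN"):
                tp, _, treat = col.rpartition("_")
                roothair[(tp, treat)] = float(val)
            else:
                atlas[col] = float(val)
        return cls(gene_id, atlas, roothair)


@dataclass
class ExpressionCall:
    gene_id: str
    rh_induced: bool
    nodule_preferential: bool
    category: str


@dataclass
class GroupCallSummary:
    group_id: str
    rh_induced_any: dict[str, bool]        # species -> any member induced
    nodule_pref_any: dict[str, bool]
    member_categories: dict[str, str]      # gene id -> category


def fold_change(treated: float, control: float, pseudocount: float = 1.0) -> float:
    """``(treated + pc) / (control + pc)``; finite and positive."""
    if treated < 0 or control < 0:
        raise ValueError("abundances must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if treated == control:
        return 1.0  # identity holds for any pseudocount, including 0/0 at pc=0
    denom = control + pseudocount
    if denom == 0:
        raise ValueError("zero denominator: control + pseudocount must be positive")
    return (treated + pseudocount) / denom


def call_rh_induced(
    profile: ExpressionProfile,
    threshold: float = 2.0,
    pseudocount: float = 1.0,
    mode: str = "any",
) -> bool:
    """True iff inoculated/mock fold-change strictly exceeds the threshold.

    ``mode="any"`` (default): at any paired time point; ``"all"``: at every
    paired time point.  Raises on a profile without paired time points.
    """
    tps = profile.paired_timepoints()
    if not tps:
        raise ValueError(f"{profile.gene_id}: no paired IN/UN timepoints")
    fcs = [fold_change(profile.roothair[(tp, "IN")], profile.roothair[(tp, "UN")],
                       pseudocount) for tp in tps]
    if mode == "any":
        return any(fc > threshold for fc in fcs)
    if mode == "all":
        return all(fc > threshold for fc in fcs)
    raise ValueError("mode must be 'any' or 'all'")


def call_nodule_preferential(
    profile: ExpressionProfile,
    threshold: float = 2.0,
    pseudocount: float = 1.0,
    other: str = "max",
    nodule_tissue: str = "nodule",
) -> bool:
    """True iff nodule abundance exceeds the other tissues by > threshold-fold.

    The reference is the maximum over non-nodule tissues by default
    (``other="mean"`` switches to their mean).
    """
    if nodule_tissue not in profile.atlas:
        raise ValueError(f"{profile.gene_id}: no '{nodule_tissue}' column in atlas")
    others = [v for t, v in profile.atlas.items() if t != nodule_tissue]
    if not others:
        raise ValueError(f"{profile.gene_id}: atlas needs at least one non-nodule tissue")
    ref = max(others) if other == "max" else sum(others) / len(others)
    return fold_change(profile.atlas[nodule_tissue], ref, pseudocount) > threshold


def classify_pattern(
    profile: ExpressionProfile,
    rh_induced: bool,
    nodule_preferential: bool,
    floor: float = 1.0,
) -> str:
    """nodulation-restricted if either call; broad if expressed in >= 2 tissues; else silent."""
    if rh_induced or nodule_preferential:
        return CATEGORY_RESTRICTED
    n_expressed = sum(1 for v in profile.atlas.values() if v > floor)
    return CATEGORY_BROAD if n_expressed >= 2 else CATEGORY_SILENT


def call_genes(
    expression: pd.DataFrame,
    threshold: float = 2.0,
    pseudocount: float = 1.0,
    floor: float = 1.0,
    rh_mode: str = "any",
    other: str = "max",
) -> dict[str, ExpressionCall]:
    """All three classifications for every row of an expression matrix."""
    calls: dict[str, ExpressionCall] = {}
    for gene_id, row in expression.iterrows():
        prof = ExpressionProfile.from_row(str(gene_id), row.to_dict())
        rh = call_rh_induced(prof, threshold, pseudocount, rh_mode)
        pref = call_nodule_preferential(prof, threshold, pseudocount, other)
        calls[str(gene_id)] = ExpressionCall(
            str(gene_id), rh, pref, classify_pattern(prof, rh, pref, floor))
    return calls


def lift_to_groups(
    groups: Iterable[OrthologGroup],
    calls: Mapping[str, ExpressionCall],
) -> list[GroupCallSummary]:
    """Any-member rule: a species flag is true iff >= 1 member gene has it."""
    out: list[GroupCallSummary] = []
    for grp in groups:
        rh: dict[str, bool] = {}
        pref: dict[str, bool] = {}
        cats: dict[str, str] = {}
        for sp, members in grp.members.items():
            rh[sp] = any(calls[m].rh_induced for m in members if m in calls)
            pref[sp] = any(calls[m].nodule_preferential for m in members if m in calls)
            for m in members:
                if m in calls:
                    cats[m] = calls[m].category
        out.append(GroupCallSummary(grp.group_id, rh, pref, cats))
    return out


def flagged_group_counts(
    summaries: Iterable[GroupCallSummary], flag: str
) -> dict[str, int]:
    """Per-species number of groups carrying the flag (``rh_induced`` or
    ``nodule_preferential``)."""
    counts: dict[str, int] = {}
    for s in summaries:
        flags = s.rh_induced_any if flag == "rh_induced" else s.nodule_pref_any
        for sp, val in flags.items():
            counts.setdefault(sp, 0)
            if val:
                counts[sp] += 1
    return dict(sorted(counts.items()))


def overlap_groups(
    summaries: Iterable[GroupCallSummary],
    flag: str,
    species_list: Sequence[str],
) -> dict[frozenset[str], int]:
    """Full Venn partition: groups flagged in exactly each subset of species.

    Keys are all non-empty subsets of ``species_list``; per-species totals
    are conserved (the counts of subsets containing S sum to the number of
    S-flagged groups).
    """
    if len(species_list) < 2:
        raise ValueError("need at least two species")
    counts: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(species_list) + 1)
        for sub in combinations(species_list, r)
    }
    for s in summaries:
        flags = s.rh_induced_any if flag == "rh_induced" else s.nodule_pref_any
        subset = frozenset(sp for sp in species_list if flags.get(sp, False))
        if subset:
            counts[subset] += 1
    return counts


def overlap_percent(n_shared: int, n_species_total: int) -> int:
    """Integer percent of a species' flagged groups that are shared.

    Rounded to the nearest integer, half away from zero (reproducing the
    printed 34/69/22/29% from counts 11/32, 11/16, 4/18, 4/14).
    """
    if n_species_total <= 0:
        raise ValueError("n_species_total must be positive")
    if n_shared < 0 or n_shared > n_species_total:
        raise ValueError("n_shared must lie in [0, n_species_total]")
    return int(math.floor(100.0 * n_shared / n_species_total + 0.5))


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def calls_table(calls: Mapping[str, ExpressionCall]) -> pd.DataFrame:
    rows = [(c.gene_id, c.rh_induced, c.nodule_preferential, c.category)
            for c in calls.values()]
    return pd.DataFrame(rows, columns=[
        "gene_id", "rh_induced", "nodule_preferential", "category"]).sort_values(
        "gene_id").reset_index(drop=True)


def group_summary_table(summaries: Iterable[GroupCallSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for sp in sorted(set(s.rh_induced_any) | set(s.nodule_pref_any)):
            rows.append((s.group_id, sp,
                         s.rh_induced_any.get(sp, False),
                         s.nodule_pref_any.get(sp, False)))
    return pd.DataFrame(rows, columns=[
        "group_id", "species", "rh_induced_any", "nodule_pref_any"])


def venn_table(
    summaries: Sequence[GroupCallSummary],
    flag: str,
    species_list: Sequence[str],
) -> pd.DataFrame:
    """Venn counts with the shared-of-total percentage per species.

    The percentage reported for the full intersection row mirrors the
    shared-over-per-species-total statistic of the underlying analysis.
    """
    counts = overlap_groups(summaries, flag, species_list)
    totals = flagged_group_counts(summaries, flag)
    rows = []
    for subset in sorted(counts, key=lambda s: (len(s), sorted(s))):
        n = counts[subset]
        pct = {}
        for sp in sorted(subset):
            total = totals.get(sp, 0)
            pct[sp] = overlap_percent(n, total) if total else 0
        rows.append(("&".join(sorted(subset)), n,
                     ";".join(f"{sp}={p}" for sp, p in pct.items())))
    return pd.DataFrame(rows, columns=["subset", "n_groups", "percent_of_species_total"])
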