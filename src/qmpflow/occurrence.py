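"""Longitudinal occurrence patterns: colonization, disappearance, core.

Per genus and gut segment, the number of birds in which the genus is
detected (abundance above the detection threshold, default > 0 copies/g)
is counted at every sampling day. Counts become per-day states:

    present    detected in >= presence_min birds (default 9 of 10)
    absent     detected in <= absence_max birds (default 1)
    transition otherwise

and the ordered state sequence is classified:

    core           present at every day
    colonization   absent at the first day, absent up to some onset,
                   present from the onset onward
    disappearance  present at the first day, present up to some offset,
                   absent from the offset onward
    irregular      everything else, including any transition state
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable

STATES = ("present", "absent", "transition")
CATEGORIES = ("colonization", "disappearance", "core", "irregular")


@dataclass
class PatternCategory:
    category: str
    onset_dph: float | None = None  # first present day (colonization)
    offset_dph: float | None = None  # first absent day (disappearance)


def detection_matrix(
    table: FeatureTable, genus: str, segment: str, threshold: float = 0.0
) -> pd.Series:
    """Birds with abundance > threshold at each day, for one genus and
    segment. Indexed by DPH, ascending."""
    if genus not in table.taxa:
        raise ValueError(f"genus {genus!r} absent from table")
    sub = table.subset(table.meta["segment"] == segment)
    detected = sub.data[genus] > threshold
    counts = detected.groupby(sub.meta["dph"]).sum()
    return counts.sort_index().astype(int)


def states_from_counts(
    counts, n_birds: int, presence_min: int = 9, absence_max: int = 1
) -> list[str]:
    """Threshold detection counts into per-day states."""
    if presence_min <= absence_max:
        raise ValueError("presence_min must exceed absence_max")
    counts = np.asarray(counts)
    if np.any(counts > n_birds):
        raise ValueError("detection count exceeds the number of birds")
    out = []
    for c in counts:
        if c >= presence_min:
            out.append("present")
        elif c <= absence_max:
            out.append("absent")
        else:
            out.append("transition")
    return out


def classify_pattern(
    states: list[str],
    dph: list | None = None,
    transitions_as: str = "irregular",
) -> PatternCategory:
    """Classify an ordered state sequence into an occurrence category.

    ``transitions_as`` controls strictness: "irregular" (default) sends
    any sequence containing a transition state to the irregular category;
    "absent"/"present" recode transitions before classification.
    """
    if len(states) < 2:
        raise ValueError("need at least two time points")
    states = list(states)
    if transitions_as in ("absent", "present"):
        states = [transitions_as if s == "transition" else s for s in states]
    elif transitions_as != "irregular":
        raise ValueError("transitions_as must be absent|present|irregular")
    if "transition" in states:
        return PatternCategory("irregular")
    flags = [s == "present" for s in states]
    idx = dph if dph is not None else list(range(len(states)))
    if all(flags):
        return PatternCategory("core")
    if not flags[0]:
        # colonization: absent prefix then present suffix
        try:
            onset = flags.index(True)
        except ValueError:
            return PatternCategory("irregular")  # never present
        if all(flags[onset:]) and not any(flags[:onset]):
            return PatternCategory("colonization", onset_dph=idx[onset])
        return PatternCategory("irregular")
    # present at first day
    try:
        offset = flags.index(False)
    except ValueError:  # unreachable: all(flags) handled above
        return PatternCategory("core")
    if not any(flags[offset:]):
        return PatternCategory("disappearance", offset_dph=idx[offset])
    return PatternCategory("irregular")


def occurrence_table(
    table: FeatureTable,
    segment: str,
    presence_min: int = 9,
    absence_max: int = 1,
    threshold: float = 0.0,
    transitions_as: str = "irregular",
) -> pd.DataFrame:
    """Per-genus occurrence states and category for one segment."""
    sub = table.subset(table.meta["segment"] == segment)
    days = sorted(sub.meta["dph"].unique())
    n_birds = sub.meta.groupby("dph")["bird"].nunique().max()
    rows = []
    for genus in table.taxa:
        counts = detection_matrix(table, genus, segment, threshold).reindex(days, fill_value=0)
        states = states_from_counts(counts.to_numpy(), n_birds, presence_min, absence_max)
        cat = classify_pattern(states, dph=days, transitions_as=transitions_as)
        rows.append(
            {
                "genus": genus,
                "segment": segment,
                "category": cat.category,
                "onset_dph": cat.onset_dph,
                "offset_dph": cat.offset_dph,
                "states": ",".join(states),
            }
        )
    return pd.DataFrame(rows)


def pattern_census(
    table: FeatureTable,
    segments: list[str],
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[tuple, set]]]:
    """Occurrence inventory across segments.

    Returns (long per-genus table, per-segment x category counts of
    genera and of distinct state sequences, per-category intersection
    sets keyed by segment combination).
    """
    longs = [occurrence_table(table, seg, **kwargs) for seg in segments]
    long_df = pd.concat(longs, ignore_index=True)
    census = (
        long_df.groupby(["segment", "category"])
        .agg(n_genera=("genus", "nunique"), n_patterns=("states", "nunique"))
        .reset_index()
    )
    intersections: dict[str, dict[tuple, set]] = {}
    for cat in CATEGORIES:
        per_seg = {
            seg: set(long_df[(long_df.segment == seg) & (long_df.category == cat)].genus)
            for seg in segments
        }
        combos: dict[tuple, set] = {}
        from itertools import combinations

        for r in range(1, len(segments) + 1):
            for combo in combinations(segments, r):
                inter = set.intersection(*(per_seg[s] for s in combo)) if combo else set()
                combos[combo] = inter
        intersections[cat] = combos
    return long_df, census, intersections
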