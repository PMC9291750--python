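"""Social natal dispersal: community assignment of calves over time.

A calf's social position is read off the adult females it is grouped with:
each detection is assigned to the social community holding the majority of
the adult females in that group.  The natal community is the modal
assignment before weaning (<= 18 months), and social dispersal is a
permanent post-weaning switch of association: the calf shifts to, and is
subsequently always associated with, one or more communities different from
its natal one.  Non-natal spells that are followed by a return to the natal
community count as exploratory social visits, not dispersal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UNASSIGNED",
    "WEANING_AGE_MONTHS",
    "assign_detection_community",
    "community_timeline",
    "natal_community",
    "classify_social",
    "SocialOutcome",
    "bachelor_herd_ages",
]

#: sentinel for detections that cannot be assigned to a community
UNASSIGNED = "UNASSIGNED"

#: maximum weaning age (months); calves travel with their mothers before this
WEANING_AGE_MONTHS = 18.0


def assign_detection_community(member_communities, method: str = "majority"):
    """Community assignment of one detection from its adult-female groupmates.

    Parameters
    ----------
    member_communities : sequence
        Community labels of the adult females in the group.
    method : "majority" or "unanimous"
        Majority takes the plurality label (tie -> UNASSIGNED); unanimous
        assigns only when all adult females agree.

    Returns
    -------
    (label, support) where support is the fraction of adult females carrying
    the winning label; (UNASSIGNED, nan) when no assignment is possible.
    """
    labels = [c for c in member_communities if c is not None]
    if not labels:
        return UNASSIGNED, float("nan")
    counts = pd.Series(labels).value_counts()
    if method == "unanimous":
        if len(counts) == 1:
            return counts.index[0], 1.0
        return UNASSIGNED, float("nan")
    if method != "majority":
        raise ValueError(f"unknown method {method!r}")
    top = counts.iloc[0]
    winners = counts.index[counts == top]
    if len(winners) > 1:
        return UNASSIGNED, float("nan")
    return winners[0], float(top / len(labels))


def community_timeline(
    calf_id,
    detections: pd.DataFrame,
    membership: dict,
    method: str = "majority",
) -> pd.DataFrame:
    """Per-detection community assignments of one calf, chronologically.

    ``detections`` is the full detection table (used to find the adult
    females sharing the calf's groups); ``membership`` maps adult-female id
    to community.  Returns a DataFrame with columns ``occasion``,
    ``age_months``, ``community`` (label or UNASSIGNED) and ``support``.
    """
    calf = detections[detections["id"] == calf_id].sort_values("occasion")
    if calf.empty:
        raise ValueError(f"no detections for calf {calf_id!r}")
    adults = detections[detections["id"].isin(membership)]
    by_group = adults.groupby(["occasion", "group_id"])["id"].apply(list)
    rows = []
    for _, det in calf.iterrows():
        key = (det["occasion"], det["group_id"])
        members = by_group.get(key, [])
        comms = [membership[a] for a in members if a != calf_id]
        label, support = assign_detection_community(comms, method=method)
        rows.append(
            {
                "occasion": det["occasion"],
                "age_months": float(det["age_months"]),
                "community": label,
                "support": support,
            }
        )
    return pd.DataFrame(rows)


def natal_community(timeline: pd.DataFrame, weaning_age: float = WEANING_AGE_MONTHS):
    """Natal community: modal assignment among detections before weaning.

    Ties are broken in favour of the earliest assigned detection's community.
    Returns None when the calf has no assigned pre-weaning detection (such
    calves cannot be classified socially).
    """
    early = timeline[
        (timeline["age_months"] <= weaning_age)
        & (timeline["community"] != UNASSIGNED)
    ]
    if early.empty:
        return None
    counts = early["community"].value_counts()
    top = counts.iloc[0]
    winners = set(counts.index[counts == top])
    if len(winners) == 1:
        return counts.index[0]
    for c in early["community"]:
        if c in winners:
            return c


@dataclass
class SocialOutcome:
    """Social-dispersal classification of one calf."""

    calf_id: object
    natal_community: object
    social_dispersal: int | None  # None when undetermined
    dispersal_age_months: float | None = None
    destinations: list = field(default_factory=list)
    n_exploratory_visits: int = 0
    undetermined: bool = False
    single_terminal: bool = False


def classify_social(
    timeline: pd.DataFrame,
    natal,
    calf_id=None,
    weaning_age: float = WEANING_AGE_MONTHS,
) -> SocialOutcome:
    """Classify social dispersal from a calf's community timeline.

    Rules, applied to the assigned (non-UNASSIGNED) detections in order:

    * always natal -> no social dispersal;
    * non-natal spells followed by a later natal detection -> exploratory
      visits, no social dispersal;
    * a terminal run of non-natal assignments starting after weaning ->
      social dispersal, with dispersal age the age at the first detection of
      that run.  A terminal run of length one is still counted as dispersal
      but flagged ``single_terminal`` (the switch cannot be confirmed by a
      repeat sighting).

    Fewer than two assigned detections, or no natal community, yields an
    undetermined outcome.
    """
    rows = timeline[timeline["community"] != UNASSIGNED].sort_values("occasion")
    if natal is None or len(rows) < 2 or not (rows["community"] == natal).any():
        return SocialOutcome(
            calf_id, natal, None, undetermined=True
        )
    labels = rows["community"].to_numpy(object)
    ages = rows["age_months"].to_numpy(float)
    is_natal = labels == natal
    last_natal = int(np.flatnonzero(is_natal)[-1])

    # maximal non-natal runs
    visits = 0
    i = 0
    while i < len(labels):
        if not is_natal[i]:
            j = i
            while j + 1 < len(labels) and not is_natal[j + 1]:
                j += 1
            if j < last_natal:
                visits += 1
            i = j + 1
        else:
            i += 1

    if last_natal == len(labels) - 1:
        return SocialOutcome(
            calf_id, natal, 0, n_exploratory_visits=visits
        )
    switch = last_natal + 1
    switch_age = float(ages[switch])
    if switch_age <= weaning_age:
        # apparent pre-weaning switch: not interpretable as independent dispersal
        return SocialOutcome(
            calf_id, natal, 0, n_exploratory_visits=visits
        )
    terminal = labels[switch:]
    dests = list(pd.unique(pd.Series(terminal)))
    return SocialOutcome(
        calf_id,
        natal,
        1,
        dispersal_age_months=switch_age,
        destinations=dests,
        n_exploratory_visits=visits,
        single_terminal=(len(terminal) == 1),
    )


def bachelor_herd_ages(detections: pd.DataFrame) -> pd.Series:
    """Age each individual was first seen in a bachelor herd.

    A bachelor herd is a group with strictly more males than females
    (individuals of unknown sex are ignored in the count).  Returns a Series
    indexed by individual id; individuals never seen in such a group are
    absent.  Requires ``sex`` and ``age_months`` columns.
    """
    d = detections.copy()
    sex_known = d["sex"].isin(["M", "F"])
    counts = (
        d[sex_known]
        .drop_duplicates(["occasion", "group_id", "id"])
        .groupby(["occasion", "group_id"])["sex"]
        .value_counts()
        .unstack(fill_value=0)
    )
    males = counts["M"] if "M" in counts else 0
    females = counts["F"] if "F" in counts else 0
    bachelor = counts.index[(males > females)] if len(counts) else []
    keys = pd.MultiIndex.from_frame(d[["occasion", "group_id"]])
    in_bachelor = keys.isin(bachelor)
    sub = d[in_bachelor]
    if sub.empty:
        return pd.Series(dtype=float, name="first_bachelor_age")
    out = sub.groupby("id")["age_months"].min()
    out.name = "first_bachelor_age"
    return out
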