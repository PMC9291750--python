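"""Adult-female association network and social-community detection.

Under the gambit of the group, all individuals photographed in the same
fission-fusion group are taken to be associating.  Grouped detections of
adult females are converted to a group-by-individual matrix, pairwise
association strengths are measured with the simple ratio index (SRI), and the
weighted network is partitioned into social communities by modularity
maximisation (greedy local moving with refinement, seeded).  In multi-level
societies these communities are the stable upper tier of organisation on top
of fluid day-to-day group membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "adult_females",
    "build_gbi",
    "GroupByIndividualMatrix",
    "simple_ratio_index",
    "AssociationMatrix",
    "detect_communities",
    "CommunityPartition",
    "community_stability",
    "StabilityReport",
    "partition_assortativity",
]


def adult_females(detections: pd.DataFrame, min_sightings: int = 0) -> list:
    """IDs of adult females: sex F and adult at first sighting.

    An individual qualifies when its earliest detection carries the field age
    class "adult", or an estimated age of at least 48 months where an
    ``age_months`` column is available.  ``min_sightings`` optionally drops
    rarely seen individuals before networking.
    """
    d = detections.sort_values("occasion")
    first = d.groupby("id", sort=True).first()
    is_f = first["sex"] == "F"
    is_adult = first.get("age_class")
    adult = is_adult == "adult" if is_adult is not None else pd.Series(False, index=first.index)
    if "age_months" in first.columns:
        adult = adult | (first["age_months"] >= 48)
    ids = first.index[is_f & adult]
    if min_sightings > 0:
        counts = d.groupby("id").size()
        ids = [i for i in ids if counts.get(i, 0) >= min_sightings]
    return sorted(ids)


@dataclass
class GroupByIndividualMatrix:
    """Binary groups-by-individuals matrix with the occasion of each group."""

    matrix: np.ndarray  # (n_groups, n_individuals), 0/1
    ids: list
    occasions: np.ndarray  # (n_groups,)
    group_ids: list


def build_gbi(detections: pd.DataFrame, adult_ids=None, min_sightings: int = 0) -> GroupByIndividualMatrix:
    """Group-by-individual matrix over adult females.

    One row per observed group (within an occasion) containing at least one
    adult female; columns are restricted to adult females.
    """
    if adult_ids is None:
        adult_ids = adult_females(detections, min_sightings=min_sightings)
    adult_ids = sorted(adult_ids)
    if not adult_ids:
        raise ValueError("no adult females in the detection table")
    col = {a: j for j, a in enumerate(adult_ids)}
    sub = detections[detections["id"].isin(col)]
    rows = []
    occasions = []
    group_keys = []
    for (occ, gid), grp in sub.groupby(["occasion", "group_id"], sort=True):
        row = np.zeros(len(adult_ids), dtype=np.int8)
        row[[col[i] for i in grp["id"].unique()]] = 1
        rows.append(row)
        occasions.append(occ)
        group_keys.append((occ, gid))
    if not rows:
        raise ValueError("no groups containing adult females")
    return GroupByIndividualMatrix(
        np.array(rows, dtype=np.int8), adult_ids, np.asarray(occasions), group_keys
    )


@dataclass
class AssociationMatrix:
    """Symmetric simple-ratio-index matrix with its ID order."""

    matrix: np.ndarray
    ids: list

    def to_edgelist(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.ids), k=1)
        return pd.DataFrame(
            {
                "id_a": [self.ids[i] for i in iu],
                "id_b": [self.ids[j] for j in ju],
                "sri": self.matrix[iu, ju],
            }
        )


def simple_ratio_index(gbi: GroupByIndividualMatrix) -> AssociationMatrix:
    """Simple ratio index over a group-by-individual matrix.

    SRI(a, b) = x / (x + y_ab + y_a + y_b), with x the number of groups
    containing both, y_a (y_b) the occasions where only a (only b) was seen,
    and y_ab the occasions where both were seen but in different groups.
    The denominator equals the number of occasions in which at least one of
    the pair was seen; 0/0 is defined as 0.
    """
    x_mat = gbi.matrix.astype(float)
    if x_mat.shape[1] < 2:
        raise ValueError("need at least 2 individuals")
    together = x_mat.T @ x_mat  # group-level co-occurrence counts
    # occasion-level "seen" indicator
    occ_index = pd.factorize(gbi.occasions)[0]
    n_occ = occ_index.max() + 1
    seen = np.zeros((n_occ, x_mat.shape[1]))
    np.maximum.at(seen, occ_index, x_mat)
    both_seen = seen.T @ seen
    n_seen = seen.sum(axis=0)
    denom = n_seen[:, None] + n_seen[None, :] - both_seen
    with np.errstate(divide="ignore", invalid="ignore"):
        sri = np.where(denom > 0, together / denom, 0.0)
    np.fill_diagonal(sri, 0.0)
    sri = 0.5 * (sri + sri.T)  # enforce exact symmetry
    return AssociationMatrix(sri, list(gbi.ids))


@dataclass
class CommunityPartition:
    """Partition of adult females into social communities."""

    membership: dict  # id -> community label (0..k-1)
    modularity: float
    n_communities: int

    def labels_for(self, ids) -> np.ndarray:
        return np.array([self.membership[i] for i in ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.membership.items()), columns=["id", "community"]
        )


def _igraph_from(assoc: AssociationMatrix):
    n = len(assoc.ids)
    iu, ju = np.triu_indices(n, k=1)
    w = assoc.matrix[iu, ju]
    pos = w > 0
    g = igraph.Graph(
        n=n, edges=list(zip(iu[pos].tolist(), ju[pos].tolist()))
    )
    g.es["weight"] = w[pos].tolist()
    return g


def detect_communities(assoc: AssociationMatrix, seed: int = 0) -> CommunityPartition:
    """Partition the weighted association network into social communities.

    Maximises weighted Newman modularity Q by iterated greedy local moving
    with community refinement and aggregation (the Leiden algorithm, run to
    convergence), which resolves many similar-sized communities where plain
    agglomerative merging stalls.  Deterministic given the seed.  Labels are
    assigned 0..k-1 by decreasing community size, ties by smallest member ID.
    """
    n = len(assoc.ids)
    if n == 0:
        raise ValueError("empty network")
    g = _igraph_from(assoc)
    if g.ecount() == 0:
        communities = [{v} for v in assoc.ids]
        q = 0.0
    else:
        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, weights="weight",
            seed=seed, n_iterations=-1,
        )
        communities = [
            {assoc.ids[v] for v in comm} for comm in part
        ]
        q = g.modularity(part.membership, weights="weight")
    communities = sorted(communities, key=lambda c: (-len(c), min(map(str, c))))
    membership = {v: k for k, nodes in enumerate(communities) for v in nodes}
    return CommunityPartition(membership, float(q), len(communities))


def partition_assortativity(assoc: AssociationMatrix, membership: dict) -> float:
    """Weighted assortativity of a discrete partition on a network.

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i), where e is the
    weight-mixing matrix between community labels.  1 means all weight falls
    within communities; ~0 means the partition is unrelated to edge weight.
    """
    ids = assoc.ids
    labels = np.array([membership[i] for i in ids])
    uniq = np.unique(labels)
    idx = {c: k for k, c in enumerate(uniq)}
    lab = np.array([idx[c] for c in labels])
    W = assoc.matrix
    total = W.sum()
    if total == 0:
        return 0.0
    e = np.zeros((len(uniq), len(uniq)))
    for a in range(len(uniq)):
        for b in range(len(uniq)):
            e[a, b] = W[np.ix_(lab == a, lab == b)].sum()
    e /= total
    trace = np.trace(e)
    ab = float((e.sum(axis=0) * e.sum(axis=1)).sum())
    if ab >= 1.0:
        return 0.0
    return float((trace - ab) / (1.0 - ab))


@dataclass
class StabilityReport:
    per_block: pd.DataFrame
    pairwise_ari: pd.DataFrame

    @property
    def mean_ari(self) -> float:
        m = self.pairwise_ari.to_numpy(dtype=float)
        iu = np.triu_indices(m.shape[0], k=1)
        return float(np.nanmean(m[iu])) if iu[0].size else float("nan")


def community_stability(
    detections: pd.DataFrame,
    partition: CommunityPartition,
    n_periods: int,
    adult_ids=None,
    seed: int = 0,
) -> StabilityReport:
    """Temporal stability of the community partition.

    The occasion range is split into ``n_periods`` contiguous blocks; the
    network and partition are re-derived in each block and compared to the
    full-data partition (adjusted Rand index) and to each other (pairwise
    ARI).  The report also gives the assortativity of the full-data labels
    on each block's network.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    if adult_ids is None:
        adult_ids = adult_females(detections)
    occ = np.sort(detections["occasion"].unique())
    blocks = np.array_split(occ, n_periods)
    rows, parts = [], {}
    for b, occs in enumerate(blocks):
        sub = detections[detections["occasion"].isin(occs)]
        present = [i for i in adult_ids if (sub["id"] == i).any()]
        if len(present) < 2:
            warnings.warn(f"block {b} has <2 adult females; skipped")
            continue
        gbi = build_gbi(sub, adult_ids=present)
        assoc = simple_ratio_index(gbi)
        part = detect_communities(assoc, seed=seed)
        parts[b] = part
        shared = [i for i in present if i in partition.membership]
        ari = adjusted_rand_score(
            partition.labels_for(shared), part.labels_for(shared)
        )
        rows.append(
            {
                "block": b,
                "n_individuals": len(present),
                "n_communities": part.n_communities,
                "ari_vs_full": float(ari),
                "assortativity_full_labels": partition_assortativity(
                    assoc, partition.membership
                ),
            }
        )
    labels = sorted(parts)
    pw = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for bl in labels[i + 1:]:
            shared = [
                x for x in parts[a].membership if x in parts[bl].membership
            ]
            v = (
                adjusted_rand_score(
                    parts[a].labels_for(shared), parts[bl].labels_for(shared)
                )
                if len(shared) >= 2
                else np.nan
            )
            pw.loc[a, bl] = pw.loc[bl, a] = v
    return StabilityReport(pd.DataFrame(rows), pw)
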