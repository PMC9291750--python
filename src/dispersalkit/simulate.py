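"""Synthetic fission-fusion society with known dispersal ground truth.

The generator emulates a photographic mark-resight study of a giraffe-like
metapopulation: ~12 spatially overlapping adult-female communities of 60-90
members are surveyed over 7 years on a robust design (3 survey seasons per
year, each with 2 back-to-back secondary samples, 42 occasions in all).
Each occasion, community members are partitioned into fission-fusion groups
by a Chinese-restaurant process; a small fraction of groups merge with a
group from the nearest neighbouring community, producing the weak
between-community ties real networks show.  Calves are born in the first two
study years with a planted dispersal fate per sex:

* ``none`` - keep sampling natal-community groups near the natal range;
* ``social`` - at the planted dispersal age, permanently switch group
  sampling to the nearest neighbouring community while shifting location
  only a fraction of the threshold radius;
* ``spatial`` - relocate well beyond the natal threshold radius while still
  sampling natal-community groups;
* ``social-and-spatial`` - relocate and switch community.

Sorties (single-occasion exceedances of the threshold with return) occur at
a per-occasion rate before dispersal.  Detection is Bernoulli per occasion,
and measured heights follow the shared growth curve plus noise, so the
photogrammetric ageing stage can be exercised end to end.  Everything is a
deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .growth import DEFAULT_CURVE, GrowthCurve, assign_age_class
from .spatial import _tm_inverse

__all__ = [
    "SimConfig",
    "SyntheticSociety",
    "simulate_society",
    "simulate_multinomial_records",
    "simulate_binary_records",
    "FATES",
]

#: dispersal fates, in the order used by fate probability vectors
FATES = ("none", "social", "spatial", "social-and-spatial")

#: fate probabilities matching the field study's observed per-sex class
#: frequencies (males 21/12/8/26 of 67; females 52/4/9/5 of 70)
_DEFAULT_FATE_PROBS = {
    "M": (21 / 67, 12 / 67, 8 / 67, 26 / 67),
    "F": (52 / 70, 4 / 70, 9 / 70, 5 / 70),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic society.

    Distances are km, rates are per-occasion probabilities, ages are months.
    ``hr_sigma`` is the per-occasion bivariate-normal movement scatter of
    adult females about their fixed home-range centres, which makes the true
    95% home-range isopleth analytically known: area = 5.991*pi*hr_sigma^2,
    hence a generating threshold radius of sqrt(5.991)*hr_sigma.
    ``calf_sigma`` is the (smaller) movement scatter of dependent young.
    """

    n_communities: int = 12
    members_per_community: tuple = (60, 90)
    hr_center_spacing: float = 6.0
    hr_sigma: float = 2.5
    calf_sigma: float = 1.5
    center_scatter_km: float = 1.0
    n_years: int = 7
    occasions_per_year: int = 3
    secondary_per_primary: int = 2
    p_detect: float = 0.9
    group_mixing: float = 0.02
    crp_concentration: float = 8.0
    n_calves: int = 200
    fate_probs: dict = field(default_factory=lambda: dict(_DEFAULT_FATE_PROBS))
    dispersal_age_mean: float = 46.0
    dispersal_age_sd: float = 13.0
    dispersal_age_min: float = 20.0
    sortie_rate: float = 0.02
    sortie_factor: float = 1.5
    social_shift_factor: float = 0.4
    spatial_shift_factor: float = 2.0
    both_shift_factor: float = 2.5
    height_noise_sd: float = 10.0
    covariate_effects: dict | None = None
    growth_curve: GrowthCurve = DEFAULT_CURVE
    origin_lonlat: tuple = (36.0, -4.0)
    start_year: int = 2012
    seed: int = 0

    def __post_init__(self):
        if self.n_communities < 2:
            raise ValueError("need at least 2 communities")
        lo, hi = self.members_per_community
        if lo < 3:
            raise ValueError("members_per_community too small to form groups")
        if hi < lo:
            raise ValueError("invalid members_per_community range")
        for name in ("p_detect", "group_mixing", "sortie_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for sex, probs in self.fate_probs.items():
            if len(probs) != len(FATES) or any(p < 0 for p in probs):
                raise ValueError(f"fate_probs[{sex!r}] must be 4 non-negative values")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"fate_probs[{sex!r}] must sum to 1")

    @property
    def n_occasions(self) -> int:
        return self.n_years * self.occasions_per_year * self.secondary_per_primary

    @property
    def threshold_radius_km(self) -> float:
        """Generating spatial-dispersal threshold: radius of the true 95%
        isopleth of adult movement, sqrt(chi2_2(0.95)) * hr_sigma."""
        return float(np.sqrt(stats.chi2.ppf(0.95, df=2)) * self.hr_sigma)

    def occasion_time_months(self, occ: int) -> float:
        """Months since study start at a given occasion index."""
        per_year = self.occasions_per_year * self.secondary_per_primary
        year, rem = divmod(occ, per_year)
        season, secondary = divmod(rem, self.secondary_per_primary)
        season_month = 12.0 * (season + 1) / self.occasions_per_year - 2.0
        return 12.0 * year + season_month + 0.25 * secondary


@dataclass
class SyntheticSociety:
    """Output bundle of :func:`simulate_society`."""

    detections: pd.DataFrame
    truth: pd.DataFrame
    covariates: pd.DataFrame
    adult_communities: dict
    config: SimConfig

    def __iter__(self):
        # allow ``detections, truth = simulate_society(cfg)``
        return iter((self.detections, self.truth))


def _crp_partition(members: np.ndarray, theta: float, rng) -> list:
    """Chinese-restaurant-process partition of ``members`` into groups."""
    order = rng.permutation(len(members))
    groups: list[list] = []
    for i, idx in enumerate(order):
        if i == 0:
            groups.append([members[idx]])
            continue
        sizes = np.array([len(g) for g in groups], dtype=float)
        probs = np.append(sizes, theta)
        probs /= probs.sum()
        k = rng.choice(len(groups) + 1, p=probs)
        if k == len(groups):
            groups.append([members[idx]])
        else:
            groups[k].append(members[idx])
    return groups


def _fate_probs_for(cfg: SimConfig, sex: str, cov_row, cov_means) -> np.ndarray:
    """Fate probabilities, optionally tilted by community covariates via a
    multinomial-logit link (reference level: none)."""
    base = np.asarray(cfg.fate_probs[sex], dtype=float)
    if cfg.covariate_effects is None:
        return base
    base = np.clip(base, 1e-9, None)
    logits = np.log(base / base[0])
    for j, fate in enumerate(FATES[1:], start=1):
        for cov, coef in cfg.covariate_effects.get(fate, {}).items():
            logits[j] += coef * (cov_row[cov] - cov_means[cov])
    ex = np.exp(logits - logits.max())
    return ex / ex.sum()


def simulate_society(config: SimConfig) -> SyntheticSociety:
    """Generate a detection table and ground-truth table for one society.

    See the module docstring for the generative model.  The same config
    (including its seed) always produces identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_communities
    r_thr = cfg.threshold_radius_km

    # --- communities on a grid, nearest-neighbour adjacency
    ncols = int(np.ceil(np.sqrt(K)))
    centers = np.array(
        [((k % ncols) * cfg.hr_center_spacing, (k // ncols) * cfg.hr_center_spacing)
         for k in range(K)],
        dtype=float,
    )
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nearest = d2.argmin(axis=1)

    # --- community covariates
    covariates = pd.DataFrame(
        {
            "community": np.arange(K),
            "forage": rng.uniform(0.2, 0.8, K),
            "dist_town": rng.uniform(2.0, 30.0, K),
            "dist_boma": rng.uniform(0.5, 10.0, K),
            "density": rng.uniform(0.8, 2.2, K),
        }
    ).set_index("community")
    cov_means = covariates.mean()

    # --- adult females
    lo, hi = cfg.members_per_community
    n_members = rng.integers(lo, hi + 1, K)
    adult_ids, adult_comm, adult_centers = [], [], []
    for k in range(K):
        for j in range(n_members[k]):
            adult_ids.append(f"A{k:02d}_{j:03d}")
            adult_comm.append(k)
            adult_centers.append(
                centers[k] + rng.normal(0.0, cfg.center_scatter_km, 2)
            )
    adult_comm = np.array(adult_comm)
    adult_centers = np.array(adult_centers)
    n_adults = len(adult_ids)
    adult_age0 = rng.uniform(48.0, 200.0, n_adults)  # months at study start

    # --- calves with planted fates
    study_end = cfg.occasion_time_months(cfg.n_occasions - 1)
    calves = []
    for i in range(cfg.n_calves):
        natal = int(rng.integers(0, K))
        sex = "M" if rng.random() < 0.5 else "F"
        birth_year = int(rng.integers(0, 2))
        birth = 12.0 * birth_year + rng.integers(0, 12)
        probs = _fate_probs_for(cfg, sex, covariates.loc[natal], cov_means)
        fate = FATES[rng.choice(len(FATES), p=probs)]
        mother = int(rng.integers(0, n_members[natal]))
        mother_idx = int(np.flatnonzero(adult_comm == natal)[mother])
        # planted dispersal age, conditioned to fall inside the observation
        # window with enough follow-up occasions to confirm the switch
        age_cap = study_end - birth - 10.0
        disp_age = np.nan
        if fate != "none":
            a, b = cfg.dispersal_age_min, max(age_cap, cfg.dispersal_age_min + 6.0)
            while True:
                draw = rng.normal(cfg.dispersal_age_mean, cfg.dispersal_age_sd)
                if a <= draw <= b:
                    disp_age = float(draw)
                    break
        theta = rng.uniform(0, 2 * np.pi)
        shift_dir = np.array([np.cos(theta), np.sin(theta)])
        dest = int(nearest[natal])
        to_dest = centers[dest] - centers[natal]
        to_dest = to_dest / np.linalg.norm(to_dest)
        if fate == "social":
            shift = to_dest * cfg.social_shift_factor * r_thr
        elif fate == "spatial":
            shift = shift_dir * cfg.spatial_shift_factor * r_thr
        elif fate == "social-and-spatial":
            shift = shift_dir * cfg.both_shift_factor * r_thr
        else:
            shift = np.zeros(2)
        calves.append(
            {
                "id": f"C{i:03d}",
                "sex": sex,
                "birth_community": natal,
                "fate": fate,
                "dispersal_age_months": disp_age,
                "birth_month": float(birth),
                "mother_id": adult_ids[mother_idx],
                "_mother_idx": mother_idx,
                "_home": adult_centers[mother_idx].copy(),
                "_shift": shift,
                "_dest": dest if fate in ("social", "social-and-spatial") else natal,
            }
        )

    # planted sortie occasions (pre-dispersal, post-birth)
    for c in calves:
        sorties = []
        for occ in range(cfg.n_occasions):
            age = cfg.occasion_time_months(occ) - c["birth_month"]
            if age < 2.0:
                continue
            end = c["dispersal_age_months"]
            if np.isfinite(end) and age >= end:
                continue
            if rng.random() < cfg.sortie_rate:
                sorties.append(occ)
        c["_sorties"] = set(sorties)

    # --- occasion loop
    records = []
    per_year = cfg.occasions_per_year * cfg.secondary_per_primary
    for occ in range(cfg.n_occasions):
        t = cfg.occasion_time_months(occ)
        year = cfg.start_year + occ // per_year
        season = (occ % per_year) // cfg.secondary_per_primary
        secondary = occ % cfg.secondary_per_primary

        adult_loc = adult_centers + rng.normal(0.0, cfg.hr_sigma, (n_adults, 2))

        # fission-fusion groups per community
        groups = []  # list of dicts: community, adult indices
        for k in range(K):
            members = np.flatnonzero(adult_comm == k)
            for g in _crp_partition(members, cfg.crp_concentration, rng):
                groups.append({"community": k, "adults": list(g)})
        # cross-community merging with the nearest neighbour community
        merged = [False] * len(groups)
        for gi in range(len(groups)):
            if merged[gi] or rng.random() >= cfg.group_mixing:
                continue
            nb = nearest[groups[gi]["community"]]
            cands = [
                j
                for j in range(len(groups))
                if not merged[j] and j != gi and groups[j]["community"] == nb
            ]
            if not cands:
                continue
            gj = cands[int(rng.integers(0, len(cands)))]
            groups[gi]["adults"].extend(groups[gj]["adults"])
            merged[gj] = True
        groups = [g for j, g in enumerate(groups) if not merged[j]]
        adult_group = {}
        for gid, g in enumerate(groups):
            for a in g["adults"]:
                adult_group[a] = gid
        sizes_by_comm = {}
        for gid, g in enumerate(groups):
            sizes_by_comm.setdefault(g["community"], []).append(
                (gid, len(g["adults"]))
            )

        def pick_group(comm):
            opts = sizes_by_comm[comm]
            w = np.array([s for _, s in opts], dtype=float)
            return opts[rng.choice(len(opts), p=w / w.sum())][0]

        # calves
        calf_rows = []
        for c in calves:
            age = t - c["birth_month"]
            if age < 0:
                continue
            home = c["_home"]
            disp = c["dispersal_age_months"]
            dispersed = np.isfinite(disp) and age >= disp
            if age < 18.0:
                # dependent calves share the mother's group but stay in the
                # core of her range (creche behaviour): their own, smaller,
                # movement scatter about her home-range centre
                gid = adult_group[c["_mother_idx"]]
                loc = home + rng.normal(0.0, cfg.calf_sigma, 2)
            else:
                comm = c["_dest"] if dispersed else c["birth_community"]
                gid = pick_group(comm)
                center = home + c["_shift"] if dispersed else home
                loc = center + rng.normal(0.0, cfg.calf_sigma, 2)
            if occ in c["_sorties"]:
                phi = rng.uniform(0, 2 * np.pi)
                loc = home + cfg.sortie_factor * r_thr * np.array(
                    [np.cos(phi), np.sin(phi)]
                )
            calf_rows.append((c, age, gid, loc))

        # detection
        for a in range(n_adults):
            if rng.random() < cfg.p_detect:
                records.append(
                    (
                        adult_ids[a], occ, year, season, secondary,
                        adult_group[a], adult_loc[a, 0], adult_loc[a, 1],
                        "F", adult_age0[a] + t,
                    )
                )
        for c, age, gid, loc in calf_rows:
            if rng.random() < cfg.p_detect:
                records.append(
                    (
                        c["id"], occ, year, season, secondary,
                        gid, loc[0], loc[1], c["sex"], age,
                    )
                )

    det = pd.DataFrame(
        records,
        columns=[
            "id", "occasion", "year", "season", "secondary",
            "group_id", "x_km", "y_km", "sex", "_true_age",
        ],
    )
    # heights from the shared growth curve, plus measurement noise
    h = np.empty(len(det))
    for sex in ("F", "M"):
        m = (det["sex"] == sex).to_numpy()
        h[m] = cfg.growth_curve.height_at(det.loc[m, "_true_age"].to_numpy(), sex)
    det["height_cm"] = h + rng.normal(0.0, cfg.height_noise_sd, len(det))
    det["age_class"] = assign_age_class(det["_true_age"].to_numpy())
    lon, lat = _tm_inverse(
        det["x_km"].to_numpy(), det["y_km"].to_numpy(),
        cfg.origin_lonlat[0], cfg.origin_lonlat[1],
    )
    det["lon"] = lon
    det["lat"] = lat
    det = det.drop(columns=["_true_age"])
    det["group_id"] = det["occasion"].astype(str) + "_" + det["group_id"].astype(str)

    truth = pd.DataFrame(
        [
            {
                "id": c["id"],
                "sex": c["sex"],
                "birth_community": c["birth_community"],
                "fate": c["fate"],
                "dispersal_age_months": c["dispersal_age_months"],
                "birth_month": c["birth_month"],
                "mother_id": c["mother_id"],
                "destination_community": c["_dest"],
                "sortie_occasions": ";".join(map(str, sorted(c["_sorties"]))),
            }
            for c in calves
        ]
    )
    adult_communities = dict(zip(adult_ids, adult_comm.tolist()))
    return SyntheticSociety(det, truth, covariates.reset_index(), adult_communities, cfg)


def simulate_multinomial_records(
    n: int,
    coefficients: dict,
    seed: int = 0,
    dist_town_range: tuple = (2.0, 30.0),
) -> pd.DataFrame:
    """Per-individual dispersal records drawn from a known multinomial logit.

    ``coefficients`` maps each non-reference class to a dict with keys
    ``intercept``, ``sexM`` and ``dist_town`` (missing keys are 0); the
    reference class is ``none``.  Used as the parameter-recovery oracle for
    the dispersal-type model.
    """
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    dist_town = rng.uniform(*dist_town_range, n)
    classes = [c for c in FATES if c != "none"]
    logits = np.zeros((n, len(FATES)))
    for j, cls in enumerate(classes, start=1):
        co = coefficients.get(cls, {})
        logits[:, j] = (
            co.get("intercept", 0.0)
            + co.get("sexM", 0.0) * (sex == "M")
            + co.get("dist_town", 0.0) * dist_town
        )
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    draws = np.array([rng.choice(len(FATES), p=row) for row in p])
    return pd.DataFrame(
        {
            "id": [f"R{i:04d}" for i in range(n)],
            "sex": sex,
            "dist_town": dist_town,
            "dispersal_class": [FATES[k] for k in draws],
        }
    )


def simulate_binary_records(
    n: int,
    intercept: float,
    beta_sex: float,
    community_sd: float,
    n_communities: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary dispersal outcomes from a random-intercept logistic model.

    Individuals are assigned round-robin to communities whose intercepts are
    N(0, community_sd^2); the linear predictor is
    ``intercept + beta_sex * [sex == M] + b_community``.
    """
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    comm = np.arange(n) % n_communities
    b = rng.normal(0.0, community_sd, n_communities) if community_sd > 0 else np.zeros(n_communities)
    eta = intercept + beta_sex * (sex == "M") + b[comm]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {"sex": sex, "community": comm, "dispersed": y}
    )
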