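"""Synthetic worlds: nation tables, language taxonomies and speaker shares.

The generator emulates the structure the analysis assumes for real
nation-level data: ~236 nations whose capitals cluster into six continental
caps on the sphere, a rooted multi-family language taxonomy (undated,
unresolved-style), mostly-monolingual speaker tables with occasional
multilingual nations, and ancestry-surrogate coordinates available for only
a subset of nations.  Families are anchored to home continents so that
region fixed effects and family fixed effects are meaningful (if coarse)
controls, as they are in the real world.

Everything is deterministic under the configured seed: the same
:class:`WorldConfig` always yields byte-identical CSV and Newick output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from galton.proximity import (
    LanguageTaxonomy,
    NationTable,
    ProximityMatrix,
    SpeakerTable,
    as_correlation,
    geographic_proximity_matrix,
    linguistic_proximity_matrix,
)

__all__ = ["WorldConfig", "World", "make_taxonomy", "make_world",
           "CONTINENTS", "LANGUAGE_FAMILIES"]

CONTINENTS = ["Africa", "Asia", "Europe", "North America", "Oceania",
              "South America"]

# rough continental anchor points (lat, lon) and relative nation counts
_CONTINENT_CENTERS = {
    "Africa": (5.0, 20.0),
    "Asia": (30.0, 90.0),
    "Europe": (50.0, 15.0),
    "North America": (40.0, -100.0),
    "Oceania": (-20.0, 150.0),
    "South America": (-15.0, -60.0),
}
_CONTINENT_WEIGHTS = {
    "Africa": 54, "Asia": 48, "Europe": 44, "North America": 23,
    "Oceania": 14, "South America": 12,
}

LANGUAGE_FAMILIES = [
    "Afro-Asiatic", "Atlantic-Congo", "Austroasiatic", "Austronesian",
    "Eskimo-Aleut", "Indo-European", "Japonic", "Kartvelian", "Koreanic",
    "Mande", "Mongolic-Khitan", "Nilotic", "Nuclear_Trans_New_Guinea",
    "Sino-Tibetan", "Tai-Kadai", "Tupian", "Turkic", "Uralic",
]

# home continent of each family, for the family->continent affinity
_FAMILY_HOMES = {
    "Afro-Asiatic": "Africa", "Atlantic-Congo": "Africa",
    "Austroasiatic": "Asia", "Austronesian": "Oceania",
    "Eskimo-Aleut": "North America", "Indo-European": "Europe",
    "Japonic": "Asia", "Kartvelian": "Asia", "Koreanic": "Asia",
    "Mande": "Africa", "Mongolic-Khitan": "Asia", "Nilotic": "Africa",
    "Nuclear_Trans_New_Guinea": "Oceania", "Sino-Tibetan": "Asia",
    "Tai-Kadai": "Asia", "Tupian": "South America", "Turkic": "Asia",
    "Uralic": "Europe",
}


@dataclass
class WorldConfig:
    """Configuration of the synthetic world.

    Parameters
    ----------
    n_nations : int
        Number of nations (default 236).
    n_families : int
        Number of top-level language families (default 18).
    n_continents : int
        Number of continental clusters (default 6, capped at ``n_nations``).
    clustering : float
        von-Mises--Fisher-style concentration of capitals around their
        continental anchor; larger is tighter.  The default 12 gives
        within-continent spreads of roughly 1500--2500 km, comparable to
        real continental capital scatter.  Capitals additionally bunch into
        denser sub-regional clusters within each continent (with
        concentration ``subcluster_factor`` times tighter), emulating dense
        neighbourhoods like Europe, the Caribbean or West Africa.
    subcluster_factor : float
        How much tighter sub-regional clusters are than their continent
        (default 12; ~500-km scatter within a sub-region).
    spread_prob : float
        Probability that a nation's majority language is one of a handful
        of widely spread ("colonial") languages rather than a language of a
        locally homed family (default 0.3, roughly the share of nations
        whose majority language is a global spread language).
    monolingual_prob : float
        Probability a nation is monolingual (default 0.7).
    ancestry_coverage : float
        Fraction of nations carrying ancestry-surrogate coordinates
        (default 177/236, the coverage of genetic-distance coordinates in
        real nation data).
    tips_per_family : tuple
        Inclusive range for the number of languages per family.
    seed : int
        RNG seed; the world is a pure function of the config.
    """

    n_nations: int = 236
    n_families: int = 18
    n_continents: int = 6
    clustering: float = 12.0
    subcluster_factor: float = 12.0
    spread_prob: float = 0.3
    monolingual_prob: float = 0.7
    ancestry_coverage: float = 177 / 236
    tips_per_family: tuple[int, int] = (3, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nations < 3:
            raise ValueError("n_nations must be >= 3")
        for name in ("monolingual_prob", "ancestry_coverage", "spread_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        if self.clustering <= 0:
            raise ValueError("clustering must be positive")


@dataclass
class World:
    """A nation table, taxonomy, speaker table and their proximity matrices.

    ``geo_P`` and ``ling_P`` are the raw proximity matrices; ``geo_C`` and
    ``ling_C`` the positive-definite correlation versions used as covariance
    sources in simulation and model fitting.
    """

    nations: NationTable
    taxonomy: LanguageTaxonomy
    speakers: SpeakerTable
    geo_P: ProximityMatrix
    ling_P: ProximityMatrix
    geo_C: ProximityMatrix = None
    ling_C: ProximityMatrix = None
    config: WorldConfig | None = None

    def __post_init__(self) -> None:
        if self.geo_C is None:
            self.geo_C = as_correlation(self.geo_P)
        if self.ling_C is None:
            self.ling_C = as_correlation(self.ling_P)

    @property
    def ids(self) -> list[str]:
        return self.nations.ids

    def sigma(self, source: str) -> ProximityMatrix:
        """The PD correlation matrix for a named autocorrelation source."""
        if source in ("geographic", "geo"):
            return self.geo_C
        if source in ("linguistic", "ling"):
            return self.ling_C
        if source == "identity":
            return ProximityMatrix(self.ids, np.eye(len(self.ids)))
        raise KeyError(f"unknown sigma source: {source!r}")

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.nations.to_csv(outdir / "nations.csv")
        self.speakers.to_csv(outdir / "speakers.csv")
        (outdir / "taxonomy.nwk").write_text(self.taxonomy.to_newick() + "\n")
        self.geo_P.to_csv(outdir / "geo_P.csv")
        self.ling_P.to_csv(outdir / "ling_P.csv")

    @classmethod
    def load(cls, indir) -> "World":
        """Load a world from a directory of nations.csv, speakers.csv, taxonomy.nwk.

        Proximity matrices are recomputed if geo_P.csv / ling_P.csv are absent.
        """
        indir = Path(indir)
        nations = NationTable.from_csv(indir / "nations.csv")
        speakers = SpeakerTable.from_csv(indir / "speakers.csv")
        taxonomy = LanguageTaxonomy.from_file(indir / "taxonomy.nwk")
        geo_path, ling_path = indir / "geo_P.csv", indir / "ling_P.csv"
        geo_P = (ProximityMatrix.from_csv(geo_path) if geo_path.exists()
                 else geographic_proximity_matrix(nations))
        ling_P = (ProximityMatrix.from_csv(ling_path) if ling_path.exists()
                  else linguistic_proximity_matrix(taxonomy, speakers))
        ling_P = ling_P.reindex(nations.ids)
        return cls(nations, taxonomy, speakers, geo_P.reindex(nations.ids), ling_P)


# ---------------------------------------------------------------------------
# taxonomy generation
# ---------------------------------------------------------------------------

def _yule_clade(labels: list[str], rng: np.random.Generator) -> str:
    """Random Yule-like topology over ``labels``, as a Newick fragment."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0]


def make_taxonomy(n_families: int = 18,
                  tips_per_family_range: tuple[int, int] = (3, 40),
                  seed: int = 0,
                  family_names: list[str] | None = None) -> LanguageTaxonomy:
    """Random rooted taxonomy: a root with ``n_families`` child clades.

    Each family clade is an independent random Yule-like tree whose tip
    count is drawn uniformly from ``tips_per_family_range``.  Tips are
    labelled ``<family>.L<index>``; cross-family proximity is exactly 0
    because the only shared ancestor of two families is the root.
    """
    lo, hi = tips_per_family_range
    if lo > hi or lo < 1:
        raise ValueError("tips_per_family_range must be (lo, hi) with 1 <= lo <= hi")
    if n_families < 2:
        raise ValueError("need at least 2 families")
    if family_names is None:
        family_names = (LANGUAGE_FAMILIES[:n_families]
                        if n_families <= len(LANGUAGE_FAMILIES)
                        else [f"Family{i:02d}" for i in range(n_families)])
    rng = np.random.default_rng(seed)
    clades = []
    for fam in family_names[:n_families]:
        k = int(rng.integers(lo, hi + 1))
        labels = [f"{fam}.L{i:03d}" for i in range(k)]
        clades.append(_yule_clade(labels, rng))
    return LanguageTaxonomy.from_newick("(" + ",".join(clades) + ");")


def family_of(language_id: str) -> str:
    """Family token of a synthetic tip label ``<family>.L<index>``."""
    return language_id.rsplit(".", 1)[0]


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

def _sample_cap(center_lat: float, center_lon: float, kappa: float, size: int,
                rng: np.random.Generator) -> np.ndarray:
    """von-Mises--Fisher sample of (lat, lon) around a center direction."""
    mu = _unit(center_lat, center_lon)
    # Wood's method for vMF on S^2: w has density prop to exp(kappa*w)
    u = rng.uniform(size=size)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    theta = rng.uniform(0.0, 2.0 * np.pi, size=size)
    # orthonormal basis around mu
    ref = np.array([0.0, 0.0, 1.0]) if abs(mu[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(mu, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - w ** 2, 0.0, None))
    pts = (w[:, None] * mu[None, :]
           + s[:, None] * (np.cos(theta)[:, None] * e1[None, :]
                           + np.sin(theta)[:, None] * e2[None, :]))
    lat = np.degrees(np.arcsin(np.clip(pts[:, 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    return np.column_stack([lat, lon])


def _unit(lat: float, lon: float) -> np.ndarray:
    phi, lam = math.radians(lat), math.radians(lon)
    return np.array([math.cos(phi) * math.cos(lam),
                     math.cos(phi) * math.sin(lam),
                     math.sin(phi)])


def _allocate(n: int, weights: list[float], minimum: int = 1) -> list[int]:
    """Largest-remainder allocation of n units to weighted groups."""
    w = np.asarray(weights, float)
    raw = n * w / w.sum()
    counts = np.maximum(np.floor(raw).astype(int), minimum)
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n:
        counts[np.argmax(raw - counts)] += 1
    return counts.tolist()


def _ancestry_embedding(taxonomy: LanguageTaxonomy, majority_langs: list[str],
                        rng: np.random.Generator) -> np.ndarray:
    """2-D classical-scaling embedding of linguistic distance (1 - s), plus noise.

    Emulates ancestry-surrogate coordinates: nations with related majority
    languages land near each other in the plane.
    """
    uniq = sorted(set(majority_langs))
    S = taxonomy.proximity_matrix(uniq)
    D2 = (1.0 - S) ** 2
    n = len(uniq)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, Q = np.linalg.eigh(B)
    top = np.argsort(w)[::-1][:2]
    coords = Q[:, top] * np.sqrt(np.clip(w[top], 0.0, None))
    pos = {lang: coords[i] for i, lang in enumerate(uniq)}
    xy = np.array([pos[l] for l in majority_langs])
    scale = max(np.abs(xy).max(), 1e-3)
    return xy + rng.normal(0.0, 0.05 * scale, size=xy.shape)


# relative use of the spread ("colonial") languages per continent, and how
# strongly each continent relies on spread languages at all
_SPREAD_WEIGHTS = {
    "Africa": {"ar": 0.45, "fr": 0.25, "en": 0.20, "pt": 0.10},
    "Asia": {"ar": 0.70, "en": 0.30},
    "Europe": {"en": 0.60, "fr": 0.40},
    "North America": {"es": 0.45, "en": 0.45, "fr": 0.10},
    "Oceania": {"en": 0.90, "fr": 0.10},
    "South America": {"es": 0.70, "pt": 0.25, "en": 0.05},
}
_SPREAD_FACTOR = {"Africa": 1.3, "Asia": 0.6, "Europe": 0.35,
                  "North America": 2.3, "Oceania": 1.8, "South America": 3.0}
# Europe's capitals are far denser than other continents'
_CONTINENT_TIGHTNESS = {"Europe": 3.0}


def _spread_languages(fam_tips: dict[str, list[str]]) -> dict[str, str]:
    """Pick the globally spread languages: 4 from one large family, 1 from another.

    Mirrors the real pattern where several colonial languages belong to a
    single family (Indo-European) plus one from Afro-Asiatic (Arabic).
    """
    fams = sorted(fam_tips, key=lambda f: -len(fam_tips[f]))
    ie = "Indo-European" if "Indo-European" in fam_tips else fams[0]
    aa = "Afro-Asiatic" if "Afro-Asiatic" in fam_tips and "Afro-Asiatic" != ie \
        else next(f for f in fams if f != ie)
    ie_tips = fam_tips[ie]
    slots = ["es", "en", "fr", "pt"]
    out = {s: ie_tips[i % len(ie_tips)] for i, s in enumerate(slots)}
    out["ar"] = fam_tips[aa][0]
    return out


def _continent_points(cont: str, cnt: int, cfg: WorldConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Two-level clustered capitals: continental cap + denser sub-regions."""
    lat0, lon0 = _CONTINENT_CENTERS[cont]
    kc = cfg.clustering * _CONTINENT_TIGHTNESS.get(cont, 1.0)
    n_sub = max(1, cnt // 6)
    sub_centers = _sample_cap(lat0, lon0, kc, n_sub, rng)
    pts = []
    for _ in range(cnt):
        if n_sub > 1 and rng.uniform() < 0.75:
            sc = sub_centers[rng.integers(n_sub)]
            pts.append(_sample_cap(sc[0], sc[1], kc * cfg.subcluster_factor,
                                   1, rng)[0])
        else:
            pts.append(_sample_cap(lat0, lon0, kc, 1, rng)[0])
    return np.asarray(pts)


def _enforce_separation(latlon: np.ndarray, rng: np.random.Generator,
                        min_km: float = 5.0) -> np.ndarray:
    """Jitter capitals so no two are closer than ``min_km`` (log-distance safety)."""
    from galton.proximity import pairwise_geodesic_km
    latlon = latlon.copy()
    for _ in range(100):
        D = pairwise_geodesic_km(latlon)
        np.fill_diagonal(D, np.inf)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        if D[i, j] >= min_km:
            break
        latlon[i, 0] = np.clip(latlon[i, 0] + rng.uniform(-0.2, 0.2), -90, 90)
        latlon[i, 1] += rng.uniform(-0.2, 0.2)
    return latlon


def make_world(cfg: WorldConfig) -> World:
    """Generate a full synthetic world from a :class:`WorldConfig`."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_nations
    n_cont = min(cfg.n_continents, len(CONTINENTS), n)
    continents = CONTINENTS[:n_cont]
    counts = _allocate(n, [_CONTINENT_WEIGHTS[c] for c in continents])

    taxonomy = make_taxonomy(cfg.n_families, cfg.tips_per_family, seed=cfg.seed,
                             family_names=None)
    fam_names = sorted({family_of(t) for t in taxonomy.tip_labels})
    fam_tips = {f: sorted(t for t in taxonomy.tip_labels if family_of(t) == f)
                for f in fam_names}
    homes = {f: _FAMILY_HOMES.get(f, continents[i % n_cont])
             for i, f in enumerate(fam_names)}
    local_fams = {c: [f for f in fam_names if homes[f] == c] for c in continents}
    # every continent needs at least one local family
    for i, c in enumerate(continents):
        if not local_fams[c]:
            local_fams[c] = [fam_names[i % len(fam_names)]]
    spread = _spread_languages(fam_tips)

    all_pts = [_continent_points(cont, cnt, cfg, rng)
               for cont, cnt in zip(continents, counts)]
    flat = _enforce_separation(np.concatenate(all_pts), rng)
    splits = np.cumsum(counts)[:-1]
    all_pts = np.split(flat, splits)

    rows = []
    speaker_rows = []
    k = 0
    for cont, cnt, pts in zip(continents, counts, all_pts):
        sw = _SPREAD_WEIGHTS.get(cont)
        p_spread = (min(cfg.spread_prob * _SPREAD_FACTOR.get(cont, 1.0), 0.95)
                    if sw else 0.0)
        for p in pts:
            nid = f"N{k:03d}"
            k += 1
            if sw and rng.uniform() < p_spread:
                # a widely spread language is the majority language
                slots = sorted(sw)
                wts = np.array([sw[s] for s in slots])
                major = spread[slots[rng.choice(len(slots), p=wts / wts.sum())]]
                fam = family_of(major)
            else:
                # majority language from a family homed on this continent
                if rng.uniform() < 0.85:
                    fam = local_fams[cont][rng.integers(len(local_fams[cont]))]
                else:
                    fam = fam_names[rng.integers(len(fam_names))]
                tips = fam_tips[fam]
                major = tips[rng.integers(len(tips))]
            tips = fam_tips[fam]
            langs, shares = [major], [1.0]
            if rng.uniform() >= cfg.monolingual_prob:
                n_extra = int(rng.integers(1, 3))
                pool = [t for t in tips if t != major] or taxonomy.tip_labels
                major_share = rng.uniform(0.55, 0.9)
                rest = 1.0 - major_share
                props = rng.dirichlet(np.ones(n_extra))
                shares = [major_share]
                langs = [major]
                for i in range(n_extra):
                    # minority languages: same family or anywhere
                    if pool and rng.uniform() < 0.7:
                        cand = pool[rng.integers(len(pool))]
                    else:
                        cand = taxonomy.tip_labels[rng.integers(len(taxonomy.tip_labels))]
                    if cand in langs:
                        continue
                    langs.append(cand)
                    shares.append(rest * props[i])
                tot = sum(shares)
                shares = [s / tot for s in shares]
            rows.append({"nation_id": nid, "capital_lat": round(p[0], 6),
                         "capital_lon": round(p[1], 6), "continent": cont,
                         "majority_family": fam})
            for lg, sh in zip(langs, shares):
                speaker_rows.append({"nation_id": nid, "language_id": lg,
                                     "share": round(sh, 9)})

    nations_df = pd.DataFrame(rows)
    sp_df = pd.DataFrame(speaker_rows)
    majors = (sp_df.sort_values(["nation_id", "share"], ascending=[True, False])
              .groupby("nation_id").first()["language_id"])
    majority_langs = [majors[r["nation_id"]] for r in rows]

    xy = _ancestry_embedding(taxonomy, majority_langs, rng)
    n_cov = math.ceil(cfg.ancestry_coverage * n)
    covered = rng.choice(n, size=n_cov, replace=False)
    ax = np.full(n, np.nan)
    ay = np.full(n, np.nan)
    ax[covered] = np.round(xy[covered, 0], 6)
    ay[covered] = np.round(xy[covered, 1], 6)
    nations_df["ancestry_x"] = ax
    nations_df["ancestry_y"] = ay

    nations = NationTable(nations_df)
    speakers = SpeakerTable(sp_df)
    geo_P = geographic_proximity_matrix(nations)
    ling_P = linguistic_proximity_matrix(taxonomy, speakers).reindex(nations.ids)
    return World(nations, taxonomy, speakers, geo_P, ling_P, config=cfg)
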