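"""Geographic and linguistic proximity matrices between nations.

Geographic proximity is one minus the min–max-scaled log geodesic distance
between capital cities, so the closest pair of nations scores 1 and the most
distant pair scores 0.  Linguistic proximity between two nations is the
speaker-share-weighted average of pairwise language proximities

    w_lm = sum_j sum_k  p_lj * p_mk * s_jk,

where ``p_lj`` is the fraction of nation *l*'s population speaking language
*j* and the language proximity ``s_jk = (n_r - n_i) / n_r`` measures the
relative depth of the most recent common ancestor *i* of *j* and *k* in a
rooted (undated, possibly unresolved) language taxonomy: ``n_r`` is the
maximum root-to-tip path length in edges, ``n_i`` the maximum path length
from *i* down to any of its descendant tips.  ``s = 1`` for identical
languages and 0 for languages whose only common ancestor is the root.

Either matrix can be repaired into a valid correlation matrix (positive
definite, unit diagonal) with :func:`as_correlation` before use as a
covariance structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

__all__ = [
    "NationTable", "LanguageTaxonomy", "SpeakerTable", "ProximityMatrix",
    "ProximityRepairWarning", "geodesic_distance_km", "pairwise_geodesic_km",
    "geographic_proximity_matrix", "language_pair_proximity",
    "linguistic_proximity_matrix", "as_correlation",
]


class ProximityRepairWarning(UserWarning):
    """Positive-definiteness repair moved a matrix entry noticeably."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

NATION_COLUMNS = ["nation_id", "capital_lat", "capital_lon", "continent",
                  "majority_family", "ancestry_x", "ancestry_y"]


@dataclass
class NationTable:
    """Table of nations: id, capital coordinates, region, majority language family.

    ``ancestry_x``/``ancestry_y`` are optional unitless surrogate coordinates
    for cultural (ancestry-based) distances; they may be missing per nation.
    Longitudes are normalised into (-180, 180] on construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in NATION_COLUMNS[:5] if c not in df.columns]
        if missing:
            raise ValueError(f"NationTable missing columns: {missing}")
        for c in ("ancestry_x", "ancestry_y"):
            if c not in df.columns:
                df[c] = np.nan
        df["nation_id"] = df["nation_id"].astype(str)
        if df["nation_id"].duplicated().any():
            dup = df.loc[df["nation_id"].duplicated(), "nation_id"].tolist()
            raise ValueError(f"duplicate nation ids: {dup}")
        lat = df["capital_lat"].to_numpy(float)
        lon = df["capital_lon"].to_numpy(float)
        if np.isnan(lat).any() or np.isnan(lon).any():
            raise ValueError("missing capital coordinates")
        if (np.abs(lat) > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        # normalise longitude into (-180, 180]
        lon = ((lon + 180.0) % 360.0) - 180.0
        lon[lon == -180.0] = 180.0
        df["capital_lon"] = lon
        self.data = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.data["nation_id"].tolist()

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def latlon(self) -> np.ndarray:
        """(n, 2) array of (lat, lon) in degrees."""
        return self.data[["capital_lat", "capital_lon"]].to_numpy(float)

    def ancestry_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (mask of nations with ancestry coordinates, their (k, 2) coords)."""
        xy = self.data[["ancestry_x", "ancestry_y"]].to_numpy(float)
        mask = ~np.isnan(xy).any(axis=1)
        return mask, xy[mask]

    @classmethod
    def from_csv(cls, path) -> "NationTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class SpeakerTable:
    """Rows of (nation_id, language_id, share), share = population fraction in (0, 1]."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        need = ["nation_id", "language_id", "share"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValueError(f"SpeakerTable missing columns: {missing}")
        df["nation_id"] = df["nation_id"].astype(str)
        df["language_id"] = df["language_id"].astype(str)
        share = df["share"].to_numpy(float)
        if np.isnan(share).any() or (share <= 0).any() or (share > 1).any():
            raise ValueError("speaker shares must lie in (0, 1]")
        totals = df.groupby("nation_id")["share"].sum()
        bad = totals[totals > 1 + 1e-9]
        if len(bad):
            raise ValueError(f"speaker shares exceed 1 for: {bad.index.tolist()}")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "SpeakerTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


class LanguageTaxonomy:
    """A rooted language taxonomy; branch lengths, if present, are ignored.

    Only the tree topology matters: language proximity is defined through
    node depths counted in edges.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        self.tree = tree
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels in taxonomy")
        self.tip_labels = tips
        self._tip_set = set(tips)
        # edge-count depth of every node from the root
        self._depth: dict[int, int] = {}
        for nd in tree.preorder_node_iter():
            self._depth[id(nd)] = 0 if nd.parent_node is None else self._depth[id(nd.parent_node)] + 1
        self.max_depth = max(self._depth[id(lf)] for lf in tree.leaf_node_iter())
        if self.max_depth == 0:
            raise ValueError("taxonomy has a single tip; proximity undefined")

    @classmethod
    def from_newick(cls, newick: str) -> "LanguageTaxonomy":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "LanguageTaxonomy":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   suppress_edge_lengths=True,
                                   unquoted_underscores=True).strip()

    def __contains__(self, label: str) -> bool:
        return label in self._tip_set

    # -- proximity ----------------------------------------------------------

    def pair_proximity(self, j: str, k: str) -> float:
        """Proximity s_jk = (n_r - n_i)/n_r for two tip labels."""
        for lab in (j, k):
            if lab not in self._tip_set:
                raise KeyError(f"unknown tip label: {lab!r}")
        if j == k:
            return 1.0
        taxa = [t for t in self.tree.taxon_namespace if t.label in (j, k)]
        mrca = self.tree.mrca(taxa=taxa)
        n_i = max(self._depth[id(lf)] for lf in mrca.leaf_iter()) - self._depth[id(mrca)]
        return (self.max_depth - n_i) / self.max_depth

    def proximity_matrix(self, labels: list[str]) -> np.ndarray:
        """Pairwise s matrix for the given tip labels (one postorder pass).

        The MRCA of every tip pair is the node at which their lineages merge,
        so cross-pairs between the child subtrees of each internal node are
        assigned that node's proximity.
        """
        for lab in labels:
            if lab not in self._tip_set:
                raise KeyError(f"unknown tip label: {lab!r}")
        idx = {lab: i for i, lab in enumerate(labels)}
        m = len(labels)
        S = np.eye(m)
        n_r = self.max_depth
        # subtree info: (deepest-tip depth, indices of requested tips)
        info: dict[int, tuple[int, list[int]]] = {}
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                lab = nd.taxon.label
                members = [idx[lab]] if lab in idx else []
                info[id(nd)] = (self._depth[id(nd)], members)
                continue
            child_infos = [info.pop(id(ch)) for ch in nd.child_nodes()]
            deepest = max(d for d, _ in child_infos)
            n_i = deepest - self._depth[id(nd)]
            s = (n_r - n_i) / n_r
            merged: list[int] = []
            for _, mem in child_infos:
                for a in merged:
                    for b in mem:
                        S[a, b] = S[b, a] = s
                merged.extend(mem)
            info[id(nd)] = (deepest, merged)
        return S


@dataclass
class ProximityMatrix:
    """Labelled symmetric matrix with entries in [0, 1].

    ``unit_diagonal`` records whether the diagonal was forced to 1 (the
    convention for use as a correlation/covariance source); ``raw_diagonal``
    keeps the pre-forcing diagonal for inspection.  ``pd_repaired`` is set by
    :func:`as_correlation` when eigenvalue flooring changed the matrix;
    ``frobenius_delta`` is the Frobenius distance moved by the repair.
    """

    ids: list[str]
    values: np.ndarray
    unit_diagonal: bool = True
    pd_repaired: bool = False
    raw_diagonal: np.ndarray | None = None
    frobenius_delta: float = 0.0

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        V = np.asarray(self.values, float)
        if V.ndim != 2 or V.shape[0] != V.shape[1] or V.shape[0] != len(self.ids):
            raise ValueError("values must be square and match ids")
        if not np.allclose(V, V.T, atol=1e-12, rtol=0.0):
            raise ValueError("matrix not symmetric to 1e-12")
        if V.min() < -1e-12 or V.max() > 1 + 1e-12:
            raise ValueError("entries outside [0, 1]")
        V = np.clip((V + V.T) / 2.0, 0.0, 1.0)
        if self.unit_diagonal:
            np.fill_diagonal(V, 1.0)
        self.values = V

    @property
    def n(self) -> int:
        return len(self.ids)

    def reindex(self, ids: list[str]) -> "ProximityMatrix":
        """Return the submatrix for ``ids`` in the given order."""
        pos = {lab: i for i, lab in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids not in matrix: {missing}")
        take = [pos[i] for i in ids]
        raw = self.raw_diagonal[take] if self.raw_diagonal is not None else None
        return ProximityMatrix(list(ids), self.values[np.ix_(take, take)],
                               unit_diagonal=self.unit_diagonal,
                               pd_repaired=self.pd_repaired, raw_diagonal=raw)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, unit_diagonal: bool = True) -> "ProximityMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("matrix CSV row/column ids disagree")
        return cls(list(df.index.astype(str)), df.to_numpy(float),
                   unit_diagonal=unit_diagonal)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _check_coords(lat, lon) -> None:
    lat, lon = np.asarray(lat, float), np.asarray(lon, float)
    if (np.abs(lat) > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (lon <= -180 - 1e-9).any() or (lon > 180 + 1e-9).any():
        raise ValueError("longitude outside (-180, 180]")


def geodesic_distance_km(lat1, lon1, lat2, lon2) -> float | np.ndarray:
    """Great-circle (haversine) distance in km on a sphere of mean Earth radius."""
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_geodesic_km(latlon: np.ndarray) -> np.ndarray:
    """Symmetric matrix of great-circle distances for (n, 2) (lat, lon) degrees."""
    latlon = np.asarray(latlon, float)
    lat = latlon[:, 0][:, None]
    lon = latlon[:, 1][:, None]
    D = geodesic_distance_km(lat, lon, lat.T, lon.T)
    np.fill_diagonal(D, 0.0)
    return D


def geographic_proximity_matrix(nations: NationTable) -> ProximityMatrix:
    """Proximity = 1 − min–max-scaled log geodesic distance between capitals.

    The scaling runs over off-diagonal pairs only; the diagonal is fixed at 1.
    The nearest pair of distinct nations gets proximity 1 and the most
    distant pair gets 0.
    """
    if nations.n < 3:
        raise ValueError("need at least 3 nations")
    D = pairwise_geodesic_km(nations.latlon)
    off = ~np.eye(nations.n, dtype=bool)
    if (D[off] <= 0).any():
        i, j = np.argwhere((D <= 0) & off)[0]
        raise ValueError(
            f"duplicate capital coordinates for {nations.ids[i]!r} and "
            f"{nations.ids[j]!r}: log distance undefined")
    logd = np.log(D, out=np.zeros_like(D), where=off)
    lo, hi = logd[off].min(), logd[off].max()
    if hi - lo < 1e-12:
        raise ValueError("all pairwise distances equal: min-max scaling degenerate")
    P = np.zeros_like(D)
    P[off] = 1.0 - (logd[off] - lo) / (hi - lo)
    np.fill_diagonal(P, 1.0)
    return ProximityMatrix(nations.ids, P, unit_diagonal=True)


def language_pair_proximity(tree: LanguageTaxonomy, j: str, k: str) -> float:
    """Relative MRCA depth s_jk = (n_r − n_i)/n_r for tips ``j`` and ``k``."""
    return tree.pair_proximity(j, k)


def linguistic_proximity_matrix(tree: LanguageTaxonomy, speakers: SpeakerTable,
                                threshold: float = 0.001,
                                renormalize: bool = False) -> ProximityMatrix:
    """Speaker-weighted linguistic proximity w_lm = ΣΣ p_lj p_mk s_jk.

    Languages spoken by less than ``threshold`` (default 1 permille) of a
    nation's population are dropped before the double sum.  Shares are not
    renormalised after thresholding unless ``renormalize=True``; with the raw
    shares, totals below 1 simply shrink ``w``.  The raw diagonal (which can
    be < 1 for multilingual nations) is recorded on the result, and the
    stored diagonal is forced to 1 so the matrix can serve as a correlation
    source.
    """
    df = speakers.data
    kept = df[df["share"] >= threshold]
    all_nations = df["nation_id"].unique()
    empty = sorted(set(all_nations) - set(kept["nation_id"].unique()))
    if empty:
        raise ValueError(f"no language above threshold {threshold} for: {empty}")
    unknown = sorted(set(kept["language_id"]) - set(tree.tip_labels))
    if unknown:
        raise KeyError(f"speaker languages not in taxonomy: {unknown}")
    langs = sorted(kept["language_id"].unique())
    S = tree.proximity_matrix(langs)
    # nation x language share matrix
    P = (kept.pivot_table(index="nation_id", columns="language_id",
                          values="share", aggfunc="sum", fill_value=0.0)
         .reindex(columns=langs, fill_value=0.0))
    if renormalize:
        P = P.div(P.sum(axis=1), axis=0)
    ids = list(P.index)
    Pm = P.to_numpy(float)
    W = Pm @ S @ Pm.T
    W = np.clip((W + W.T) / 2.0, 0.0, 1.0)
    raw_diag = np.diag(W).copy()
    return ProximityMatrix(ids, W, unit_diagonal=True, raw_diagonal=raw_diag)


def as_correlation(P: ProximityMatrix, eig_floor: float = 1e-6,
                   strict: bool = False, max_entry_change: float = 0.05) -> ProximityMatrix:
    """Repair a proximity matrix into a positive-definite correlation matrix.

    Eigenvalues below ``eig_floor`` are raised to it and the diagonal is
    rescaled back to 1; the two steps are alternated until the smallest
    eigenvalue respects the floor.  If any entry moves by more than
    ``max_entry_change`` a warning is issued (an error in strict mode): the
    input was far from a valid correlation structure.
    """
    A = P.values.copy()
    np.fill_diagonal(A, 1.0)
    repaired = False
    for _ in range(100):
        A = np.clip((A + A.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(A, 1.0)
        w, Q = np.linalg.eigh(A)
        if w.min() >= eig_floor:
            break
        repaired = True
        # floor with headroom: the diagonal rescale shaves the smallest
        # eigenvalue slightly, so flooring exactly at eig_floor never converges
        A = (Q * np.maximum(w, 1.1 * eig_floor)) @ Q.T
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
    else:
        raise np.linalg.LinAlgError("positive-definiteness repair did not converge")
    delta = float(np.linalg.norm(A - P.values))
    max_change = float(np.abs(A - P.values).max())
    if repaired and max_change > max_entry_change:
        msg = (f"PD repair moved an entry by {max_change:.4f} "
               f"(> {max_entry_change})")
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, ProximityRepairWarning, stacklevel=2)
    return ProximityMatrix(P.ids, A, unit_diagonal=True, pd_repaired=repaired,
                           raw_diagonal=P.raw_diagonal, frobenius_delta=delta)
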