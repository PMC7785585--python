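"""Environmental correlation screens and distance-matrix permutation tests.

ANOSIM, simple and partial Mantel tests are implemented with explicit
seeded permutation engines so whole-pipeline runs are reproducible.
Permutation p-values carry the +1 correction,
``p = (#extreme + 1) / (n_perm + 1)``, and are therefore never below
``1 / (n_perm + 1)``.  Mantel tests are one-tailed for positive association
by default (the ecological convention for distance-decay questions);
two-tailed is available via ``alternative``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ._util import logger
from .data_model import OtuTable

__all__ = [
    "spearman_screen",
    "env_distance",
    "geo_distance",
    "anosim",
    "simper",
    "mantel",
    "partial_mantel",
    "distance_decay",
    "MantelResult",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    alternative: str
    controlled: str | None = None


def spearman_screen(
    responses: pd.DataFrame, env: pd.DataFrame, variables: list[str]
) -> pd.DataFrame:
    """Spearman rank correlation of each response column with each variable.

    ``responses`` is indexed by sample_id (alpha-diversity indices or taxon
    group relative abundances); ``env`` must contain ``sample_id`` plus the
    requested variable columns.  Ties get midranks; two-sided p-values come
    from the t approximation.  Constant inputs yield a flagged missing row.
    """
    env_idx = env.set_index("sample_id").loc[responses.index]
    rows = []
    for var in variables:
        x = pd.to_numeric(env_idx[var]).to_numpy(dtype=float)
        for resp in responses.columns:
            y = responses[resp].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 5:
                raise ValueError(f"fewer than 5 paired observations for {var!r}")
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rows.append(
                    {"variable": var, "response": resp, "spearman_r": np.nan,
                     "p_value": np.nan, "n": int(ok.sum()), "flag": "constant"}
                )
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            rows.append(
                {"variable": var, "response": resp, "spearman_r": float(r),
                 "p_value": float(p), "n": int(ok.sum()), "flag": ""}
            )
    return pd.DataFrame(rows)


def env_distance(meta: pd.DataFrame, variables: list[str]) -> DistanceMatrix:
    """Euclidean distance on z-scored environmental variables.

    Zero-variance variables are dropped with a warning; at least two
    variables must be requested.
    """
    if len(variables) < 2:
        raise ValueError("need at least two environmental variables")
    ids = meta["sample_id"].astype(str).tolist()
    x = meta[variables].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        logger.warning("env_distance dropped zero-variance variable(s): %s", dropped)
    if not keep.any():
        raise ValueError("all environmental variables have zero variance")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    return DistanceMatrix(squareform(pdist(z)), ids=ids)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geo_distance(meta: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle (haversine) distances between samples, in km."""
    ids = meta["sample_id"].astype(str).tolist()
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(d, ids=ids)


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    return float((ranks[~within].mean() - ranks[within].mean()) / denom)


def anosim(
    dm: DistanceMatrix, groups: list[str], n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with a label-permutation p-value.  Each group needs >= 2 members.
    """
    labels = np.asarray(groups)
    n = len(dm.ids)
    if labels.shape[0] != n:
        raise ValueError("group labels must match distance matrix ids")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    condensed = squareform(np.asarray(dm.data), checks=False)
    ranks = stats.rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0
    within = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, within, denom)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm[iu] == perm[ju], denom) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p


def simper(
    table: OtuTable, groups: list[str], tax=None, rank: int | None = None
) -> dict[tuple[str, str], pd.DataFrame]:
    """Similarity-percentage decomposition of between-group Bray-Curtis.

    For each group pair, the mean over between-group sample pairs of each
    OTU's Bray-Curtis term ``|x_i - y_i| / sum(x + y)``.  Contributions sum
    exactly to the mean between-group Bray-Curtis dissimilarity.  When a
    taxonomy and rank are given, a ``taxon_group`` column supports
    aggregated percent contributions per lineage.
    """
    labels = np.asarray(groups)
    if labels.shape[0] != table.n_samples:
        raise ValueError("group labels must match sample count")
    uniq = [u for u in pd.unique(labels)]
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    for u in uniq:
        if (labels == u).sum() == 0:
            raise ValueError(f"empty group {u!r}")
    x = table.counts.astype(float)
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for a_i in range(len(uniq) - 1):
        for b_i in range(a_i + 1, len(uniq)):
            a, b = uniq[a_i], uniq[b_i]
            ia = np.where(labels == a)[0]
            ib = np.where(labels == b)[0]
            contrib = np.zeros(table.n_otus)
            n_pairs = 0
            for i in ia:
                for j in ib:
                    tot = x[i].sum() + x[j].sum()
                    if tot == 0:
                        continue
                    contrib += np.abs(x[i] - x[j]) / tot
                    n_pairs += 1
            if n_pairs == 0:
                raise ValueError(f"no usable sample pairs between {a!r} and {b!r}")
            contrib /= n_pairs
            total = contrib.sum()
            df = pd.DataFrame(
                {
                    "otu_id": table.otu_ids,
                    "contribution": contrib,
                    "percent": 100.0 * contrib / total if total > 0 else 0.0,
                }
            ).sort_values("contribution", ascending=False, kind="mergesort")
            df["cumulative_percent"] = df["percent"].cumsum()
            if tax is not None and rank is not None:
                df["taxon_group"] = [tax.rank_label(o, rank) for o in df["otu_id"]]
            results[(a, b)] = df.reset_index(drop=True)
    return results


def _triangle(dm: DistanceMatrix) -> np.ndarray:
    return squareform(np.asarray(dm.data), checks=False)


def _check_match(*dms: DistanceMatrix) -> None:
    ids = dms[0].ids
    for dm in dms[1:]:
        if dm.ids != ids:
            raise ValueError("distance matrices must share identical id order")


def mantel(
    dmA: DistanceMatrix,
    dmB: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower-triangle vectors; the p-value
    permutes rows/columns of ``dmA`` jointly.
    """
    _check_match(dmA, dmB)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    va, vb = _triangle(dmA), _triangle(dmB)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant distance matrix; Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    a = np.asarray(dmA.data)
    n = a.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = squareform(a[np.ix_(perm, perm)], checks=False)
        r_null = float(np.corrcoef(vp, vb)[0, 1])
        if alternative == "greater":
            count += r_null >= r_obs
        else:
            count += abs(r_null) >= abs(r_obs)
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, alternative)


def _residual_matrix(dm: DistanceMatrix, control: DistanceMatrix) -> np.ndarray:
    """Entrywise OLS residuals of one distance matrix on another, kept square."""
    v = _triangle(dm)
    c = _triangle(control)
    if np.ptp(c) == 0:
        slope, intercept = 0.0, v.mean()
    else:
        slope, intercept = np.polyfit(c, v, 1)
    resid = v - (slope * c + intercept)
    return squareform(resid, checks=False)


def partial_mantel(
    dmA: DistanceMatrix,
    dmB: DistanceMatrix,
    dmC: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel: correlation of A and B after removing C from both.

    Residual-permutation test: both matrices are residualized on the
    control, then the residual matrix of A is row/column permuted.
    """
    _check_match(dmA, dmB, dmC)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    ra = _residual_matrix(dmA, dmC)
    rb = _residual_matrix(dmB, dmC)
    va, vb = squareform(ra, checks=False), squareform(rb, checks=False)
    # a matrix explained entirely by the control leaves only rounding noise:
    # there is no residual signal to correlate
    tol_a = 1e-12 * max(np.ptp(_triangle(dmA)), 1.0)
    tol_b = 1e-12 * max(np.ptp(_triangle(dmB)), 1.0)
    if np.ptp(va) <= tol_a or np.ptp(vb) <= tol_b:
        return MantelResult(0.0, 1.0, n_perm, alternative, controlled="control")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    n = ra.shape[0]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = squareform(ra[np.ix_(perm, perm)], checks=False)
        r_null = float(np.corrcoef(vp, vb)[0, 1])
        if alternative == "greater":
            count += r_null >= r_obs
        else:
            count += abs(r_null) >= abs(r_obs)
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, alternative, controlled="control")


def distance_decay(
    dm_comm: DistanceMatrix, dm_geo: DistanceMatrix
) -> tuple[float, float, float]:
    """OLS of community similarity (1 - dissimilarity) on geographic distance.

    Returns (slope, intercept, Pearson r) over the lower triangle.
    """
    _check_match(dm_comm, dm_geo)
    sim = 1.0 - _triangle(dm_comm)
    geo = _triangle(dm_geo)
    if sim.size < 3:
        raise ValueError("need at least three sample pairs")
    if np.ptp(geo) == 0:
        raise ValueError("zero geographic variance")
    res = stats.linregress(geo, sim)
    return float(res.slope), float(res.intercept), float(res.rvalue)
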