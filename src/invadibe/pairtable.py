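"""Build the pairwise modelling table: one row per unordered sample pair.

Each row carries the pairwise F_ST response (clamped into [0,1)), the
great-circle distance between the two sampling points, absolute differences
in distance to the two putative introduction reference points, absolute
environmental differences (delta_*) and the cluster pair type
(P1P1 / P2P2 / P1P2, with the small P3 sub-cluster merged into P1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import ENV_COLUMNS, SampleMetadata

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

DELTA_COLUMNS = tuple(f"delta_{c}" for c in ENV_COLUMNS)
SPATIAL_COLUMNS = ("dist_geo_km", "delta_dist_km_CT", "delta_dist_km_SB")


@dataclass(frozen=True)
class ReferencePoints:
    """Putative introduction reference points (lat, lon), overridable."""
    cape_town: tuple[float, float] = (-33.9875, 18.4327)
    stellenbosch: tuple[float, float] = (-33.9463, 18.8717)


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points (WGS84
    mean radius)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def _merged_cluster(c: str) -> str:
    # the P3 sub-cluster is treated as part of P1 ("P1+3") throughout
    return "P1" if c in ("P1", "P3") else c


def clus_type(ca: str, cb: str) -> str:
    a, b = sorted((_merged_cluster(ca), _merged_cluster(cb)))
    return f"{a}{b}" if a != b else f"{a}{a}"


def build_pair_table(meta: Sequence[SampleMetadata], fst_matrix: np.ndarray,
                     fst_ids: Sequence[str] | None = None,
                     refs: ReferencePoints = ReferencePoints()) -> pd.DataFrame:
    """Assemble the C(n,2)-row pair table.

    ``fst_matrix`` is the symmetric per-individual F_ST matrix, aligned to
    ``fst_ids`` (defaults to the metadata order). Negative F_ST values are
    clamped to 0 and values >=1 to 1-1e-8 so the logit-link response stays in
    range. Rows whose pair lacks an environmental covariate are dropped with
    a warning.
    """
    ids = [m.sample_id for m in meta]
    if fst_ids is None:
        fst_ids = ids
    order = {s: k for k, s in enumerate(fst_ids)}
    missing = [s for s in ids if s not in order]
    if missing:
        raise ValueError(f"fst matrix does not cover samples: {missing}")
    by_id = {m.sample_id: m for m in meta}
    d_ct = {s: haversine_km((by_id[s].lat, by_id[s].lon), refs.cape_town)
            for s in ids}
    d_sb = {s: haversine_km((by_id[s].lat, by_id[s].lon), refs.stellenbosch)
            for s in ids}
    rows, dropped = [], 0
    for sa, sb in combinations(ids, 2):
        ma, mb = by_id[sa], by_id[sb]
        env_a, env_b = ma.env.as_dict(), mb.env.as_dict()
        if any(not np.isfinite(env_a[c]) or not np.isfinite(env_b[c])
               for c in ENV_COLUMNS):
            dropped += 1
            continue
        fst = float(fst_matrix[order[sa], order[sb]])
        fst = min(max(fst, 0.0), 1.0 - 1e-8)
        row = {
            "id_a": sa, "id_b": sb, "fst": fst,
            "dist_geo_km": haversine_km((ma.lat, ma.lon), (mb.lat, mb.lon)),
            "delta_dist_km_CT": abs(d_ct[sa] - d_ct[sb]),
            "delta_dist_km_SB": abs(d_sb[sa] - d_sb[sb]),
            "clus_type": clus_type(ma.cluster, mb.cluster),
        }
        for c in ENV_COLUMNS:
            row[f"delta_{c}"] = abs(env_a[c] - env_b[c])
        rows.append(row)
    if dropped:
        warnings.warn(f"dropped {dropped} pair rows with missing env covariates")
    table = pd.DataFrame(rows)
    logger.info("pair table: %d rows from %d samples (%d dropped)",
                len(table), len(ids), dropped)
    return table


def screen_predictors(table: pd.DataFrame,
                      predictors: Sequence[str] | None = None,
                      r_threshold: float = 0.75):
    """Greedy collinearity screen on numeric predictors.

    While any |Pearson r| exceeds ``r_threshold``, the predictor with the
    highest mean absolute correlation to the others is dropped (ties broken
    by the fixed input order). Returns (retained list, correlation matrix of
    the original predictors).
    """
    if predictors is None:
        predictors = [c for c in table.columns
                      if c not in ("id_a", "id_b", "fst", "clus_type")]
    if len(table) < 3:
        raise ValueError("need >=3 rows to screen predictors")
    corr = table[list(predictors)].corr()
    keep = list(predictors)
    while len(keep) > 1:
        sub = corr.loc[keep, keep].abs()
        np.fill_diagonal(sub.values, 0.0)
        if (sub.values > r_threshold).sum() == 0:
            break
        mean_abs = sub.mean(axis=1)
        offender_rows = sub.max(axis=1) > r_threshold
        # drop, among predictors involved in a violation, the most correlated one
        cand = mean_abs[offender_rows]
        drop = cand.index[int(np.argmax(cand.values))]
        keep.remove(drop)
    return keep, corr
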