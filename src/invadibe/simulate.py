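"""Synthetic dual-introduction datasets for end-to-end pipeline testing.

The generator emulates the statistical structure the downstream analysis
assumes: two divergent founder lineages (Balding-Nichols allele-frequency
model indexed by a target F_ST), within-lineage isolation by distance
(deme allele frequencies from a logit-scale Gaussian process with
exponential spatial covariance), environmental covariates correlated with
lineage (isolation by environment), mito-nuclear linkage with a small
discordance rate, and per-genotype missingness. Coordinates are planar km
in a 150 x 100 km window converted to pseudo lat/lon around (-34, 19) so
downstream great-circle code runs unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit, logit

from .genotype_io import EnvRecord, GenotypeMatrix, SampleMetadata

# per-covariate (baseline, lineage-0 shift, east-west gradient per km, noise sd)
_ENV_MODEL: Mapping[str, tuple[float, float, float, float]] = {
    "rmean":    (900.0, -200.0, -1.0,    60.0),   # mm; lineage 0 drier, drier inland
    "tmean":    (16.5,     0.5,  0.008,   0.4),   # degC
    "tminave":  (10.0,     0.5,  0.005,   0.4),
    "tmaxave":  (23.0,     1.5,  0.010,   0.4),
    "tmaxsum":  (27.0,     2.5,  0.012,   0.5),   # lineage 0 hotter summers
    "tminwint": (6.0,      0.5,  0.004,   0.4),
    "ndmi16":   (0.25,   -0.08, -5e-4,    0.03),  # moisture index, unitless
    "ndmi19":   (0.15,   -0.05, -5e-4,    0.03),
}

_WINDOW_KM = (150.0, 100.0)
_ORIGIN = (-34.0, 19.0)
_KM_PER_DEG = 111.32


@dataclass(frozen=True)
class SimParams:
    """Generator knobs; defaults mirror the study conditions (31 + 16
    colonies, ~0.15 between-lineage divergence, ~15% mito-nuclear
    discordance)."""
    n_per_cluster: tuple[int, int] = (31, 16)
    n_loci: int = 2000
    f_div: float = 0.15           # target between-lineage F_ST
    f_deme: float = 0.02          # within-lineage deme drift (logit-GP scale)
    n_demes: int = 5              # demes per lineage
    spatial_range_km: float = 30.0
    env_effect_scale: float = 1.0  # multiplies the lineage shifts in _ENV_MODEL
    env_noise_scale: float = 1.0
    discordance_rate: float = 7.0 / 47.0
    missing_rate: float = 0.05
    n_p3: int = 3                 # lineage-0 samples labelled as sub-cluster P3
    separate_centroids: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.f_div < 1.0) and self.f_div != 0.0:
            raise ValueError("f_div must be in [0, 1)")
        if not (0.0 <= self.discordance_rate < 1.0):
            raise ValueError("discordance_rate must be in [0, 1)")
        if min(self.n_per_cluster) < 1 or self.n_demes < 1 or self.n_loci < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    metadata: list[SampleMetadata]
    truth: dict = field(default_factory=dict)


def _balding_nichols(rng, p_anc: np.ndarray, f: float) -> np.ndarray:
    """Lineage frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around ancestral p."""
    f = max(f, 1e-6)  # clamp: F -> 0 degenerates to a point mass at p
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    return rng.beta(a, b)


def _deme_coords(rng, params: SimParams):
    """Deme centres per lineage inside the sampling window (km)."""
    w, h = _WINDOW_KM
    if params.separate_centroids:
        centroids = [(0.65 * w, 0.5 * h), (0.15 * w, 0.45 * h)]
        spread = [(0.25 * w, 0.3 * h), (0.08 * w, 0.15 * h)]
    else:
        centroids = [(0.5 * w, 0.5 * h)] * 2
        spread = [(0.25 * w, 0.3 * h)] * 2
    out = []
    for (cx, cy), (sx, sy) in zip(centroids, spread):
        xy = np.column_stack([
            np.clip(rng.normal(cx, sx, params.n_demes), 0, w),
            np.clip(rng.normal(cy, sy, params.n_demes), 0, h)])
        out.append(xy)
    return out


def _gp_field(rng, coords: np.ndarray, range_km: float, n_draws: int):
    """Standardised GP draws over points with exponential covariance."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    C = np.exp(-d / max(range_km, 1e-6)) + 1e-8 * np.eye(len(coords))
    Lc = np.linalg.cholesky(C)
    return Lc @ rng.standard_normal((len(coords), n_draws))


def simulate_dataset(params: SimParams = SimParams()) -> SimOutput:
    """Generate genotypes, metadata and a truth record from one seed."""
    rng = np.random.default_rng(params.seed)
    L = params.n_loci
    n0, n1 = params.n_per_cluster
    n = n0 + n1
    lineage = np.repeat([0, 1], [n0, n1])

    p_anc = rng.uniform(0.05, 0.95, L)
    lin_freq = np.stack([_balding_nichols(rng, p_anc, params.f_div)
                         for _ in range(2)])            # (2, L)

    deme_xy = _deme_coords(rng, params)
    deme_of = np.concatenate([np.arange(n0) % params.n_demes,
                              np.arange(n1) % params.n_demes])
    # logit-scale GP per lineage; marginal variance matched to f_deme via the
    # delta method Var(freq) ~ (p(1-p))^2 sigma^2 = f_deme * p(1-p)
    sample_freq = np.empty((n, L))
    for g in (0, 1):
        pf = np.clip(lin_freq[g], 1e-4, 1 - 1e-4)
        if params.f_deme > 0:
            z = _gp_field(rng, deme_xy[g], params.spatial_range_km, L)
            sigma = np.sqrt(params.f_deme / (pf * (1 - pf)))
            sigma = np.minimum(sigma, 3.0)
            deme_freq = expit(logit(pf)[None, :] + z * sigma[None, :])
        else:
            deme_freq = np.tile(pf, (params.n_demes, 1))
        members = np.flatnonzero(lineage == g)
        sample_freq[members] = deme_freq[deme_of[members]]

    dosages = rng.binomial(2, sample_freq).astype(np.int8)
    missing = rng.random((n, L)) < params.missing_rate

    # coordinates: deme centre + small local jitter
    xy = np.empty((n, 2))
    for i in range(n):
        xy[i] = deme_xy[lineage[i]][deme_of[i]] + rng.normal(0, 2.0, 2)
    lat = _ORIGIN[0] + (xy[:, 1] - _WINDOW_KM[1] / 2) / _KM_PER_DEG
    lon = _ORIGIN[1] + (xy[:, 0] - _WINDOW_KM[0] / 2) / (
        _KM_PER_DEG * np.cos(np.radians(_ORIGIN[0])))

    env_vals = {}
    for name, (base, shift, grad, noise) in _ENV_MODEL.items():
        env_vals[name] = (base
                          + params.env_effect_scale * shift * (lineage == 0)
                          + grad * (xy[:, 0] - _WINDOW_KM[0] / 2)
                          + rng.normal(0, noise * params.env_noise_scale, n))

    flip = rng.random(n) < params.discordance_rate
    haplotype = np.where(lineage == 0, "H1", "H2")
    haplotype = np.where(flip, np.where(haplotype == "H1", "H2", "H1"), haplotype)

    cluster = np.where(lineage == 0, "P1", "P2").astype(object)
    if params.n_p3 > 0:
        p3_idx = np.flatnonzero(lineage == 0)[-params.n_p3:]
        cluster[p3_idx] = "P3"

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    locus_ids = [f"1:{j + 1}" for j in range(L)]
    nt = np.array(list("ACGT"))
    ref = nt[rng.integers(0, 4, L)]
    alt = nt[(np.searchsorted(nt, ref) + rng.integers(1, 4, L)) % 4]
    G = GenotypeMatrix(sample_ids, locus_ids, dosages, missing, ref, alt)

    meta = []
    for i, s in enumerate(sample_ids):
        env = EnvRecord(**{k: float(env_vals[k][i]) for k in _ENV_MODEL})
        meta.append(SampleMetadata(s, f"C{i + 1:03d}", float(lat[i]),
                                   float(lon[i]), str(haplotype[i]),
                                   str(cluster[i]), env))
    truth = {
        "lineage": lineage, "lineage_freqs": lin_freq, "p_ancestral": p_anc,
        "deme_of": deme_of, "xy_km": xy, "params": params,
        "discordant": flip,
    }
    return SimOutput(G, meta, truth)


def scenario_presets() -> dict[str, SimParams]:
    """Named generator configurations.

    - "study-like": published sizes and divergence (31+16, F~0.15, ~15%
      discordance) with IBD and lineage-linked environments.
    - "null-panmixia": one panmictic gene pool split into two arbitrary
      labels; for type-I-error calibration.
    - "ibd-only": no lineage divergence, strong spatial autocorrelation.
    - "ibe-only": lineage divergence + lineage-linked environment but
      spatially interleaved lineages and no within-lineage autocorrelation.
    """
    return {
        "study-like": SimParams(),
        "null-panmixia": SimParams(f_div=0.0, f_deme=0.0, env_effect_scale=0.0,
                                   discordance_rate=0.5, n_p3=0),
        "ibd-only": SimParams(f_div=0.0, f_deme=0.1, spatial_range_km=40.0,
                              env_effect_scale=0.0, n_p3=0,
                              separate_centroids=False),
        "ibe-only": SimParams(f_deme=0.0, env_effect_scale=1.5, n_p3=0,
                              separate_centroids=False),
    }


def get_preset(name: str, seed: int = 0, **overrides) -> SimParams:
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    return replace(presets[name], seed=seed, **overrides)
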