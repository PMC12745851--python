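"""Genotype and metadata I/O plus Stacks-style locus filtering.

The central container is :class:`GenotypeMatrix`: a samples x loci matrix of
biallelic diploid ALT-allele dosages (0/1/2) with an explicit missing mask.
Readers are provided for VCF (via cyvcf2) and Genepop; writers for VCF,
Genepop and a relaxed sequential PHYLIP SNP alignment (heterozygotes as
IUPAC ambiguity codes) suitable for Neighbour-Net software.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IUPAC_HET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

HAPLOTYPES = ("H1", "H2", "unknown")
CLUSTERS = ("P1", "P2", "P3", "unassigned")
ENV_COLUMNS = ("rmean", "tmean", "tminave", "tmaxave", "tmaxsum", "tminwint",
               "ndmi16", "ndmi19")
METADATA_COLUMNS = ("sample_id", "colony_id", "lat", "lon", "haplotype",
                    "cluster") + ENV_COLUMNS


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Biallelic diploid SNP dosages with a missing mask.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    locus_ids : list of str
        Unique locus identifiers ("chrom:pos" or catalog ids), one per column.
    dosages : (n_samples, n_loci) int8 array
        ALT-allele counts in {0, 1, 2}; entries under ``missing`` are ignored.
    missing : (n_samples, n_loci) bool array
        True where the genotype call is missing.
    ref, alt : arrays of single characters, optional
        Reference/alternate nucleotides per locus (defaults "A"/"T").
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray
    missing: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    ploidy: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, L = self.dosages.shape
        if n < 1 or L < 1:
            raise ValueError("need at least 1 sample and 1 locus")
        if len(self.sample_ids) != n or len(self.locus_ids) != L:
            raise ValueError("id lists do not match dosage matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus_ids are not unique")
        valid = self.missing | np.isin(self.dosages, (0, 1, 2))
        if not valid.all():
            raise ValueError("non-missing dosages must be in {0,1,2}")
        if self.missing.shape != (n, L):
            raise ValueError("missing mask shape mismatch")
        if self.ref is None:
            self.ref = np.full(L, "A", dtype="U1")
        if self.alt is None:
            self.alt = np.full(L, "T", dtype="U1")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], list(self.locus_ids),
            self.dosages[idx], self.missing[idx], self.ref, self.alt)

    def take_loci(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.sample_ids), [self.locus_ids[j] for j in idx],
            self.dosages[:, idx], self.missing[:, idx],
            self.ref[idx], self.alt[idx])

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in ids], dtype=int)


@dataclass(frozen=True)
class EnvRecord:
    """Site-level environmental covariates (30-year climate normals + NDMI)."""
    rmean: float = np.nan       # mean annual precipitation, mm
    tmean: float = np.nan       # mean annual temperature, degC
    tminave: float = np.nan     # mean annual minimum temperature, degC
    tmaxave: float = np.nan     # mean annual maximum temperature, degC
    tmaxsum: float = np.nan     # mean summer maximum temperature, degC
    tminwint: float = np.nan    # mean winter minimum temperature, degC
    ndmi16: float = np.nan      # normalized difference moisture index, wet year
    ndmi19: float = np.nan      # normalized difference moisture index, dry year

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ENV_COLUMNS}


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample record: location, mitochondrial haplotype, nuclear cluster, env."""
    sample_id: str
    colony_id: str
    lat: float
    lon: float
    haplotype: str = "unknown"
    cluster: str = "unassigned"
    env: EnvRecord = field(default_factory=EnvRecord)

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude out of range: {self.lon}")
        if self.haplotype not in HAPLOTYPES:
            raise ValueError(f"unknown haplotype token: {self.haplotype!r}")
        if self.cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster token: {self.cluster!r}")


@dataclass(frozen=True)
class FilterConfig:
    """Locus-filter thresholds mirroring the Stacks populations flags.

    Defaults reproduce a common RAD-seq configuration: a locus must be called
    in >=70% of samples within at least ``min_populations`` population(s),
    >=30% of samples overall, have pooled minor-allele frequency >=0.05,
    minor-allele count >=1 and observed heterozygosity <=0.5.
    """
    min_samples_per_pop: float = 0.7
    min_populations: int = 1
    min_samples_overall: float = 0.3
    min_maf: float = 0.05
    min_mac: int = 1
    max_obs_het: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_samples_per_pop", "min_samples_overall", "min_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0,1], got {v}")
        if self.min_mac < 0 or self.min_populations < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.max_obs_het <= 1.0):
            raise ValueError("max_obs_het must be in [0,1]")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, *, drop_multiallelic: bool = False) -> GenotypeMatrix:
    """Read a VCF with GT fields into a :class:`GenotypeMatrix`.

    Multiallelic records raise :class:`GenotypeParseError` unless
    ``drop_multiallelic`` is set, in which case they are skipped. "./." (or
    any call with a missing allele) becomes a masked entry. Site order is
    preserved.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise GenotypeParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    dos_cols: list[np.ndarray] = []
    miss_cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if drop_multiallelic:
                continue
            raise GenotypeParseError(
                f"multiallelic record at {var.CHROM}:{var.POS} "
                "(pass drop_multiallelic=True to skip)")
        gts = np.array(var.genotypes, dtype=object)
        a = np.array([g[0] for g in gts], dtype=int)
        b = np.array([g[1] if len(g) >= 3 else -9 for g in gts], dtype=int)
        if np.any(b == -9):
            raise GenotypeParseError(
                f"non-diploid genotype at {var.CHROM}:{var.POS}")
        miss = (a < 0) | (b < 0)
        dos = np.where(miss, 0, a + b)
        dos_cols.append(dos)
        miss_cols.append(miss)
        locus_ids.append(f"{var.CHROM}:{var.POS}")
        refs.append((var.REF or "A")[0])
        alts.append((var.ALT[0] or "T")[0])
    vcf.close()
    if not locus_ids:
        raise GenotypeParseError(f"no usable biallelic sites in {path}")
    return GenotypeMatrix(
        samples, locus_ids,
        np.column_stack(dos_cols), np.column_stack(miss_cols),
        np.array(refs, dtype="U1"), np.array(alts, dtype="U1"))


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 representation of the matrix."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({lid.split(":")[0] if ":" in lid else "1"
                         for lid in G.locus_ids})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.sample_ids) + "\n")
        for j, lid in enumerate(G.locus_ids):
            if ":" in lid:
                chrom, pos = lid.split(":", 1)
            else:
                chrom, pos = "1", str(j + 1)
            gts = ["./." if G.missing[i, j] else gt_code[int(G.dosages[i, j])]
                   for i in range(G.n_samples)]
            fh.write(f"{chrom}\t{pos}\t{lid}\t{G.ref[j]}\t{G.alt[j]}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Genepop

def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Read a 2- or 3-digit Genepop file (POP blocks) into dosages.

    Alleles are recoded to a biallelic 0/1 scheme with the numerically
    smaller allele code as REF; loci showing more than two alleles raise an
    error naming the locus. "0000"/"000000" is the missing convention.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeParseError("Genepop file too short")
    body = lines[1:]
    # locus names: either comma-separated on one line or one per line up to POP
    locus_ids: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        chunk = body[i].strip()
        if chunk:
            locus_ids.extend(s.strip() for s in chunk.split(",") if s.strip())
        i += 1
    if i == len(body):
        raise GenotypeParseError("no POP keyword found")
    L = len(locus_ids)
    sample_ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_of: list[int] = []
    pop = -1
    width: int | None = None
    for ln, line in enumerate(body[i:], start=i + 2):
        s = line.strip()
        if not s:
            continue
        if s.upper() == "POP":
            pop += 1
            continue
        if "," not in s:
            raise GenotypeParseError(f"line {ln}: expected 'name , alleles'")
        name, geno = s.split(",", 1)
        toks = geno.split()
        if len(toks) != L:
            raise GenotypeParseError(
                f"line {ln}: {len(toks)} genotypes for {L} loci")
        row = []
        for t in toks:
            if width is None:
                if len(t) not in (4, 6):
                    raise GenotypeParseError(f"line {ln}: bad allele width in {t!r}")
                width = len(t) // 2
            elif len(t) != 2 * width:
                raise GenotypeParseError(f"line {ln}: inconsistent allele width {t!r}")
            row.append((int(t[:width]), int(t[width:])))
        sample_ids.append(name.strip())
        rows.append(row)
        pop_of.append(pop)
    n = len(sample_ids)
    dosages = np.zeros((n, L), dtype=np.int8)
    missing = np.zeros((n, L), dtype=bool)
    for j in range(L):
        alleles = sorted({a for r in rows for a in r[j] if a != 0})
        if len(alleles) > 2:
            raise GenotypeParseError(
                f"locus {locus_ids[j]} has {len(alleles)} alleles; need <=2")
        if not alleles:
            alleles = [1]
        ref = alleles[0]
        alt = alleles[-1] if len(alleles) == 2 else None
        for idx, r in enumerate(rows):
            a, b = r[j]
            if a == 0 or b == 0:
                missing[idx, j] = True
            else:
                dosages[idx, j] = (alt is not None) * ((a == alt) + (b == alt))
    return GenotypeMatrix(sample_ids, locus_ids, dosages, missing)


def write_genepop(G: GenotypeMatrix, path: str | Path,
                  pops: Mapping[str, str] | None = None,
                  title: str = "invadibe export") -> None:
    """Write dosages as a 2-digit Genepop file (REF=01, ALT=02, missing 0000)."""
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(G.sample_ids):
        groups.setdefault(pops[s] if pops else "all", []).append(i)
    code = {0: "0101", 1: "0102", 2: "0202"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write("\n".join(G.locus_ids) + "\n")
        for members in groups.values():
            fh.write("POP\n")
            for i in members:
                toks = ["0000" if G.missing[i, j] else code[int(G.dosages[i, j])]
                        for j in range(G.n_loci)]
                fh.write(f"{G.sample_ids[i]} , " + " ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# Metadata CSV

def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the per-sample metadata CSV (documented header) into records."""
    df = pd.read_csv(path, dtype={"sample_id": str, "colony_id": str})
    missing_cols = {"sample_id", "colony_id", "lat", "lon"} - set(df.columns)
    if missing_cols:
        raise GenotypeParseError(f"metadata missing columns: {sorted(missing_cols)}")
    unknown = set(df.columns) - set(METADATA_COLUMNS)
    if unknown:
        warnings.warn(f"ignoring unknown metadata columns: {sorted(unknown)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise GenotypeParseError(f"duplicate sample ids in metadata: {dups}")
    records = []
    for _, row in df.iterrows():
        env = EnvRecord(**{k: float(row[k]) if k in df.columns and pd.notna(row[k])
                           else np.nan for k in ENV_COLUMNS})
        hap = str(row["haplotype"]) if "haplotype" in df.columns and pd.notna(
            row.get("haplotype")) else "unknown"
        clus = str(row["cluster"]) if "cluster" in df.columns and pd.notna(
            row.get("cluster")) else "unassigned"
        try:
            lat, lon = float(row["lat"]), float(row["lon"])
        except (TypeError, ValueError) as exc:
            raise GenotypeParseError(
                f"unparseable coordinates for {row['sample_id']}") from exc
        records.append(SampleMetadata(str(row["sample_id"]), str(row["colony_id"]),
                                      lat, lon, hap, clus, env))
    counts = pd.Series([r.cluster for r in records]).value_counts().to_dict()
    logger.info("read %d metadata records; cluster counts %s", len(records), counts)
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for r in records:
        d = {"sample_id": r.sample_id, "colony_id": r.colony_id,
             "lat": r.lat, "lon": r.lon, "haplotype": r.haplotype,
             "cluster": r.cluster}
        d.update(r.env.as_dict())
        rows.append(d)
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, index=False)


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Tabular view of metadata records, indexed by sample_id."""
    rows = []
    for r in records:
        d = {"sample_id": r.sample_id, "colony_id": r.colony_id, "lat": r.lat,
             "lon": r.lon, "haplotype": r.haplotype, "cluster": r.cluster}
        d.update(r.env.as_dict())
        rows.append(d)
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Locus filtering

def _locus_stats(G: GenotypeMatrix):
    called = ~G.missing
    n_called = called.sum(axis=0)
    alt = np.where(called, G.dosages, 0).sum(axis=0)
    copies = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
        maf = np.minimum(p_alt, 1.0 - p_alt)
        mac = np.minimum(alt, copies - alt)
        het = np.where(called, G.dosages == 1, False).sum(axis=0)
        obs_het = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
    return n_called, maf, mac, obs_het


def filter_loci(G: GenotypeMatrix, pops: Mapping[str, str],
                cfg: FilterConfig = FilterConfig()):
    """Apply the Stacks-style per-locus filters; returns (filtered, report).

    A locus is retained iff it is called in >= ``min_samples_per_pop`` of the
    samples of at least ``min_populations`` populations, called overall in
    >= ``min_samples_overall`` of samples, has pooled minor-allele frequency
    >= ``min_maf``, minor-allele count >= ``min_mac`` and observed
    heterozygosity <= ``max_obs_het``. The report lists per-filter removal
    counts (a locus may fail several filters).
    """
    missing_map = [s for s in G.sample_ids if s not in pops]
    if missing_map:
        raise ValueError(f"samples without population assignment: {missing_map}")
    labels = np.array([pops[s] for s in G.sample_ids])
    uniq = np.unique(labels)
    called = ~G.missing
    pops_ok = np.zeros(G.n_loci, dtype=int)
    for u in uniq:
        sub = called[labels == u]
        pops_ok += (sub.mean(axis=0) >= cfg.min_samples_per_pop)
    n_called, maf, mac, obs_het = _locus_stats(G)
    overall_rate = n_called / G.n_samples
    fail = {
        "min_samples_per_pop": pops_ok < cfg.min_populations,
        "min_samples_overall": overall_rate < cfg.min_samples_overall,
        "min_maf": ~(maf >= cfg.min_maf),
        "min_mac": ~(mac >= cfg.min_mac),
        "max_obs_het": ~(obs_het <= cfg.max_obs_het),
    }
    keep = ~np.logical_or.reduce(list(fail.values()))
    report = {name: int(mask.sum()) for name, mask in fail.items()}
    report["n_input"] = G.n_loci
    report["n_retained"] = int(keep.sum())
    if report["n_retained"] == 0:
        # GenotypeMatrix forbids zero loci; surface the degenerate case as None
        warnings.warn("all loci removed by filters")
        return None, report
    return G.take_loci(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# PHYLIP SNP alignment

def snp_sequences(G: GenotypeMatrix) -> list[str]:
    """Per-sample concatenated SNP pseudo-sequences (IUPAC hets, N missing)."""
    seqs = []
    het_codes = np.array(
        [IUPAC_HET.get(frozenset((r, a)), "N") if r != a else r
         for r, a in zip(G.ref, G.alt)], dtype="U1")
    for i in range(G.n_samples):
        chars = np.where(G.dosages[i] == 0, G.ref,
                         np.where(G.dosages[i] == 2, G.alt, het_codes))
        chars = np.where(G.missing[i], "N", chars)
        seqs.append("".join(chars))
    return seqs


def write_phylip_snp(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a relaxed sequential PHYLIP alignment of the SNP pseudo-sequences."""
    seqs = snp_sequences(G)
    with open(path, "w") as fh:
        fh.write(f"{G.n_samples} {G.n_loci}\n")
        for name, seq in zip(G.sample_ids, seqs):
            fh.write(f"{name}  {seq}\n")
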