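"""Genotype and cohort I/O.

Genotypes are held additively coded: each cell is the alt-allele count
(0, 1 or 2) of a diploid biallelic genotype, with ``-1`` marking a missing
call.  Cohort tables hold per-sample quantitative traits (e.g. systolic and
diastolic blood pressure in mmHg) and environmental covariates (age in
years, binary smoking / medication indicators).

Supported formats: VCF 4.x (read via :mod:`cyvcf2`, written as plain text)
and tab-delimited tables with a header row whose first column is the sample
id.  Tables may carry ``##``-prefixed metadata lines that make the
round-trip lossless (SNP coordinates, trait/environment column roles).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call in :class:`GenotypeMatrix.codes`
MISSING = -1

# column-name heuristic used only when a cohort table has no ## metadata
_ENV_NAME_HINTS = {"age", "smoke", "smoking", "medication", "med", "sex", "bmi"}


@dataclass(frozen=True)
class SNPRecord:
    """Identity and coordinates of one biallelic SNP (1-based position)."""

    id: str
    chrom: str = "NA"
    pos: int = 0
    ref: str = "N"
    alt: str = "A"


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive genotype codes with SNP metadata.

    ``codes[i, j]`` is the alt-allele count of sample ``i`` at SNP ``j``;
    ``-1`` means missing.  Sample order and SNP order are significant and
    preserved through I/O.
    """

    samples: list[str]
    snps: list[SNPRecord]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D sample x SNP matrix")
        n, p = self.codes.shape
        if n != len(self.samples):
            raise ValueError(
                f"{len(self.samples)} samples but {n} genotype rows"
            )
        if p != len(self.snps):
            raise ValueError(f"{len(self.snps)} SNP records but {p} columns")
        bad = ~np.isin(self.codes, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype code {self.codes[i, j]} at sample "
                f"{self.samples[i]!r}, SNP {self.snps[j].id!r} is not in "
                "{0,1,2} or missing"
            )
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in genotype matrix")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in genotype matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Restrict to samples at positional indices ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            snps=list(self.snps),
            codes=self.codes[idx, :],
        )


@dataclass
class CohortTable:
    """Per-sample quantitative traits and environmental covariates.

    Values are floats with NaN as the missing marker.  Binary environments
    must contain only {0, 1, NaN}.
    """

    samples: list[str]
    traits: dict[str, np.ndarray] = field(default_factory=dict)
    environments: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in cohort table")
        for group in (self.traits, self.environments):
            for name, vec in group.items():
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (len(self.samples),):
                    raise ValueError(
                        f"column {name!r} has length {vec.shape} but the "
                        f"cohort has {len(self.samples)} samples"
                    )
                group[name] = vec

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def trait(self, name: str) -> np.ndarray:
        return self.traits[name]

    def env(self, name: str) -> np.ndarray:
        return self.environments[name]

    def is_binary_env(self, name: str) -> bool:
        v = self.environments[name]
        v = v[~np.isnan(v)]
        return bool(np.isin(v, (0.0, 1.0)).all())

    def subset_samples(self, idx: np.ndarray) -> "CohortTable":
        idx = np.asarray(idx)
        return CohortTable(
            samples=[self.samples[i] for i in idx],
            traits={k: v[idx] for k, v in self.traits.items()},
            environments={k: v[idx] for k, v in self.environments.items()},
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    dosage_rule: str = "alt-count",
    split_multiallelic: bool = False,
) -> GenotypeMatrix:
    """Read diploid GT fields from a VCF into additive 0/1/2 codes.

    Missing calls (``./.``) become the missing marker.  Multi-allelic
    records are rejected unless ``split_multiallelic`` is set, in which case
    one pseudo-SNP per alternate allele is emitted (counting that allele).
    """
    if dosage_rule != "alt-count":
        raise ValueError(f"unknown dosage rule {dosage_rule!r}")
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on parse failure
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    records: list[SNPRecord] = []
    for var in vcf:
        alts = list(var.ALT) if var.ALT else ["."]
        if len(alts) > 1 and not split_multiallelic:
            raise ValueError(
                f"multi-allelic record {var.CHROM}:{var.POS} "
                f"(ALT={','.join(alts)}); rerun with split_multiallelic=True"
            )
        genotypes = var.genotypes
        for alt_index, alt in enumerate(alts, start=1):
            codes = np.full(len(samples), MISSING, dtype=np.int8)
            for si, gt in enumerate(genotypes):
                alleles = gt[:-1]  # last element is the phase flag
                if len(alleles) != 2:
                    raise ValueError(
                        f"non-diploid genotype for sample {samples[si]!r} "
                        f"in record {var.CHROM}:{var.POS}"
                    )
                if alleles[0] < 0 or alleles[1] < 0:
                    continue
                codes[si] = int(alleles[0] == alt_index) + int(
                    alleles[1] == alt_index
                )
            snp_id = var.ID or f"{var.CHROM}:{var.POS}"
            if len(alts) > 1:
                snp_id = f"{snp_id}:{alt}"
            records.append(
                SNPRecord(snp_id, str(var.CHROM), int(var.POS), var.REF, alt)
            )
            columns.append(codes)
    vcf.close()
    codes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, snps=records, codes=codes)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 text file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=puregxe\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, snp in enumerate(g.snps):
            gts = "\t".join(_GT_STRING[int(c)] for c in g.codes[:, j])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{snp.ref}\t{snp.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def write_table(
    obj: GenotypeMatrix | CohortTable, path: str | Path
) -> None:
    """Write either data type as a TSV with ``##`` metadata lines."""
    path = Path(path)
    if isinstance(obj, GenotypeMatrix):
        with path.open("w") as fh:
            fh.write("##genotype-table\tv1\n")
            for s in obj.snps:
                fh.write(f"##snp\t{s.id}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\n")
            fh.write("sample_id\t" + "\t".join(obj.snp_ids) + "\n")
            for i, sid in enumerate(obj.samples):
                cells = [
                    "NA" if c == MISSING else str(int(c))
                    for c in obj.codes[i, :]
                ]
                fh.write(sid + "\t" + "\t".join(cells) + "\n")
    elif isinstance(obj, CohortTable):
        with path.open("w") as fh:
            fh.write("##cohort-table\tv1\n")
            for name in obj.traits:
                fh.write(f"##trait\t{name}\n")
            for name in obj.environments:
                fh.write(f"##env\t{name}\n")
            cols = list(obj.traits) + list(obj.environments)
            fh.write("sample_id\t" + "\t".join(cols) + "\n")
            for i, sid in enumerate(obj.samples):
                vals = []
                for name in cols:
                    v = (
                        obj.traits[name][i]
                        if name in obj.traits
                        else obj.environments[name][i]
                    )
                    vals.append("NA" if np.isnan(v) else format(v, ".12g"))
                fh.write(sid + "\t" + "\t".join(vals) + "\n")
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")


def _read_meta_and_frame(path: Path) -> tuple[list[list[str]], pd.DataFrame]:
    meta: list[list[str]] = []
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("##"):
            meta.append(line.rstrip("\n").split("\t"))
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype=str, na_values=["NA"])
    if df.shape[0] == 0:
        raise ValueError(f"{path}: table has zero data rows")
    return meta, df


def read_table(
    path: str | Path,
    kind: str,
    trait_cols: list[str] | None = None,
    env_cols: list[str] | None = None,
) -> GenotypeMatrix | CohortTable:
    """Read a delimited genotype or cohort table.

    ``kind`` is ``"genotypes"`` or ``"cohort"``.  For cohort tables the
    trait/environment split is taken from ``##trait`` / ``##env`` metadata
    lines when present, else from the ``trait_cols`` / ``env_cols``
    arguments, else from a conservative column-name heuristic.
    """
    path = Path(path)
    meta, df = _read_meta_and_frame(path)
    sample_col = df.columns[0]
    samples = df[sample_col].astype(str).tolist()
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample ids")
    body = df.drop(columns=[sample_col])

    if kind == "genotypes":
        snp_meta = {m[1]: m for m in meta if m[0] == "##snp" and len(m) >= 6}
        records = []
        for j, col in enumerate(body.columns):
            if col in snp_meta:
                _, sid, chrom, p, ref, alt = snp_meta[col][:6]
                records.append(SNPRecord(sid, chrom, int(p), ref, alt))
            else:
                records.append(SNPRecord(str(col), "NA", j + 1))
        codes = np.full(body.shape, MISSING, dtype=np.int8)
        for j, col in enumerate(body.columns):
            raw = body[col]
            for i, cell in enumerate(raw):
                if pd.isna(cell):
                    continue
                try:
                    v = int(float(cell))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: unparseable genotype {cell!r} for sample "
                        f"{samples[i]!r}, SNP {col!r}"
                    ) from exc
                if v not in (0, 1, 2):
                    raise ValueError(
                        f"{path}: genotype code {v} for sample "
                        f"{samples[i]!r}, SNP {col!r} is outside {{0,1,2}}"
                    )
                codes[i, j] = v
        return GenotypeMatrix(samples=samples, snps=records, codes=codes)

    if kind == "cohort":
        meta_traits = [m[1] for m in meta if m[0] == "##trait"]
        meta_envs = [m[1] for m in meta if m[0] == "##env"]
        if meta_traits or meta_envs:
            trait_cols, env_cols = meta_traits, meta_envs
        if trait_cols is None and env_cols is None:
            env_cols = [
                c for c in body.columns if c.lower() in _ENV_NAME_HINTS
            ]
            trait_cols = [c for c in body.columns if c not in env_cols]
        trait_cols = trait_cols or []
        env_cols = env_cols or []
        missing = set(trait_cols + env_cols) - set(body.columns)
        if missing:
            raise ValueError(f"{path}: columns not found: {sorted(missing)}")

        def parse(col: str) -> np.ndarray:
            out = np.full(len(samples), np.nan)
            for i, cell in enumerate(body[col]):
                if pd.isna(cell):
                    continue
                try:
                    out[i] = float(cell)
                except ValueError:
                    logger.warning(
                        "%s: unparseable value %r in column %r for sample "
                        "%r; treated as missing",
                        path, cell, col, samples[i],
                    )
            return out

        return CohortTable(
            samples=samples,
            traits={c: parse(c) for c in trait_cols},
            environments={c: parse(c) for c in env_cols},
        )

    raise ValueError(f"unknown table kind {kind!r}")


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def align_and_drop_missing(
    g: GenotypeMatrix,
    c: CohortTable,
    trait: str,
    envs: list[str],
) -> tuple[GenotypeMatrix, CohortTable]:
    """Intersect samples and drop any with a missing trait or requested env.

    Sample order follows the genotype matrix.  Per-SNP missing genotypes are
    left in place; each downstream single-SNP test deletes them pairwise.
    """
    cohort_pos = {s: i for i, s in enumerate(c.samples)}
    g_keep: list[int] = []
    c_keep: list[int] = []
    for gi, sid in enumerate(g.samples):
        ci = cohort_pos.get(sid)
        if ci is None:
            continue
        if np.isnan(c.traits[trait][ci]):
            continue
        if any(np.isnan(c.environments[e][ci]) for e in envs):
            continue
        g_keep.append(gi)
        c_keep.append(ci)
    if not g_keep:
        raise ValueError(
            "no samples shared by genotypes and cohort after removing "
            "missing values"
        )
    return g.subset_samples(np.array(g_keep)), c.subset_samples(
        np.array(c_keep)
    )
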