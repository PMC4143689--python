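"""Genome-wide scans: pure G x E two-step scan and genotype-only scans.

``scan_pure_gxe`` runs, for every SNP, the two-step procedure: remove the
environment's then the SNP's main effect from the trait by stepwise PPR
residualization, partition the samples by genotype x dichotomized
environment, and score the residuals with the influence measure, assessing
significance by permutation.  ``scan_g_only`` scores the raw (standardized)
trait on the genotype-only partition, optionally within an age subgroup,
reporting the all-sample score alongside for comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import CohortTable, GenotypeMatrix, MISSING, align_and_drop_missing
from .discretize import two_means_dichotomize
from .influence import (
    _center_rows,
    _factor_indices,
    build_partition,
    i_score,
    permutation_p,
)
from .ppr import _backfit_two_way, fit_ppr, residualize_stepwise

__all__ = ["ScanConfig", "ScanTable", "SignificanceTally", "scan_pure_gxe",
           "scan_g_only", "tally_significance"]

_COLUMNS = ["rank", "snp_id", "chrom", "pos", "n_used", "i_score",
            "p_perm", "n_perm", "flags"]


@dataclass
class ScanConfig:
    """Tuning knobs shared by the scan drivers."""

    smoother: str = "lowess"          # continuous smoother for Step 1
    max_levels: int = 4               # <= this many distinct values => level-means
    n_perm: int = 2000                # permutations per SNP (0 = skip p-values)
    seed: int = 0
    min_cell_total: int = 20          # minimum usable samples per SNP test
    standardize: bool = True
    refit_permutations: bool = False  # re-run Step 1 inside each permutation
    batch_size: int = 20_000


def _snp_seed(seed: int, j: int) -> np.random.SeedSequence:
    # counter-based substream: results do not depend on scan order
    return np.random.SeedSequence(entropy=seed, spawn_key=(j,))


@dataclass
class ScanTable:
    """Per-SNP scan results, one row per tested SNP, in input SNP order."""

    rows: pd.DataFrame
    mode: str                      # "pure-GxE" or "G-only"
    env_name: str | None = None
    subgroup: str | None = None

    def top(self, k: int) -> list[str]:
        """SNP ids of the k highest I-scores (skipped SNPs excluded)."""
        ok = self.rows.dropna(subset=["i_score"])
        return ok.sort_values("i_score", ascending=False, kind="stable")[
            "snp_id"
        ].head(k).tolist()

    def ranked(self) -> pd.DataFrame:
        """Rows sorted by descending I-score (stable; skipped rows last)."""
        return self.rows.sort_values(
            "i_score", ascending=False, kind="stable", na_position="last"
        ).reset_index(drop=True)

    def to_tsv(self, path: str | Path, meta: dict | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for k, v in (meta or {}).items():
                fh.write(f"# {k}: {v}\n")
            fh.write(f"# mode: {self.mode}\n")
            if self.env_name:
                fh.write(f"# env: {self.env_name}\n")
            if self.subgroup:
                fh.write(f"# subgroup: {self.subgroup}\n")
            self.rows.to_csv(fh, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScanTable":
        path = Path(path)
        meta: dict[str, str] = {}
        with path.open() as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            rows = pd.read_csv(fh, sep="\t", na_values=["NA"])
        return cls(
            rows=rows,
            mode=meta.get("mode", "unknown"),
            env_name=meta.get("env") or None,
            subgroup=meta.get("subgroup") or None,
        )


@dataclass
class SignificanceTally:
    """SNP counts reaching each permutation p-value threshold."""

    thresholds: list[float]
    counts: list[int]
    fractions: list[float]


def _assign_ranks(rows: pd.DataFrame) -> pd.DataFrame:
    score = rows["i_score"]
    order = score.rank(ascending=False, method="first", na_option="bottom")
    rows = rows.copy()
    rows["rank"] = order.astype(int)
    return rows


def scan_pure_gxe(
    g: GenotypeMatrix,
    c: CohortTable,
    trait: str,
    env: str,
    cfg: ScanConfig | None = None,
) -> ScanTable:
    """Two-step pure interaction scan of every SNP against one environment.

    A continuous environment (age) is residualized on its continuous values
    in Step 1 and dichotomized by exact two-means only for the Step-2
    partition; a binary environment is used as-is for both.  SNPs with
    fewer than ``cfg.min_cell_total`` usable samples, or without genotype
    variation, are flagged and skipped rather than raising.
    """
    cfg = cfg or ScanConfig()
    g, c = align_and_drop_missing(g, c, trait, [env])
    y = c.trait(trait)
    e = c.env(env)
    if c.is_binary_env(env):
        z = e.astype(int)
    else:
        z = two_means_dichotomize(e).labels

    # Step-1 environment fit is shared by every SNP with complete genotypes
    env_smoother = (
        "level-means" if np.unique(e).size <= cfg.max_levels else cfg.smoother
    )
    res1_full = fit_ppr(
        e, y, M=1, smoother=env_smoother, max_levels=cfg.max_levels
    ).residuals

    records = []
    for j, snp in enumerate(g.snps):
        codes = g.codes[:, j]
        mask = codes != MISSING
        n_used = int(mask.sum())
        rec = {
            "snp_id": snp.id, "chrom": snp.chrom, "pos": snp.pos,
            "n_used": n_used, "i_score": np.nan, "p_perm": np.nan,
            "n_perm": 0, "flags": "",
        }
        gv = codes[mask].astype(float)
        if n_used < cfg.min_cell_total:
            rec["flags"] = "skipped:too-few-samples"
            records.append(rec)
            continue
        if np.unique(gv).size < 2:
            rec["flags"] = "skipped:monomorphic"
            records.append(rec)
            continue

        if mask.all():
            res1 = res1_full
        else:  # pairwise deletion: refit Step 1 on this SNP's samples
            res1 = fit_ppr(
                e[mask], y[mask], M=1, smoother=env_smoother,
                max_levels=cfg.max_levels,
            ).residuals
        res2 = fit_ppr(gv, res1, M=1, smoother="level-means",
                       max_levels=4).residuals
        # polish so the residual's means within every genotype level AND
        # every environment group are exactly zero: the statistic then
        # carries no main-effect remnant, and the permutation comparison
        # (which applies the same margin removal to every shuffle) uses
        # the identical statistic
        res2 = _backfit_two_way(res2, z[mask], gv)
        factors = [gv, z[mask]]
        part = build_partition(factors)
        rec["i_score"] = i_score(res2, part, standardize=cfg.standardize)

        if cfg.n_perm <= 0:
            pass
        elif cfg.refit_permutations:
            obs = rec["i_score"]
            rng = np.random.default_rng(_snp_seed(cfg.seed, j))
            exceed = 0
            for _ in range(cfg.n_perm):
                yp = rng.permutation(y[mask])
                rp = residualize_stepwise(
                    yp, e[mask], gv, smoother=cfg.smoother,
                    max_levels=cfg.max_levels,
                ).values
                if i_score(rp, part, standardize=cfg.standardize) >= obs:
                    exceed += 1
            rec["p_perm"] = (1 + exceed) / (1 + cfg.n_perm)
            rec["n_perm"] = cfg.n_perm
        else:
            res = permutation_p(
                res2, part, n_perm=cfg.n_perm, seed=_snp_seed(cfg.seed, j),
                standardize=cfg.standardize, batch_size=cfg.batch_size,
                response_kind="residual", center_factors=factors,
            )
            rec["p_perm"] = res.p_value
            rec["n_perm"] = res.n_perm
        records.append(rec)

    rows = _assign_ranks(pd.DataFrame.from_records(records))
    return ScanTable(rows=rows[_COLUMNS], mode="pure-GxE", env_name=env)


def scan_g_only(
    g: GenotypeMatrix,
    c: CohortTable,
    trait: str,
    subgroup_mask: np.ndarray | None = None,
    cfg: ScanConfig | None = None,
    subgroup_label: str | None = None,
    min_subgroup_n: int = 20,
) -> ScanTable:
    """Genotype-only influence scan, optionally within a sample subgroup.

    Scores the standardized trait on the <= 3-cell genotype partition using
    only the masked samples, and reports the all-sample ("overall") score
    next to it.  Permutation p-values are computed within the subgroup when
    ``cfg.n_perm > 0``.
    """
    cfg = cfg or ScanConfig()
    g, c = align_and_drop_missing(g, c, trait, [])
    y = c.trait(trait)
    n = g.n_samples
    if subgroup_mask is None:
        subgroup_mask = np.ones(n, dtype=bool)
    subgroup_mask = np.asarray(subgroup_mask, dtype=bool)
    if subgroup_mask.size != n:
        raise ValueError("subgroup mask length does not match cohort")
    if subgroup_mask.sum() < min_subgroup_n:
        raise ValueError(
            f"subgroup has {int(subgroup_mask.sum())} samples; "
            f"need >= {min_subgroup_n}"
        )

    records = []
    for j, snp in enumerate(g.snps):
        codes = g.codes[:, j]
        ok = codes != MISSING
        mask = ok & subgroup_mask
        n_used = int(mask.sum())
        rec = {
            "snp_id": snp.id, "chrom": snp.chrom, "pos": snp.pos,
            "n_used": n_used, "i_score": np.nan,
            "overall_i_score": np.nan, "p_perm": np.nan, "n_perm": 0,
            "flags": "",
        }
        if n_used < cfg.min_cell_total:
            rec["flags"] = "skipped:too-few-samples"
            records.append(rec)
            continue
        gv = codes[mask].astype(float)
        if np.unique(gv).size < 2:
            rec["flags"] = "skipped:monomorphic"
            records.append(rec)
            continue
        part = build_partition([gv])
        if np.unique(codes[ok]).size >= 2:
            part_all = build_partition([codes[ok].astype(float)])
            rec["overall_i_score"] = i_score(
                y[ok], part_all, standardize=cfg.standardize
            )
        if cfg.n_perm > 0:
            res = permutation_p(
                y[mask], part, n_perm=cfg.n_perm,
                seed=_snp_seed(cfg.seed, j), standardize=cfg.standardize,
                batch_size=cfg.batch_size,
            )
            rec["i_score"] = res.score
            rec["p_perm"] = res.p_value
            rec["n_perm"] = res.n_perm
        else:
            rec["i_score"] = i_score(y[mask], part,
                                     standardize=cfg.standardize)
        records.append(rec)

    rows = _assign_ranks(pd.DataFrame.from_records(records))
    cols = _COLUMNS[:6] + ["overall_i_score"] + _COLUMNS[6:]
    return ScanTable(rows=rows[cols], mode="G-only",
                     subgroup=subgroup_label)


def tally_significance(
    t: ScanTable, thresholds: list[float]
) -> SignificanceTally:
    """Count SNPs whose permutation p-value is strictly below each cutoff."""
    p = t.rows["p_perm"].to_numpy(dtype=float)
    total = int(np.isfinite(p).sum())
    counts = [int(np.sum(p[np.isfinite(p)] < thr)) for thr in thresholds]
    fractions = [cnt / total if total else 0.0 for cnt in counts]
    return SignificanceTally(
        thresholds=list(thresholds), counts=counts, fractions=fractions
    )
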