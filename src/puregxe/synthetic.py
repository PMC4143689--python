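"""Synthetic cohorts for testing every stage of the pipeline.

The generator emulates the shape of a small unrelated blood-pressure
cohort: Hardy-Weinberg genotypes with per-SNP minor allele frequencies
drawn from a range, an age distribution built from a two-component normal
mixture (so a two-means cut lands near the component boundary), binary
smoking and medication indicators, and a quantitative trait (mmHg scale)
assembled from genetic main effects, environmental main effects, pure
(no-marginal) gene-age interactions, regime-switch effects that are active
only in one age range, and Gaussian noise.

Pure interactions are constructed as beta * (g - E[g]) * (z - E[z]) with z
the over-threshold age indicator and both expectations taken under the
population distribution, so the marginal association of the SNP and of the
age group vanish in expectation; finite samples show them only at sampling
noise scale.  Regime-switch SNPs get the additive effect beta * g only
within one age regime, producing disjoint top rankings between age
subgroups.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .genio import CohortTable, GenotypeMatrix, SNPRecord, write_table, write_vcf

__all__ = ["CausalSNP", "EnvSpec", "SimConfig", "simulate_cohort",
           "write_fixture"]


@dataclass(frozen=True)
class CausalSNP:
    """One causal SNP: positional index, effect kind and size (mmHg)."""

    index: int
    kind: str            # "main" | "pure-interaction" | "regime-switch"
    beta: float
    regime: str = "older"  # regime-switch only: "older" or "younger"

    _KINDS = ("main", "pure-interaction", "regime-switch")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.regime not in ("older", "younger"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass(frozen=True)
class EnvSpec:
    """Environment distributions: an age mixture and two binary exposures.

    Age is a two-component normal mixture; the default means of 44 and 67
    years with sd 8 and a 0.58 weight on the younger component give a
    bimodal-ish distribution whose exact two-means cut sits at ~55 years
    in the population, so the estimated dichotomy coincides with the
    generator's own age threshold (a cohort split near 55, with the
    younger group the slight majority).
    """

    age_means: tuple[float, float] = (44.0, 67.0)
    age_sds: tuple[float, float] = (8.0, 8.0)
    age_weight_young: float = 0.58
    smoke_prev: float = 0.25
    medication_prev: float = 0.30

    def p_older(self, threshold: float) -> float:
        """Population probability that age exceeds ``threshold``."""
        w = self.age_weight_young
        return float(
            w * norm.sf(threshold, self.age_means[0], self.age_sds[0])
            + (1 - w) * norm.sf(threshold, self.age_means[1], self.age_sds[1])
        )


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults reflect a small unrelated cohort: 130 samples, 200 SNPs with
    MAF uniform on [0.05, 0.5], a systolic-pressure-like trait with a
    baseline of 120 mmHg, a 0.4 mmHg/year age slope, modest smoking and
    medication effects, and 10 mmHg residual noise.
    """

    n_samples: int = 130
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    env: EnvSpec = field(default_factory=EnvSpec)
    causal: list[CausalSNP] = field(default_factory=list)
    trait_name: str = "SBP"
    baseline: float = 120.0
    age_slope: float = 0.4       # mmHg per year
    smoke_effect: float = 4.0    # mmHg
    medication_effect: float = -3.0  # mmHg
    age_threshold: float = 55.0  # defines the older regime / interaction z
    noise_sd: float = 10.0       # mmHg
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for cs in self.causal:
            if not 0 <= cs.index < self.n_snps:
                raise ValueError(
                    f"causal index {cs.index} outside [0, {self.n_snps})"
                )


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, CohortTable, dict]:
    """Draw one cohort; returns genotypes, cohort table and a truth record.

    Deterministic for a given config (including its seed): the same config
    yields bitwise-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_snps

    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=p)
    codes = rng.binomial(2, mafs[None, :], size=(n, p)).astype(np.int8)

    young = rng.random(n) < cfg.env.age_weight_young
    age = np.where(
        young,
        rng.normal(cfg.env.age_means[0], cfg.env.age_sds[0], size=n),
        rng.normal(cfg.env.age_means[1], cfg.env.age_sds[1], size=n),
    )
    smoke = (rng.random(n) < cfg.env.smoke_prev).astype(float)
    med = (rng.random(n) < cfg.env.medication_prev).astype(float)

    z = (age > cfg.age_threshold).astype(float)
    p_old = cfg.env.p_older(cfg.age_threshold)

    y = (
        cfg.baseline
        + cfg.age_slope * age
        + cfg.smoke_effect * smoke
        + cfg.medication_effect * med
        + rng.normal(0.0, cfg.noise_sd, size=n)
    )
    for cs in cfg.causal:
        gj = codes[:, cs.index].astype(float)
        if cs.kind == "main":
            y = y + cs.beta * gj
        elif cs.kind == "pure-interaction":
            # population-centered product: no marginal G or E association
            y = y + cs.beta * (gj - 2 * mafs[cs.index]) * (z - p_old)
        else:  # regime-switch
            active = z if cs.regime == "older" else 1.0 - z
            y = y + cs.beta * gj * active

    samples = [f"S{i:04d}" for i in range(n)]
    snps = [
        SNPRecord(
            id=f"snp{j:05d}", chrom="3", pos=1000 * (j + 1),
            ref="A", alt="G",
        )
        for j in range(p)
    ]
    g = GenotypeMatrix(samples=samples, snps=snps, codes=codes)
    c = CohortTable(
        samples=list(samples),
        traits={cfg.trait_name: y},
        environments={"age": age, "smoke": smoke, "medication": med},
    )
    truth = {
        "causal": [asdict(cs) for cs in cfg.causal],
        "causal_ids": [snps[cs.index].id for cs in cfg.causal],
        "mafs": mafs,
        "age_threshold": cfg.age_threshold,
        "p_older": p_old,
        "seed": cfg.seed,
    }
    return g, c, truth


def write_fixture(
    g: GenotypeMatrix, c: CohortTable, out_dir: str | Path
) -> dict[str, Path]:
    """Write a cohort as VCF + cohort TSV consumable by :mod:`genio`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / "genotypes.vcf"
    cohort_path = out_dir / "cohort.tsv"
    write_vcf(g, vcf_path)
    write_table(c, cohort_path)
    return {"vcf": vcf_path, "cohort": cohort_path}
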