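"""Synthetic HapMap-style study generator.

Emulates the inputs a genotyping array produces for a case-control or trio
study: biallelic SNP calls per donor under Hardy-Weinberg equilibrium at a
configurable allele-A frequency spectrum, a small missing-call rate, optional
planted case/control allele-frequency differences, and parent-child trios
with a controllable transmission probability.

Defaults mirror a reduced HapMap-like panel: 270 donors (the classic HapMap
release size), a 1000-SNP panel (a down-sampled stand-in for a 500K array),
allele-A frequencies uniform on [0.1, 0.5] (a common post-QC MAF window),
a 1% missing-call rate, and 500 trios.  What the generator deliberately does
not model: linkage disequilibrium between SNPs, population stratification and
realistic MAF spectra — each SNP is independent.

All draws come from one ``numpy`` Generator seeded from the config, so any
run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .genotypes import GenotypeMatrix, PhenotypeTable, TrioStructure

import pandas as pd

_CALL_CODES = np.array(["AA", "AB", "BB", "NN"])


@dataclass(frozen=True)
class PlantedSnp:
    """A SNP regenerated with different allele-A frequencies in cases and
    controls (equal frequencies = null)."""

    index: int
    f_case: float
    f_ctrl: float


@dataclass(frozen=True)
class SimulationConfig:
    n_donors: int = 270
    n_snps: int = 1000
    #: fixed allele-A frequency, or a (low, high) uniform range per SNP
    maf: float | tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.01
    planted: tuple[PlantedSnp, ...] = ()
    trio_count: int = 500
    #: probability a heterozygous parent transmits allele A; 0.5 is the null
    transmission_prob: float = 0.5
    #: SNP indices the transmission distortion applies to; None = all SNPs
    distorted_snps: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = self.maf if isinstance(self.maf, tuple) else (self.maf,)
        for f in freqs:
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"allele frequency {f} outside [0,1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate outside [0,1]")
        if not 0.0 <= self.transmission_prob <= 1.0:
            raise ConfigurationError("transmission_prob outside [0,1]")
        for p in self.planted:
            if not 0 <= p.index < self.n_snps:
                raise ConfigurationError(f"planted SNP index {p.index} out of range")
            for f in (p.f_case, p.f_ctrl):
                if not 0.0 <= f <= 1.0:
                    raise ConfigurationError(f"planted frequency {f} outside [0,1]")


def _snp_frequencies(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.maf, tuple):
        lo, hi = cfg.maf
        return rng.uniform(lo, hi, size=cfg.n_snps)
    return np.full(cfg.n_snps, float(cfg.maf))


def _hwe_calls(f: float, n: int, missing_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Genotype codes 0=AA,1=AB,2=BB under HWE at allele-A frequency f,
    with independent missingness."""
    codes = rng.choice(3, size=n, p=[f * f, 2 * f * (1 - f), (1 - f) ** 2])
    if missing_rate > 0:
        codes = np.where(rng.random(n) < missing_rate, 3, codes)
    return codes


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """HWE genotype matrix at the configured frequency spectrum."""
    rng = np.random.default_rng(cfg.seed)
    freqs = _snp_frequencies(cfg, rng)
    calls = [
        list(_CALL_CODES[_hwe_calls(f, cfg.n_donors, cfg.missing_rate, rng)])
        for f in freqs
    ]
    return GenotypeMatrix(
        snp_ids=_ids("snp", cfg.n_snps),
        donor_ids=_ids("d", cfg.n_donors),
        calls=calls,
    )


def plant_association(
    cfg: SimulationConfig, matrix: GenotypeMatrix, case_ids: Sequence[str]
) -> GenotypeMatrix:
    """Regenerate the planted SNPs with case/control-specific frequencies;
    all other rows are passed through untouched."""
    if not cfg.planted:
        return matrix
    rng = np.random.default_rng([cfg.seed, 1])
    case_set = set(case_ids)
    case_cols = [i for i, d in enumerate(matrix.donor_ids) if d in case_set]
    ctrl_cols = [i for i, d in enumerate(matrix.donor_ids) if d not in case_set]
    calls = [list(row) for row in matrix.calls]
    for p in cfg.planted:
        row = calls[p.index]
        case_calls = _CALL_CODES[_hwe_calls(p.f_case, len(case_cols), cfg.missing_rate, rng)]
        ctrl_calls = _CALL_CODES[_hwe_calls(p.f_ctrl, len(ctrl_cols), cfg.missing_rate, rng)]
        for col, call in zip(case_cols, case_calls):
            row[col] = str(call)
        for col, call in zip(ctrl_cols, ctrl_calls):
            row[col] = str(call)
    return GenotypeMatrix(list(matrix.snp_ids), list(matrix.donor_ids), calls)


def _transmit(parent_codes: np.ndarray, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Allele transmitted by each parent: 0 = A, 1 = B.  Homozygotes are
    forced; heterozygotes transmit A with probability tau."""
    out = np.where(parent_codes == 0, 0, 1)
    het = parent_codes == 1
    out = np.where(het, (rng.random(parent_codes.shape) >= tau).astype(int), out)
    return out


def simulate_trios(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TrioStructure]:
    """Parent-child trios: parents under HWE, children by Mendelian
    transmission except that heterozygous parents transmit allele A with
    probability tau at the distorted SNPs (tau = 0.5 everywhere is the null).

    Donor columns are laid out child, mother, father per trio.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    freqs = _snp_frequencies(cfg, rng)
    n_t = cfg.trio_count
    n_donors = 3 * n_t
    distorted = (
        set(cfg.distorted_snps) if cfg.distorted_snps is not None else None
    )
    calls: list[list[str]] = []
    for s, f in enumerate(freqs):
        tau = cfg.transmission_prob if (distorted is None or s in distorted) else 0.5
        mothers = _hwe_calls(f, n_t, 0.0, rng)
        fathers = _hwe_calls(f, n_t, 0.0, rng)
        children = _transmit(mothers, tau, rng) + _transmit(fathers, tau, rng)
        row = np.empty(n_donors, dtype=int)
        row[0::3] = children
        row[1::3] = mothers
        row[2::3] = fathers
        if cfg.missing_rate > 0:
            row = np.where(rng.random(n_donors) < cfg.missing_rate, 3, row)
        calls.append(list(_CALL_CODES[row]))
    donor_ids = []
    trios = []
    for t in range(n_t):
        donor_ids += [f"t{t:04d}c", f"t{t:04d}m", f"t{t:04d}f"]
        trios.append((3 * t, 3 * t + 1, 3 * t + 2))
    return (
        GenotypeMatrix(_ids("snp", cfg.n_snps), donor_ids, calls),
        TrioStructure(trios),
    )


def simulate_phenotypes(
    cfg: SimulationConfig, case_fraction: float, donor_ids: Sequence[str] | None = None
) -> tuple[PhenotypeTable, list[str]]:
    """Phenotype table built so that the criterion ``"has_disease"`` recovers
    the intended case set exactly.  Also carries an independent integer
    ``age`` (uniform 30..79) for compound-criterion exercises.

    Returns (table, intended case IDs).
    """
    if not 0.0 <= case_fraction <= 1.0:
        raise ConfigurationError("case_fraction outside [0,1]")
    rng = np.random.default_rng([cfg.seed, 3])
    ids = list(donor_ids) if donor_ids is not None else _ids("d", cfg.n_donors)
    n = len(ids)
    n_cases = round(case_fraction * n)
    case_cols = rng.choice(n, size=n_cases, replace=False)
    flags = np.zeros(n, dtype=bool)
    flags[case_cols] = True
    ages = rng.integers(30, 80, size=n)
    df = pd.DataFrame({"has_disease": flags, "age": ages}, index=ids)
    table = PhenotypeTable(donor_ids=ids, data=df)
    return table, [ids[i] for i in sorted(case_cols)]


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of the config with a different seed (replicate runs)."""
    return replace(cfg, seed=seed)
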