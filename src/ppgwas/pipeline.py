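"""End-to-end secure runs: share, form cohorts, tabulate, test, decide.

This is the library-level workhorse behind the CLI; tests and the
reproduction script drive it directly.  Every run verifies the ring-width
overflow bound up front, executes a data-independent schedule of secure
operations, and opens nothing but the per-SNP decision bits (plus the
undefined-statistic flags and, for the FDR procedure, the rejection count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .assoc import (
    RationalStat,
    TrendWeights,
    chi2_independence,
    chi2_proportion,
    cochran_armitage,
    tdt,
)
from .cohort import IndexVector, complement, evaluate_criterion, index_from_plaintext
from .contingency import allele_table, genotype_table, tdt_counts_for_snp
from .errors import ConfigurationError
from .genotypes import (
    GenotypeMatrix,
    PhenotypeTable,
    SharedGenotypeDB,
    TrioStructure,
    share_database,
    share_phenotypes,
)
from .mpc import Engine, RingConfig
from .significance import (
    DEFAULT_Q,
    DecisionVector,
    bh_ring_width_check,
    bonferroni,
    chi2_critical_rational,
    decide_all,
    ring_width_check,
    secure_bh,
)

TESTS = ("chi2", "chi2prop", "catt", "tdt")
CORRECTIONS = ("none", "bonferroni", "bh")


@dataclass(frozen=True)
class RunConfig:
    """Public parameters of one secure analysis run."""

    test: str = "chi2"
    alpha: float = 0.05
    correction: str = "bonferroni"
    q_precision: int = DEFAULT_Q
    ring_k: int = 128
    seed: int = 0
    weights: TrendWeights = field(default_factory=TrendWeights)

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ConfigurationError(f"unknown test {self.test!r}; choose from {TESTS}")
        if self.correction not in CORRECTIONS:
            raise ConfigurationError(
                f"unknown correction {self.correction!r}; choose from {CORRECTIONS}"
            )

    def check_ring(self, n_donors: int) -> None:
        check = bh_ring_width_check if self.correction == "bh" else ring_width_check
        ok, min_k = check(self.ring_k, n_donors, self.q_precision)
        if not ok:
            raise ConfigurationError(
                f"ring k={self.ring_k} cannot hold the significance comparison for "
                f"{n_donors} donors at q={self.q_precision}; need k >= {min_k}"
            )


def compute_statistics(
    engine: Engine,
    db: SharedGenotypeDB,
    cfg: RunConfig,
    cases: IndexVector | None = None,
    controls: IndexVector | None = None,
    trios: TrioStructure | None = None,
) -> list[RationalStat]:
    """Shared statistic fractions for every SNP in the database."""
    stats: list[RationalStat] = []
    if cfg.test == "tdt":
        if trios is None:
            raise ConfigurationError("tdt requires a trio structure")
        for i in range(db.n_snps):
            stats.append(tdt(engine, tdt_counts_for_snp(engine, db, i, trios)))
        return stats
    if cases is None or controls is None:
        raise ConfigurationError(f"test {cfg.test!r} requires case and control vectors")
    for i in range(db.n_snps):
        if cfg.test in ("chi2", "chi2prop"):
            table = allele_table(engine, cases, controls, db.fA[i], db.fB[i])
            fn = chi2_independence if cfg.test == "chi2" else chi2_proportion
            stats.append(fn(engine, table))
        else:
            gt = genotype_table(
                engine, cases, controls, db.fA[i], db.fB[i], db.hAA[i], db.hBB[i]
            )
            stats.append(cochran_armitage(engine, gt, cfg.weights))
    return stats


def decide_statistics(
    engine: Engine,
    stats: Sequence[RationalStat],
    snp_ids: Sequence[str],
    cfg: RunConfig,
) -> DecisionVector:
    if cfg.correction == "bh":
        return secure_bh(engine, stats, cfg.alpha, snp_ids, cfg.q_precision)
    if cfg.correction == "bonferroni":
        th = bonferroni(cfg.alpha, len(stats), cfg.q_precision)
    else:
        th = chi2_critical_rational(cfg.alpha, cfg.q_precision)
    return decide_all(engine, stats, th, snp_ids, correction=cfg.correction)


def run_secure(
    matrix: GenotypeMatrix,
    cfg: RunConfig,
    case_ids: Sequence[str] | None = None,
    phenotypes: PhenotypeTable | None = None,
    criterion: str | None = None,
    trios: TrioStructure | None = None,
    engine: Engine | None = None,
) -> tuple[DecisionVector, Engine]:
    """Full secure pipeline from a staged genotype matrix.

    Cohorts come from explicit ``case_ids`` (scenario 1) or from an
    inclusion ``criterion`` evaluated obliviously over shared ``phenotypes``
    (scenario 2); controls are the in-cohort complement of the cases.  The
    TDT mode takes a trio structure instead of cohorts.
    """
    cfg.check_ring(matrix.n_donors)
    if engine is None:
        engine = Engine(RingConfig(cfg.ring_k), seed=cfg.seed)
    db = share_database(matrix, engine)

    cases = controls = None
    if cfg.test != "tdt":
        if case_ids is not None:
            cases = index_from_plaintext(case_ids, matrix.donor_ids, engine)
        elif criterion is not None and phenotypes is not None:
            pdb = share_phenotypes(phenotypes, engine)
            cases = evaluate_criterion(pdb, criterion, engine)
        else:
            raise ConfigurationError(
                "need case_ids (scenario 1) or phenotypes+criterion (scenario 2)"
            )
        controls = complement(cases)

    stats = compute_statistics(engine, db, cfg, cases, controls, trios)
    dv = decide_statistics(engine, stats, db.snp_ids, cfg)
    dv.meta.update(
        {
            "ring_k": cfg.ring_k,
            "seed": cfg.seed,
            "scenario": "plaintext-cohort" if case_ids is not None else
                        ("criterion" if criterion is not None else "trio"),
            "bus": engine.bus.snapshot(),
        }
    )
    return dv, engine


def run_reference(
    matrix: GenotypeMatrix,
    cfg: RunConfig,
    case_ids: Sequence[str] | None = None,
    phenotypes: PhenotypeTable | None = None,
    criterion: str | None = None,
    trios: TrioStructure | None = None,
):
    """The plaintext reference for the same configuration; returns a
    :class:`ppgwas.reference.PlainDecisions`."""
    from . import reference
    from .reference import PlainDecisions

    if cfg.test == "tdt":
        fractions = reference.statistic_fractions(matrix, "tdt", trios=trios)
    else:
        case_mask, ctrl_mask = reference.cohort_masks(
            matrix,
            case_ids=case_ids,
            phenotypes=None if phenotypes is None else phenotypes.data,
            criterion=criterion,
        )
        fractions = reference.statistic_fractions(
            matrix, cfg.test, case_mask, ctrl_mask, weights=cfg.weights
        )
    if cfg.correction == "bh":
        return reference.bh_plain(fractions, cfg.alpha, matrix.snp_ids, cfg.q_precision)
    if cfg.correction == "bonferroni":
        th = bonferroni(cfg.alpha, len(fractions), cfg.q_precision)
    else:
        th = chi2_critical_rational(cfg.alpha, cfg.q_precision)
    decisions, undefined = reference.decide_fractions(fractions, th)
    return PlainDecisions(
        snp_ids=list(matrix.snp_ids),
        decisions=decisions,
        undefined=undefined,
        rejection_count=sum(decisions),
    )
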