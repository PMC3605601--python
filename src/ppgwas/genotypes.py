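"""Genotype and phenotype staging, allele-count encoding, and secret sharing.

Each biallelic call is stored as a pair of allele counts ``(fA, fB)``:
``AA -> (2,0)``, ``AB -> (1,1)``, ``BB -> (0,2)`` and a missing call
``NN -> (0,0)``.  The count form turns cohort tabulation into inner products,
which is what makes the secure pipeline cheap: no string comparisons are ever
needed on shares.

Alongside ``fA``/``fB`` the shared database carries two redundant 0/1 flag
rows per SNP, ``hAA = [call == AA]`` and ``hBB = [call == BB]``.  With these,
every genotype-class count in the 2x3 table and the TDT assembly is a pure
dot product with an index vector (degree <= 2 overall), avoiding both secure
comparisons and divisions by 2 — which have no multiplicative inverse on a
ring of modulus 2^k.

Missing calls contribute zero to every allele and genotype count, so donors
with an ``NN`` call at a SNP silently drop out of that SNP's totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import GenotypeImportError, ProtocolError, RangeError
from .mpc import Engine, RingConfig, SharedVector

logger = logging.getLogger(__name__)

CALLS = ("AA", "AB", "BB", "NN")

#: call -> (fA, fB) allele-count pair
ENCODING: dict[str, tuple[int, int]] = {
    "AA": (2, 0),
    "AB": (1, 1),
    "BB": (0, 2),
    "NN": (0, 0),
}

DECODING: dict[tuple[int, int], str] = {v: k for k, v in ENCODING.items()}


def encode_genotype(call: str) -> tuple[int, int]:
    """Map a diploid call to its allele-count pair.

    Raises :class:`GenotypeImportError` for anything outside AA/AB/BB/NN —
    other tokens must be normalised (or rejected) at import time.
    """
    try:
        return ENCODING[call]
    except KeyError:
        raise GenotypeImportError(f"unknown genotype call {call!r}; expected one of {CALLS}")


@dataclass
class GenotypeMatrix:
    """Plaintext staging matrix: SNPs x donors of AA/AB/BB/NN calls."""

    snp_ids: list[str]
    donor_ids: list[str]
    calls: list[list[str]]

    def __post_init__(self) -> None:
        if len(set(self.donor_ids)) != len(self.donor_ids):
            raise GenotypeImportError("duplicate donor IDs")
        if len(self.calls) != len(self.snp_ids):
            raise GenotypeImportError(
                f"{len(self.snp_ids)} SNP ids but {len(self.calls)} call rows"
            )
        n = len(self.donor_ids)
        for si, row in zip(self.snp_ids, self.calls):
            if len(row) != n:
                raise GenotypeImportError(f"ragged row for SNP {si}: {len(row)} != {n}")
            for di, call in zip(self.donor_ids, row):
                if call not in ENCODING:
                    raise GenotypeImportError(
                        f"unknown genotype call {call!r} at SNP {si}, donor {di}"
                    )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)


def import_tsv(path) -> GenotypeMatrix:
    """Read the genotype TSV dialect: header ``snp_id<TAB>donor...``, one row
    per SNP with AA/AB/BB/NN calls."""
    snp_ids: list[str] = []
    calls: list[list[str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "snp_id":
            raise GenotypeImportError(
                f"{path}: first header field must be 'snp_id', got {header[:1]}"
            )
        donor_ids = header[1:]
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise GenotypeImportError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            snp_ids.append(parts[0])
            calls.append(parts[1:])
    return GenotypeMatrix(snp_ids, donor_ids, calls)


def export_tsv(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(matrix.donor_ids) + "\n")
        for sid, row in zip(matrix.snp_ids, matrix.calls):
            fh.write(sid + "\t" + "\t".join(row) + "\n")


def import_vcf(path) -> GenotypeMatrix:
    """Read biallelic GT calls from a VCF.

    The REF allele maps to allele A and the first ALT to allele B.  Sites with
    more than one ALT are skipped with a logged warning.  Any half-call or
    missing allele ('.') yields NN — conservative missing-data handling.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donor_ids = list(vcf.samples)
    snp_ids: list[str] = []
    calls: list[list[str]] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multi-allelic site %s:%s (%d ALT alleles)",
                variant.CHROM, variant.POS, len(variant.ALT),
            )
            continue
        sid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        row = []
        for g in variant.genotypes:  # [allele0, allele1, phased]
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                row.append("NN")
            else:
                alt = a0 + a1
                if a0 > 1 or a1 > 1:
                    raise GenotypeImportError(
                        f"{path}: malformed GT at {sid} (allele index > 1 at biallelic site)"
                    )
                row.append(("AA", "AB", "BB")[alt])
        snp_ids.append(sid)
        calls.append(row)
    return GenotypeMatrix(snp_ids, donor_ids, calls)


# --------------------------------------------------------------------------
# shared genotype database

ROW_LABELS = ("fA", "fB", "hAA", "hBB")


@dataclass
class SharedGenotypeDB:
    """Secret-shared genotype database: per SNP, four shared rows (fA, fB and
    the redundant hAA/hBB flags), one column per donor.  Donor IDs stay
    public by default; they are needed only for trio linkage and for
    analyst-supplied cohorts."""

    snp_ids: list[str]
    donor_ids: list[str]
    ring: RingConfig
    fA: list[SharedVector]
    fB: list[SharedVector]
    hAA: list[SharedVector]
    hBB: list[SharedVector]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)

    def rows_for(self, snp_index: int) -> dict[str, SharedVector]:
        return {
            "fA": self.fA[snp_index],
            "fB": self.fB[snp_index],
            "hAA": self.hAA[snp_index],
            "hBB": self.hBB[snp_index],
        }


def share_database(matrix: GenotypeMatrix, engine: Engine) -> SharedGenotypeDB:
    """Encode every call and secret-share the four per-SNP rows."""
    fA_rows, fB_rows, hAA_rows, hBB_rows = [], [], [], []
    for row in matrix.calls:
        enc = [ENCODING[c] for c in row]
        fA_rows.append(engine.share_vector([e[0] for e in enc]))
        fB_rows.append(engine.share_vector([e[1] for e in enc]))
        hAA_rows.append(engine.share_vector([1 if c == "AA" else 0 for c in row]))
        hBB_rows.append(engine.share_vector([1 if c == "BB" else 0 for c in row]))
    return SharedGenotypeDB(
        snp_ids=list(matrix.snp_ids),
        donor_ids=list(matrix.donor_ids),
        ring=engine.ring,
        fA=fA_rows,
        fB=fB_rows,
        hAA=hAA_rows,
        hBB=hBB_rows,
    )


def reconstruct_database(db: SharedGenotypeDB, engine: Engine) -> GenotypeMatrix:
    """Pool all shares and decode back to calls (test / authorised use only)."""
    calls: list[list[str]] = []
    for i in range(db.n_snps):
        fa = engine.reconstruct_vector(db.fA[i])
        fb = engine.reconstruct_vector(db.fB[i])
        row = []
        for a, b in zip(fa, fb):
            try:
                row.append(DECODING[(a, b)])
            except KeyError:
                raise ProtocolError(
                    f"reconstructed pair ({a},{b}) is not a valid allele-count encoding"
                )
        calls.append(row)
    return GenotypeMatrix(list(db.snp_ids), list(db.donor_ids), calls)


# --------------------------------------------------------------------------
# phenotypes

@dataclass
class PhenotypeTable:
    """Per-donor clinical attributes: boolean flags (e.g. has_disease) and
    non-negative integers (e.g. age)."""

    donor_ids: list[str]
    data: pd.DataFrame  # indexed by donor_id

    def __post_init__(self) -> None:
        if list(self.data.index) != list(self.donor_ids):
            self.data = self.data.loc[self.donor_ids]
        for col in self.data.columns:
            kind = self.attribute_kind(col)
            if kind == "bool":
                vals = set(self.data[col].astype(int).unique())
                if not vals <= {0, 1}:
                    raise GenotypeImportError(f"boolean attribute {col!r} has values {vals}")
            else:
                if (self.data[col] < 0).any():
                    raise GenotypeImportError(
                        f"integer attribute {col!r} has negative values; "
                        "phenotype integers must be non-negative"
                    )

    def attribute_kind(self, name: str) -> str:
        dtype = self.data[name].dtype
        return "bool" if dtype == bool else "int"

    @property
    def attributes(self) -> list[str]:
        return list(self.data.columns)


def import_phenotypes_csv(path) -> PhenotypeTable:
    """Phenotype CSV: a ``donor_id`` column plus attribute columns; columns
    whose values are only 0/1 (or true/false) are treated as booleans."""
    df = pd.read_csv(path)
    if "donor_id" not in df.columns:
        raise GenotypeImportError(f"{path}: phenotype CSV needs a 'donor_id' column")
    df = df.set_index("donor_id")
    for col in df.columns:
        series = df[col]
        if series.dtype == bool:
            continue
        uniq = set(pd.unique(series))
        if uniq <= {0, 1, True, False}:
            df[col] = series.astype(bool)
        else:
            df[col] = series.astype(int)
    return PhenotypeTable(donor_ids=list(df.index), data=df)


def export_phenotypes_csv(table: PhenotypeTable, path) -> None:
    out = table.data.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index_label="donor_id")


@dataclass
class SharedPhenotypeDB:
    donor_ids: list[str]
    ring: RingConfig
    kinds: dict[str, str]                 # attribute -> "bool" | "int"
    columns: dict[str, SharedVector] = field(default_factory=dict)

    @property
    def attributes(self) -> list[str]:
        return list(self.columns)


def share_phenotypes(table: PhenotypeTable, engine: Engine) -> SharedPhenotypeDB:
    """Secret-share each attribute column.  Integer attributes must respect
    the comparison contract (< 2^(k-2)) so criteria can use secure >=."""
    bound = 1 << (engine.ring.k - 2)
    kinds = {}
    cols = {}
    for name in table.attributes:
        kind = table.attribute_kind(name)
        values = [int(v) for v in table.data[name]]
        if any(v >= bound for v in values):
            raise RangeError(
                f"attribute {name!r} exceeds the secure-comparison bound 2^(k-2)"
            )
        kinds[name] = kind
        cols[name] = engine.share_vector(values)
    return SharedPhenotypeDB(
        donor_ids=list(table.donor_ids), ring=engine.ring, kinds=kinds, columns=cols
    )


# --------------------------------------------------------------------------
# trios

@dataclass
class TrioStructure:
    """Parent-child trio linkage: per trio the (child, mother, father)
    donor-column indices, all distinct and in range."""

    trios: list[tuple[int, int, int]]

    def validate(self, n_donors: int) -> None:
        for t in self.trios:
            if len(set(t)) != 3:
                raise ProtocolError(f"trio {t} has repeated donor columns")
            if any(not 0 <= i < n_donors for i in t):
                raise ProtocolError(f"trio {t} has a column index outside 0..{n_donors-1}")

    def __len__(self) -> int:
        return len(self.trios)

    @property
    def children(self) -> list[int]:
        return [t[0] for t in self.trios]

    @property
    def mothers(self) -> list[int]:
        return [t[1] for t in self.trios]

    @property
    def fathers(self) -> list[int]:
        return [t[2] for t in self.trios]

    @classmethod
    def from_ids(
        cls, rows: Iterable[tuple[str, str, str]], donor_ids: Sequence[str]
    ) -> "TrioStructure":
        pos = {d: i for i, d in enumerate(donor_ids)}
        trios = []
        for child, mother, father in rows:
            try:
                trios.append((pos[child], pos[mother], pos[father]))
            except KeyError as e:
                raise GenotypeImportError(f"trio references unknown donor ID {e.args[0]!r}")
        return cls(trios)


def import_trios_tsv(path, donor_ids: Sequence[str]) -> TrioStructure:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["child_id", "mother_id", "father_id"]:
            raise GenotypeImportError(
                f"{path}: trio TSV header must be child_id/mother_id/father_id"
            )
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise GenotypeImportError(f"{path}: malformed trio row {parts}")
            rows.append(tuple(parts))
    return TrioStructure.from_ids(rows, donor_ids)


def export_trios_tsv(trios: TrioStructure, donor_ids: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("child_id\tmother_id\tfather_id\n")
        for c, m, f in trios.trios:
            fh.write(f"{donor_ids[c]}\t{donor_ids[m]}\t{donor_ids[f]}\n")
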