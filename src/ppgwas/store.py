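"""Per-host share-store files.

Each host persists *its own* additive shares; a single store (or any two)
is uniformly random noise, and reconstruction requires all three.  Two
dialects, both bit-exact round-trip:

* ``jsonl`` — a JSON header line followed by one JSON array per row; human
  greppable, used for small data and fixtures;
* ``packed`` — the same header line followed by row-major little-endian
  fixed-width values (k/8 bytes each); used for large matrices.

The header records format version, ring width, shape, row labels and column
IDs, plus free-form metadata (e.g. allele orientation for VCF imports).
The four-row-per-SNP layout (fA, fB, hAA, hBB) is format version 2; version
1 (fA, fB only) is not emitted by this package.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .errors import ProtocolError, StoreFormatError
from .genotypes import ROW_LABELS, SharedGenotypeDB, SharedPhenotypeDB
from .mpc import N_HOSTS, RingConfig, SharedVector

FORMAT_NAME = "ppgwas-shares"
FORMAT_VERSION = 2


@dataclass
class HostStore:
    """One host's view of a named row-major share matrix."""

    host_id: int
    ring: RingConfig
    kind: str                      # "genotype" | "phenotype" | "index" | "stats"
    row_labels: list[str]
    col_ids: list[str]
    rows: list[list[int]]          # this host's share values
    meta: dict

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.row_labels):
            raise StoreFormatError(
                f"{len(self.row_labels)} row labels but {len(self.rows)} rows"
            )


def write_host_store(store: HostStore, path, dialect: str = "jsonl") -> None:
    header = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "dialect": dialect,
        "kind": store.kind,
        "k": store.ring.k,
        "host_id": store.host_id,
        "n_rows": len(store.rows),
        "n_cols": len(store.col_ids),
        "row_labels": store.row_labels,
        "col_ids": store.col_ids,
        "meta": store.meta,
    }
    if dialect == "jsonl":
        with open(path, "w") as fh:
            fh.write(json.dumps(header) + "\n")
            for row in store.rows:
                fh.write(json.dumps(row) + "\n")
    elif dialect == "packed":
        if store.ring.k % 8 != 0:
            raise StoreFormatError("packed dialect requires k to be a multiple of 8")
        width = store.ring.k // 8
        with open(path, "wb") as fh:
            fh.write((json.dumps(header) + "\n").encode())
            for row in store.rows:
                for v in row:
                    fh.write(v.to_bytes(width, "little"))
    else:
        raise StoreFormatError(f"unknown share-store dialect {dialect!r}")


def read_host_store(path) -> HostStore:
    with open(path, "rb") as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError:
            raise StoreFormatError(f"{path}: unreadable share-store header")
        if header.get("format") != FORMAT_NAME:
            raise StoreFormatError(f"{path}: not a {FORMAT_NAME} file")
        if header.get("version") != FORMAT_VERSION:
            raise StoreFormatError(
                f"{path}: unsupported format version {header.get('version')}"
            )
        ring = RingConfig(header["k"])
        n_rows, n_cols = header["n_rows"], header["n_cols"]
        dialect = header["dialect"]
        rows: list[list[int]] = []
        if dialect == "jsonl":
            for i in range(n_rows):
                line = fh.readline()
                if not line:
                    raise StoreFormatError(f"{path}: truncated after {i} rows")
                rows.append(json.loads(line))
        elif dialect == "packed":
            width = ring.k // 8
            for i in range(n_rows):
                blob = fh.read(width * n_cols)
                if len(blob) != width * n_cols:
                    raise StoreFormatError(f"{path}: truncated after {i} rows")
                rows.append(
                    [int.from_bytes(blob[j * width:(j + 1) * width], "little")
                     for j in range(n_cols)]
                )
        else:
            raise StoreFormatError(f"{path}: unknown dialect {dialect!r}")
    return HostStore(
        host_id=header["host_id"],
        ring=ring,
        kind=header["kind"],
        row_labels=header["row_labels"],
        col_ids=header["col_ids"],
        rows=rows,
        meta=header.get("meta", {}),
    )


# --------------------------------------------------------------------------
# genotype / phenotype / index-vector adapters

def _db_row_iter(db: SharedGenotypeDB):
    for i, sid in enumerate(db.snp_ids):
        for label, vec in db.rows_for(i).items():
            yield f"{sid}/{label}", vec


def write_genotype_stores(
    db: SharedGenotypeDB, host_dirs: Sequence[str | Path],
    dialect: str = "jsonl", meta: dict | None = None,
) -> None:
    """Write one ``genotypes.share`` file per host directory."""
    if len(host_dirs) != N_HOSTS:
        raise ProtocolError(f"expected {N_HOSTS} host directories")
    labels = [lab for lab, _ in _db_row_iter(db)]
    for h, d in enumerate(host_dirs):
        os.makedirs(d, exist_ok=True)
        rows = [vec.rows[h] for _, vec in _db_row_iter(db)]
        store = HostStore(
            host_id=h, ring=db.ring, kind="genotype",
            row_labels=labels, col_ids=list(db.donor_ids),
            rows=rows, meta=dict(meta or {}),
        )
        write_host_store(store, Path(d) / "genotypes.share", dialect)


def _load_stores(host_dirs: Sequence[str | Path], filename: str) -> list[HostStore]:
    if len(host_dirs) != N_HOSTS:
        raise ProtocolError(f"expected {N_HOSTS} host directories")
    stores = []
    for h, d in enumerate(host_dirs):
        path = Path(d) / filename
        if not path.exists():
            raise ProtocolError(
                f"host {h} store {path} is missing: reconstruction requires all "
                f"{N_HOSTS} shares (3-out-of-3 scheme)"
            )
        stores.append(read_host_store(path))
    ref = stores[0]
    for s in stores[1:]:
        if (s.ring, s.row_labels, s.col_ids, s.kind) != (ref.ring, ref.row_labels, ref.col_ids, ref.kind):
            raise ProtocolError(f"inconsistent host stores for {filename}")
    for h, s in enumerate(stores):
        if s.host_id != h:
            raise ProtocolError(f"store in slot {h} claims host_id {s.host_id}")
    return stores


def read_genotype_stores(host_dirs: Sequence[str | Path]) -> SharedGenotypeDB:
    stores = _load_stores(host_dirs, "genotypes.share")
    ref = stores[0]
    n_labels = len(ROW_LABELS)
    if len(ref.row_labels) % n_labels != 0:
        raise StoreFormatError("genotype store row count is not a multiple of 4")
    snp_ids = []
    per_label: dict[str, list[SharedVector]] = {lab: [] for lab in ROW_LABELS}
    for base in range(0, len(ref.row_labels), n_labels):
        sid = ref.row_labels[base].rsplit("/", 1)[0]
        snp_ids.append(sid)
        for off, lab in enumerate(ROW_LABELS):
            expect = f"{sid}/{lab}"
            if ref.row_labels[base + off] != expect:
                raise StoreFormatError(
                    f"unexpected row label {ref.row_labels[base + off]!r}, wanted {expect!r}"
                )
            rows = tuple(stores[h].rows[base + off] for h in range(N_HOSTS))
            per_label[lab].append(SharedVector(rows, ref.ring))  # type: ignore[arg-type]
    return SharedGenotypeDB(
        snp_ids=snp_ids, donor_ids=list(ref.col_ids), ring=ref.ring,
        fA=per_label["fA"], fB=per_label["fB"],
        hAA=per_label["hAA"], hBB=per_label["hBB"],
    )


def write_phenotype_stores(
    db: SharedPhenotypeDB, host_dirs: Sequence[str | Path], dialect: str = "jsonl"
) -> None:
    labels = list(db.columns)
    for h, d in enumerate(host_dirs):
        os.makedirs(d, exist_ok=True)
        store = HostStore(
            host_id=h, ring=db.ring, kind="phenotype",
            row_labels=labels, col_ids=list(db.donor_ids),
            rows=[db.columns[lab].rows[h] for lab in labels],
            meta={"kinds": db.kinds},
        )
        write_host_store(store, Path(d) / "phenotypes.share", dialect)


def read_phenotype_stores(host_dirs: Sequence[str | Path]) -> SharedPhenotypeDB:
    stores = _load_stores(host_dirs, "phenotypes.share")
    ref = stores[0]
    cols = {}
    for i, lab in enumerate(ref.row_labels):
        rows = tuple(stores[h].rows[i] for h in range(N_HOSTS))
        cols[lab] = SharedVector(rows, ref.ring)  # type: ignore[arg-type]
    return SharedPhenotypeDB(
        donor_ids=list(ref.col_ids), ring=ref.ring,
        kinds=dict(ref.meta["kinds"]), columns=cols,
    )


def write_index_stores(
    vectors: dict[str, SharedVector], donor_ids: Sequence[str],
    host_dirs: Sequence[str | Path], dialect: str = "jsonl",
) -> None:
    """Persist shared index vectors (e.g. 'case', 'control')."""
    labels = list(vectors)
    ring = vectors[labels[0]].ring
    for h, d in enumerate(host_dirs):
        os.makedirs(d, exist_ok=True)
        store = HostStore(
            host_id=h, ring=ring, kind="index",
            row_labels=labels, col_ids=list(donor_ids),
            rows=[vectors[lab].rows[h] for lab in labels],
            meta={},
        )
        write_host_store(store, Path(d) / "index.share", dialect)


def read_index_stores(host_dirs: Sequence[str | Path]) -> dict[str, SharedVector]:
    stores = _load_stores(host_dirs, "index.share")
    ref = stores[0]
    return {
        lab: SharedVector(tuple(stores[h].rows[i] for h in range(N_HOSTS)), ref.ring)  # type: ignore[arg-type]
        for i, lab in enumerate(ref.row_labels)
    }


def write_stats_stores(
    stats, snp_ids: Sequence[str], host_dirs: Sequence[str | Path],
    dialect: str = "jsonl",
) -> None:
    """Persist shared statistic fractions (rows ``m/<snp>``, ``n/<snp>`` per
    SNP) so significance can be decided later with ``decide-only``."""
    if not stats:
        raise ProtocolError("no statistics to persist")
    ring = stats[0].m.ring
    labels = []
    for sid in snp_ids:
        labels += [f"m/{sid}", f"n/{sid}"]
    for h, d in enumerate(host_dirs):
        os.makedirs(d, exist_ok=True)
        rows = []
        for st in stats:
            rows.append([st.m.values[h]])
            rows.append([st.n.values[h]])
        store = HostStore(
            host_id=h, ring=ring, kind="stats",
            row_labels=labels, col_ids=["value"],
            rows=rows, meta={"test": stats[0].test_id},
        )
        write_host_store(store, Path(d) / "stats.share", dialect)
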