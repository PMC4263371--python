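"""Shared domain types for the pooled-mutagenesis pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

_DNA = set("ACGT")


@dataclass(frozen=True)
class GeneRef:
    """A reference ORF used as a mutagenesis template."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id!r}: empty sequence")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: non-ACGT characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutationSpec:
    """A desired single-nucleotide substitution, 1-based coordinates."""

    gene_id: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self}: ref and alt are identical")
        if self.ref_base not in _DNA or self.alt_base not in _DNA:
            raise ValueError(f"{self}: bases must be one of ACGT")
        if self.position < 1:
            raise ValueError(f"{self}: position must be 1-based")

    @property
    def mutation_id(self) -> str:
        return f"{self.gene_id}_{self.ref_base}{self.position}{self.alt_base}"

    def validate_against(self, gene: GeneRef) -> None:
        if self.gene_id != gene.gene_id:
            raise ValueError(f"{self.mutation_id}: wrong gene {gene.gene_id}")
        if self.position > len(gene):
            raise ValueError(f"{self.mutation_id}: position beyond gene end")
        found = gene.sequence[self.position - 1]
        if found != self.ref_base:
            raise ValueError(
                f"{self.mutation_id}: reference base is {found}, "
                f"expected {self.ref_base}"
            )


@dataclass(frozen=True)
class ColonyTruth:
    """Ground truth for one picked colony in one pool."""

    mutation: MutationSpec
    pool_id: str
    success: bool
    unwanted: tuple[tuple[int, str], ...] = ()

    @property
    def colony_id(self) -> str:
        return f"{self.mutation.mutation_id}@{self.pool_id}"


@dataclass
class PoolManifest:
    """Which colony (gene, desired mutation) sits in which pool.

    ``pools`` preserves the order in which pools were created; downstream
    clone resolution prefers earlier pools.
    """

    records: list[dict] = field(default_factory=list)

    COLUMNS = ("colony_id", "gene_id", "position", "ref", "alt", "pool_id")

    def add(self, mutation: MutationSpec, pool_id: str) -> None:
        self.records.append(
            {
                "colony_id": f"{mutation.mutation_id}@{pool_id}",
                "gene_id": mutation.gene_id,
                "position": mutation.position,
                "ref": mutation.ref_base,
                "alt": mutation.alt_base,
                "pool_id": pool_id,
            }
        )

    @property
    def pools(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r["pool_id"], None)
        return list(seen)

    def mutations_in_pool(self, pool_id: str) -> list[MutationSpec]:
        return [
            MutationSpec(r["gene_id"], r["position"], r["ref"], r["alt"])
            for r in self.records
            if r["pool_id"] == pool_id
        ]

    def k(self, gene_id: str, pool_id: str) -> int:
        """Number of distinct attempted mutations for a gene in a pool."""
        return sum(
            1
            for r in self.records
            if r["gene_id"] == gene_id and r["pool_id"] == pool_id
        )

    def target_positions(self, pool_id: str) -> set[tuple[str, int]]:
        return {
            (r["gene_id"], r["position"])
            for r in self.records
            if r["pool_id"] == pool_id
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=list(self.COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PoolManifest":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "pool_id": str})
        manifest = cls()
        for row in df.itertuples(index=False):
            manifest.records.append(
                {
                    "colony_id": row.colony_id,
                    "gene_id": row.gene_id,
                    "position": int(row.position),
                    "ref": row.ref,
                    "alt": row.alt,
                    "pool_id": row.pool_id,
                }
            )
        return manifest

    def __iter__(self) -> Iterator[dict]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TruthTable:
    """All planted events of a simulated experiment."""

    colonies: list[ColonyTruth] = field(default_factory=list)

    def successes(self) -> list[ColonyTruth]:
        return [c for c in self.colonies if c.success]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "colony_id": c.colony_id,
                "gene_id": c.mutation.gene_id,
                "position": c.mutation.position,
                "ref": c.mutation.ref_base,
                "alt": c.mutation.alt_base,
                "pool_id": c.pool_id,
                "success": c.success,
                "unwanted": [[p, b] for p, b in c.unwanted],
            }
            for c in self.colonies
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        colonies = [
            ColonyTruth(
                mutation=MutationSpec(
                    d["gene_id"], d["position"], d["ref"], d["alt"]
                ),
                pool_id=d["pool_id"],
                success=d["success"],
                unwanted=tuple((p, b) for p, b in d["unwanted"]),
            )
            for d in payload
        ]
        return cls(colonies)

    def __len__(self) -> int:
        return len(self.colonies)


def read_fasta(path: str | Path) -> list[GeneRef]:
    from Bio import SeqIO

    return [
        GeneRef(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genes: Iterable[GeneRef], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")


def read_mutations_tsv(path: str | Path) -> list[MutationSpec]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        MutationSpec(r.gene_id, int(r.position), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]


def write_mutations_tsv(mutations: Iterable[MutationSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "position": m.position,
                "ref": m.ref_base,
                "alt": m.alt_base,
            }
            for m in mutations
        ]
    ).to_csv(path, sep="\t", index=False)
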