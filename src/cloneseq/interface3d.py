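"""SASA-based interaction interfaces and mutation locus classification.

Solvent-accessible surface areas are computed by Shrake-Rupley quadrature
with a 1.4 A probe radius on a deterministic spherical point set. A
residue is an interface residue when its ASA drops by more than 1 A^2
between the isolated chain and the complex; domain pairs become interface
domains either through a known domain-domain interaction plus at least
one interface residue per domain, or through five or more interface
residues per domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "StructureModel",
    "InterfaceAnnotation",
    "sasa",
    "interface_residues",
    "interface_domains",
    "classify_locus",
    "sphere_points",
]

PROBE_RADIUS = 1.4
DELTA_ASA_CUTOFF = 1.0
N_POINTS = 960

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
DEFAULT_RADIUS = 1.8

ResidueKey = tuple[str, int]  # (chain_id, residue number)


@dataclass(frozen=True)
class Atom:
    chain_id: str
    res_seq: int
    res_name: str
    name: str
    element: str
    coord: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("atom radius must be positive")
        if not all(np.isfinite(self.coord)):
            raise ValueError("non-finite atom coordinate")


@dataclass
class StructureModel:
    """Heavy-atom model: chains -> residues -> atoms."""

    atoms: list[Atom] = field(default_factory=list)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def subset(self, chain_ids: Sequence[str]) -> "StructureModel":
        wanted = set(chain_ids)
        return StructureModel([a for a in self.atoms if a.chain_id in wanted])

    def residues(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.res_seq), None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @classmethod
    def from_pdb(cls, path: str | Path) -> "StructureModel":
        """Read ATOM records; HETATM, waters and hydrogens are skipped."""
        atoms: list[Atom] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith(("ENDMDL", "END ")):
                    break
                if not line.startswith("ATOM"):
                    continue
                altloc = line[16]
                if altloc not in (" ", "A"):
                    continue
                element = line[76:78].strip() or line[12:16].strip()[0]
                element = element.upper()
                if element == "H" or element == "D":
                    continue
                res_name = line[17:20].strip()
                if res_name == "HOH":
                    continue
                atoms.append(
                    Atom(
                        chain_id=line[21].strip() or "A",
                        res_seq=int(line[22:26]),
                        res_name=res_name,
                        name=line[12:16].strip(),
                        element=element,
                        coord=(
                            float(line[30:38]),
                            float(line[38:46]),
                            float(line[46:54]),
                        ),
                        radius=VDW_RADII.get(element, DEFAULT_RADIUS),
                    )
                )
        return cls(atoms)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere points (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    model: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
) -> dict[ResidueKey, float]:
    """Per-residue solvent-accessible surface area in A^2.

    Per atom: the fraction of quadrature points on the expanded sphere
    (r_vdw + probe) not buried inside any neighbor's expanded sphere,
    times the expanded sphere's area; residue ASA sums its atoms.
    """
    if not model.atoms:
        raise ValueError("model has no atoms")
    coords = model.coords()
    radii = model.radii() + probe_radius
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * unit
        neighbors = tree.query_ball_point(coords[i], radii[i] + max_r)
        neighbors = [j for j in neighbors if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum(
                "ij,ij->i", pts - coords[j], pts - coords[j]
            )
            exposed &= d2 > radii[j] ** 2
            if not exposed.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.sum() / n_points

    out: dict[ResidueKey, float] = {}
    for atom, area in zip(model.atoms, areas):
        key = (atom.chain_id, atom.res_seq)
        out[key] = out.get(key, 0.0) + float(area)
    return out


@dataclass
class InterfaceAnnotation:
    """Per-residue burial on complex formation for one chain pair."""

    chain_pair: tuple[str, str]
    asa_unbound: dict[ResidueKey, float]
    asa_complex: dict[ResidueKey, float]
    delta_asa: dict[ResidueKey, float]
    interface_residues: set[ResidueKey]
    interface_domain_pairs: list[dict] = field(default_factory=list)

    def is_interface(self, residue: ResidueKey) -> bool:
        return residue in self.interface_residues


def interface_residues(
    complex_model: StructureModel,
    chain_pair: tuple[str, str],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
    cutoff: float = DELTA_ASA_CUTOFF,
) -> InterfaceAnnotation:
    """Residues buried by more than ``cutoff`` A^2 upon binding."""
    a, b = chain_pair
    present = set(complex_model.chains)
    for c in chain_pair:
        if c not in present:
            raise ValueError(f"chain {c!r} missing from model")
    pair_model = complex_model.subset([a, b])
    asa_cplx = sasa(pair_model, probe_radius, n_points)
    asa_free: dict[ResidueKey, float] = {}
    for c in (a, b):
        asa_free.update(sasa(complex_model.subset([c]), probe_radius, n_points))
    delta = {k: asa_free[k] - asa_cplx.get(k, 0.0) for k in asa_free}
    iface = {k for k, d in delta.items() if d > cutoff}
    return InterfaceAnnotation(
        chain_pair=(a, b),
        asa_unbound=asa_free,
        asa_complex=asa_cplx,
        delta_asa=delta,
        interface_residues=iface,
    )


def _check_ranges(domains: pd.DataFrame) -> None:
    for chain, cdf in domains.groupby("chain"):
        spans = sorted(
            (int(r.start), int(r.end), r.domain_id) for r in cdf.itertuples()
        )
        for (s1, e1, d1), (s2, e2, d2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"chain {chain}: domains {d1} and {d2} overlap"
                )


def interface_domains(
    annotation: InterfaceAnnotation,
    domain_ranges: pd.DataFrame,
    known_ddi: pd.DataFrame | None = None,
) -> list[dict]:
    """Flag cross-chain domain pairs as interface-domain pairs.

    ``domain_ranges`` columns: chain, domain_id, start, end (author residue
    numbering, inclusive). ``known_ddi`` columns: domain_id_a, domain_id_b.
    Criterion 1: the pair is a known domain-domain interaction and each
    domain holds >= 1 interface residue. Criterion 2: each domain holds
    >= 5 interface residues.
    """
    _check_ranges(domain_ranges)
    chain_a, chain_b = annotation.chain_pair
    known: set[frozenset] = set()
    if known_ddi is not None:
        for r in known_ddi.itertuples():
            known.add(frozenset((r.domain_id_a, r.domain_id_b)))

    def iface_count(chain: str, start: int, end: int) -> int:
        return sum(
            1
            for (c, pos) in annotation.interface_residues
            if c == chain and start <= pos <= end
        )

    doms_a = domain_ranges[domain_ranges["chain"] == chain_a]
    doms_b = domain_ranges[domain_ranges["chain"] == chain_b]
    flagged: list[dict] = []
    for da in doms_a.itertuples():
        for db in doms_b.itertuples():
            na = iface_count(chain_a, int(da.start), int(da.end))
            nb = iface_count(chain_b, int(db.start), int(db.end))
            criterion = None
            if (
                frozenset((da.domain_id, db.domain_id)) in known
                and na >= 1
                and nb >= 1
            ):
                criterion = 1
            elif na >= 5 and nb >= 5:
                criterion = 2
            if criterion:
                flagged.append(
                    {
                        "domain_a": da.domain_id,
                        "domain_b": db.domain_id,
                        "chain_a": chain_a,
                        "chain_b": chain_b,
                        "range_a": (int(da.start), int(da.end)),
                        "range_b": (int(db.start), int(db.end)),
                        "n_interface_a": na,
                        "n_interface_b": nb,
                        "criterion": criterion,
                    }
                )
    annotation.interface_domain_pairs = flagged
    return flagged


def classify_locus(
    residue: ResidueKey,
    annotation: InterfaceAnnotation,
) -> str:
    """'interface_residue' | 'interface_domain' | 'away' | 'unmapped'."""
    chain, pos = residue
    if residue not in annotation.delta_asa:
        return "unmapped"
    if annotation.is_interface(residue):
        return "interface_residue"
    for pair in annotation.interface_domain_pairs:
        if pair["chain_a"] == chain and pair["range_a"][0] <= pos <= pair["range_a"][1]:
            return "interface_domain"
        if pair["chain_b"] == chain and pair["range_b"][0] <= pos <= pair["range_b"][1]:
            return "interface_domain"
    return "away"


def annotation_to_frame(annotation: InterfaceAnnotation) -> pd.DataFrame:
    rows = [
        {
            "chain": c,
            "residue": pos,
            "asa_unbound": annotation.asa_unbound[(c, pos)],
            "asa_complex": annotation.asa_complex.get((c, pos), 0.0),
            "delta_asa": annotation.delta_asa[(c, pos)],
            "is_interface": (c, pos) in annotation.interface_residues,
        }
        for (c, pos) in sorted(annotation.delta_asa)
    ]
    return pd.DataFrame(rows)
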