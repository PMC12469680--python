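"""Conformer comparison: trimmed Kabsch superposition and displacement scans.

Two crystal forms of the same protein (e.g. the native repressed and the
pentasaccharide-activated conformers of antithrombin) are overlaid by their
backbone atoms with iterative outlier trimming, after which each residue's
most distal side-chain carbon is compared between the frames. Residues that
move the most are the candidates for an allosteric communication network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structio import (
    DistalAtomTable,
    DEFAULT_DISTAL_TABLE,
    StructureModel,
    distal_side_chain_carbon,
)

__all__ = [
    "SuperpositionResult",
    "DisplacementRecord",
    "DisplacementScan",
    "DeviationMap",
    "kabsch",
    "iterative_superpose",
    "displacement_scan",
    "intra_pair_distance",
    "deviation_map",
]

DEFAULT_BACKBONE = ("N", "CA", "C")


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns (rotation R, translation t, rmsd) minimizing
    ``|| R @ mobile.T + t - reference.T ||`` with det(R) = +1.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,) Å
    rmsd: float  # over retained pairs, Å
    retained_pairs: list[tuple]  # ((resnum, icode), atom_name)
    cycles_run: int
    n_start_pairs: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map mobile-frame coordinates into the reference frame."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def iterative_superpose(mobile: StructureModel, reference: StructureModel,
                        atoms: tuple[str, ...] = DEFAULT_BACKBONE,
                        trim_sigma: float = 2.0,
                        max_cycles: int = 5,
                        min_trim_deviation: float = 0.01) -> SuperpositionResult:
    """Backbone overlay with repeated outlier rejection.

    Residues are paired across the two models by residue number + insertion
    code. Each cycle runs a Kabsch fit on the retained atom pairs, then drops
    pairs whose deviation exceeds ``trim_sigma`` times the standard deviation
    of all current deviations; iteration stops when the retained set is stable
    or after ``max_cycles``. The reported RMSD covers retained pairs only.
    Pairs deviating less than ``min_trim_deviation`` Å are never dropped, so
    an essentially exact overlay is not eroded by coordinate rounding noise.
    """
    idx_m = mobile.residue_index()
    idx_r = reference.residue_index()
    shared = sorted(set(idx_m) & set(idx_r), key=lambda k: (k[0], k[1]))
    pairs: list[tuple] = []
    P, Q = [], []
    for key in shared:
        rm, rr = idx_m[key], idx_r[key]
        for name in atoms:
            if name in rm.atoms and name in rr.atoms:
                pairs.append((key, name))
                P.append(rm.coords(name))
                Q.append(rr.coords(name))
    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} shared backbone atom pairs; need >= 3")
    P = np.array(P)
    Q = np.array(Q)

    retained = np.ones(len(pairs), dtype=bool)
    n_start = len(pairs)
    R = np.eye(3)
    t = np.zeros(3)
    rmsd = math.inf
    cycles = 0
    for cycles in range(1, max_cycles + 1):
        R, t, rmsd = kabsch(P[retained], Q[retained])
        dev = np.linalg.norm((P @ R.T + t) - Q, axis=1)
        sigma = float(dev[retained].std())
        if sigma == 0.0:
            break
        new_retained = retained & (dev <= max(trim_sigma * sigma,
                                              min_trim_deviation))
        if new_retained.sum() < 3:
            break
        if np.array_equal(new_retained, retained):
            break
        retained = new_retained
    if not retained.any():
        raise ValueError("all atom pairs trimmed away")

    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd,
        retained_pairs=[p for p, keep in zip(pairs, retained) if keep],
        cycles_run=cycles, n_start_pairs=n_start)


@dataclass(frozen=True)
class DisplacementRecord:
    residue_key: tuple
    distal_atom_a: str
    distal_atom_b: str
    displacement: float  # Å, after superposition
    fallback: bool


@dataclass
class DisplacementScan:
    records: list[DisplacementRecord]
    superposition: SuperpositionResult

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: -r.displacement)

    def top(self, k: int) -> list[DisplacementRecord]:
        return self.records[:k]

    def displacement_of(self, resnum: int, icode: str = "") -> float:
        for rec in self.records:
            if rec.residue_key[1] == resnum and rec.residue_key[2] == icode:
                return rec.displacement
        raise KeyError(f"residue {resnum}{icode} not in scan")

    def median_displacement(self) -> float:
        return float(np.median([r.displacement for r in self.records]))


def displacement_scan(a: StructureModel, b: StructureModel,
                      sup: SuperpositionResult,
                      table: DistalAtomTable | None = None
                      ) -> DisplacementScan:
    """Per-residue distal-carbon displacement of b (mobile) relative to a.

    ``sup`` must map b's frame onto a's (i.e. computed with b as mobile and a
    as reference). One record per residue shared by number + insertion code
    that carries a distal carbon in both conformers, sorted largest-first.
    """
    table = table or DEFAULT_DISTAL_TABLE
    idx_a = a.residue_index()
    idx_b = b.residue_index()
    shared = sorted(set(idx_a) & set(idx_b), key=lambda k: (k[0], k[1]))
    if not shared:
        raise ValueError("no shared residues between the two conformers")
    records = []
    for key in shared:
        ra, rb = idx_a[key], idx_b[key]
        if ra.name != rb.name:
            continue  # point mutation or register difference: not comparable
        da = distal_side_chain_carbon(ra, table)
        db = distal_side_chain_carbon(rb, table)
        if da.missing or db.missing:
            continue
        moved = sup.apply(db.coords)
        records.append(DisplacementRecord(
            residue_key=ra.key,
            distal_atom_a=da.atom_name,
            distal_atom_b=db.atom_name,
            displacement=float(np.linalg.norm(da.coords - moved)),
            fallback=da.fallback or db.fallback))
    return DisplacementScan(records=records, superposition=sup)


def intra_pair_distance(s: StructureModel, res_a: tuple[int, str] | int,
                        res_b: tuple[int, str] | int,
                        table: DistalAtomTable | None = None) -> float:
    """Distal-carbon to distal-carbon distance between two residues of one
    structure (no superposition involved)."""
    table = table or DEFAULT_DISTAL_TABLE

    def fetch(spec):
        num, icode = spec if isinstance(spec, tuple) else (spec, "")
        res = s.get_residue(num, icode)
        dc = distal_side_chain_carbon(res, table)
        if dc.missing:
            raise ValueError(f"residue {num}{icode} has no side-chain carbon")
        return dc.coords

    return float(np.linalg.norm(fetch(res_a) - fetch(res_b)))


@dataclass
class DeviationMap:
    """Per-atom and per-residue deviations between two superposed models."""

    atom_keys: list[tuple]  # (residue_key, atom_name)
    atom_deviation: np.ndarray  # Å, signed only for difference maps
    residue_keys: list[tuple]
    residue_rms: np.ndarray  # Å
    scale_max: float = 5.0

    def color_channel(self) -> np.ndarray:
        """Per-residue values clipped to [0, scale_max] for rendering only."""
        return np.clip(self.residue_rms, 0.0, self.scale_max)

    def subtract(self, other: "DeviationMap") -> "DeviationMap":
        """Signed difference map (self − other), e.g. mutant − wild type."""
        if self.atom_keys != other.atom_keys:
            raise ValueError("deviation maps cover different atom sets")
        return DeviationMap(
            atom_keys=self.atom_keys,
            atom_deviation=self.atom_deviation - other.atom_deviation,
            residue_keys=self.residue_keys,
            residue_rms=self.residue_rms - other.residue_rms,
            scale_max=self.scale_max)


def deviation_map(a: StructureModel, b: StructureModel,
                  sup: SuperpositionResult, scale_max: float = 5.0
                  ) -> DeviationMap:
    """Per-atom deviation and per-residue RMS after mapping b onto a.

    The two models must expose identical atom rosters (matched residue keys
    and atom names); a mismatch is an error rather than a silent intersection,
    to avoid comparing misaligned rosters.
    """
    idx_a = a.residue_index()
    idx_b = b.residue_index()
    if set(idx_a) != set(idx_b):
        raise ValueError("residue sets differ between the two models")
    atom_keys: list[tuple] = []
    dev: list[float] = []
    residue_keys: list[tuple] = []
    res_rms: list[float] = []
    for key in sorted(idx_a, key=lambda k: (k[0], k[1])):
        ra, rb = idx_a[key], idx_b[key]
        if set(ra.atoms) != set(rb.atoms):
            raise ValueError(f"atom-count mismatch at residue {ra.key}")
        d_res = []
        for name in ra.atoms:
            moved = sup.apply(rb.coords(name))
            d = float(np.linalg.norm(ra.coords(name) - moved))
            atom_keys.append((ra.key, name))
            dev.append(d)
            d_res.append(d)
        residue_keys.append(ra.key)
        res_rms.append(float(np.sqrt(np.mean(np.square(d_res)))))
    return DeviationMap(atom_keys=atom_keys,
                        atom_deviation=np.array(dev),
                        residue_keys=residue_keys,
                        residue_rms=np.array(res_rms),
                        scale_max=scale_max)
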