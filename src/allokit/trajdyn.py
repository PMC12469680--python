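"""Trajectory dynamics: Cα PCA, windowing, and residue-correlation maps.

An MD trajectory is reduced to its Cα atoms, every frame is rigidly aligned
onto a reference frame (removing global rotation/translation), and collective
motions are analyzed two ways:

* *Essential dynamics*: PCA of the mean-centered, flattened (frames x 3N)
  coordinate matrix. Leading variance ratios and per-frame projections
  summarize how concentrated the motion is, and the displacement between the
  head and tail of a run in the (PC1, PC2) plane measures directional drift.
* *Dynamic cross-correlation (DCCM)*: the residue-residue Pearson map of
  positional fluctuations, rho_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>).
  Subtracting a reference map (mutant minus wild type) and thresholding
  |d_rho| highlights pairs whose dynamic coupling the mutation rewired.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .confdiff import kabsch

__all__ = [
    "Trajectory",
    "AlignedTrajectory",
    "PCAResult",
    "CorrelationMatrix",
    "DeltaCorrelation",
    "load_trajectory",
    "expected_frame_count",
    "align_and_window",
    "ca_pca",
    "pc_plane_displacement",
    "residue_correlation",
    "delta_correlation",
]


@dataclass
class Trajectory:
    coords: np.ndarray  # (frames, atoms, 3) Å
    residue_ids: list  # per-atom residue identifiers
    atom_names: list[str]
    spacing_ps: float = 20.0
    source: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.spacing_ps <= 0:
            raise ValueError("frame spacing must be positive")
        n_atoms = self.coords.shape[1]
        if len(self.residue_ids) != n_atoms or len(self.atom_names) != n_atoms:
            raise ValueError("atom metadata length does not match coords")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def ca_selection(self) -> "Trajectory":
        idx = [i for i, n in enumerate(self.atom_names) if n == "CA"]
        if not idx:
            raise ValueError("trajectory contains no CA atoms")
        return Trajectory(coords=self.coords[:, idx, :],
                          residue_ids=[self.residue_ids[i] for i in idx],
                          atom_names=["CA"] * len(idx),
                          spacing_ps=self.spacing_ps, source=self.source)


@dataclass
class AlignedTrajectory(Trajectory):
    reference_frame: int = 0
    window_start: int = 0


def expected_frame_count(duration_ns: float, spacing_ps: float) -> int:
    """Frames saved over a run: duration / spacing (1000 ns at 20 ps -> 50,000)."""
    if duration_ns <= 0 or spacing_ps <= 0:
        raise ValueError("duration and spacing must be positive")
    return round(duration_ns * 1000.0 / spacing_ps)


def load_trajectory(path: str | Path, spacing_ps: float = 20.0) -> Trajectory:
    """Read a multi-model PDB (one MODEL per frame) or a plain coordinate
    matrix (text, one frame per row, 3N columns, '#'-comments allowed).

    All frames must share one atom roster; the first mismatching frame is
    named in the error.
    """
    path = Path(path)
    if path.suffix.lower() in {".pdb", ".ent"}:
        st = gemmi.read_structure(str(path))
        frames: list[np.ndarray] = []
        roster: list[tuple] | None = None
        residue_ids: list = []
        atom_names: list[str] = []
        for i, model in enumerate(st):
            coords, this_roster = [], []
            for chain in model:
                for res in chain:
                    if res.is_water():
                        continue
                    for atom in res:
                        this_roster.append((chain.name, res.seqid.num,
                                            res.name, atom.name))
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if roster is None:
                roster = this_roster
                residue_ids = [(c, n) for c, n, _, _ in roster]
                atom_names = [a for _, _, _, a in roster]
            elif this_roster != roster:
                raise ValueError(
                    f"frame {i} atom roster differs from frame 0 in {path}")
            frames.append(np.array(coords))
        if not frames:
            raise ValueError(f"no models found in {path}")
        return Trajectory(coords=np.stack(frames), residue_ids=residue_ids,
                          atom_names=atom_names, spacing_ps=spacing_ps,
                          source=str(path))
    # plain text matrix: frames x 3N
    mat = np.loadtxt(path, ndmin=2)
    if mat.shape[1] % 3 != 0:
        raise ValueError(f"{path}: column count {mat.shape[1]} not divisible by 3")
    n_atoms = mat.shape[1] // 3
    return Trajectory(coords=mat.reshape(mat.shape[0], n_atoms, 3),
                      residue_ids=list(range(1, n_atoms + 1)),
                      atom_names=["CA"] * n_atoms,
                      spacing_ps=spacing_ps, source=str(path))


def align_and_window(traj: Trajectory, reference: int = 0,
                     final_fraction: float = 1.0) -> AlignedTrajectory:
    """Kabsch-align every frame's Cα set onto a reference frame, then keep
    the trailing ``ceil(final_fraction * n_frames)`` frames.

    The reference is a frame of the *full* trajectory (default frame 0, the
    starting structure), so the window choice never changes the frame all
    others are fitted to.
    """
    if not 0.0 < final_fraction <= 1.0:
        raise ValueError("final_fraction must be in (0, 1]")
    ca = traj.ca_selection()
    if ca.n_atoms < 3:
        raise ValueError("need at least 3 CA atoms to align")
    ref = ca.coords[reference]
    aligned = np.empty_like(ca.coords)
    for i in range(ca.n_frames):
        R, t, _ = kabsch(ca.coords[i], ref)
        aligned[i] = ca.coords[i] @ R.T + t
    n_keep = math.ceil(final_fraction * ca.n_frames)
    start = ca.n_frames - n_keep
    return AlignedTrajectory(coords=aligned[start:],
                             residue_ids=ca.residue_ids,
                             atom_names=ca.atom_names,
                             spacing_ps=ca.spacing_ps, source=ca.source,
                             reference_frame=reference, window_start=start)


@dataclass
class PCAResult:
    components: np.ndarray  # (n_components, 3N), orthonormal rows
    variance_ratios: np.ndarray  # fractions of *total* variance
    projections: np.ndarray  # (frames, n_components)
    mean: np.ndarray  # (3N,)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def ca_pca(atraj: AlignedTrajectory, n_components: int = 20) -> PCAResult:
    """PCA of the flattened, per-window mean-centered Cα coordinates.

    Variance ratios are fractions of the total variance (all eigenvalues),
    so they sum to 1 only across the full spectrum. Component signs are fixed
    so each component's largest-magnitude element is positive, making
    projections reproducible across runs and libraries.
    """
    X = atraj.coords.reshape(atraj.n_frames, -1)
    if atraj.n_frames <= n_components:
        n_components = atraj.n_frames - 1
    if n_components < 1:
        raise ValueError("too few frames for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(np.abs(Xc) > 1e-12):
        raise ValueError("no variance: all frames identical")
    # SVD of the centered data == eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (atraj.n_frames - 1)
    total = eigvals.sum()
    comps = Vt[:n_components]
    # sign convention: largest-|element| of each component positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    proj = Xc @ comps.T
    return PCAResult(components=comps,
                     variance_ratios=eigvals[:n_components] / total,
                     projections=proj, mean=mean)


def pc_plane_displacement(pca: PCAResult, head_fraction: float = 0.05,
                          tail_fraction: float = 0.05) -> float:
    """Drift length in the (PC1, PC2) plane: distance between the mean
    projection of the first ``head_fraction`` of frames and the mean of the
    last ``tail_fraction``."""
    for frac in (head_fraction, tail_fraction):
        if not 0.0 < frac <= 0.5:
            raise ValueError("window fractions must be in (0, 0.5]")
    if pca.projections.shape[1] < 2:
        raise ValueError("need at least two principal components")
    n = pca.projections.shape[0]
    n_head = math.ceil(head_fraction * n)
    n_tail = math.ceil(tail_fraction * n)
    if n_head < 1 or n_tail < 1 or n_head + n_tail > n:
        raise ValueError("too few frames for the requested windows")
    head = pca.projections[:n_head, :2].mean(axis=0)
    tail = pca.projections[-n_tail:, :2].mean(axis=0)
    return float(np.linalg.norm(tail - head))


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray  # (residues, residues), NaN rows for zero-variance
    residue_ids: list
    mode: str = "vector"  # "vector" (DCCM) or "per_coordinate"
    window: tuple[int, int] | None = None

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]


def residue_correlation(atraj: AlignedTrajectory,
                        mode: str = "vector") -> CorrelationMatrix:
    """Residue-residue Pearson map of Cα positional fluctuations.

    ``mode="vector"`` is the standard DCCM,
    rho_ij = <dr_i . dr_j>/sqrt(<|dr_i|^2><|dr_j|^2>) with dr the deviation
    from the time-mean position. ``mode="per_coordinate"`` instead averages
    the three coordinate-wise Pearson coefficients. Residues with zero
    positional variance get NaN rows/columns and a warning.
    """
    if atraj.n_frames < 10:
        raise ValueError("need at least 10 frames for a correlation map")
    d = atraj.coords - atraj.coords.mean(axis=0)  # (F, N, 3)
    if mode == "vector":
        inner = np.einsum("fic,fjc->ij", d, d) / atraj.n_frames
        var = np.diag(inner).copy()
        zero = var <= 0
        denom = np.sqrt(np.outer(np.where(zero, np.nan, var),
                                 np.where(zero, np.nan, var)))
        with np.errstate(invalid="ignore"):
            rho = inner / denom
    elif mode == "per_coordinate":
        F = atraj.n_frames
        var_c = (d ** 2).mean(axis=0)  # (N, 3)
        zero = np.all(var_c <= 0, axis=1)
        rho = np.zeros((atraj.n_atoms, atraj.n_atoms))
        for c in range(3):
            dc = d[:, :, c]
            sd = dc.std(axis=0)
            sd_safe = np.where(sd > 0, sd, np.nan)
            with np.errstate(invalid="ignore"):
                rho += (dc.T @ dc / F) / np.outer(sd_safe, sd_safe)
        rho /= 3.0
        rho[zero, :] = np.nan
        rho[:, zero] = np.nan
    else:
        raise ValueError(f"unknown correlation mode {mode!r}")
    if np.any(zero):
        warnings.warn(f"{int(np.sum(zero))} residue(s) with zero variance: "
                      "rows set to NaN", RuntimeWarning, stacklevel=2)
    np.fill_diagonal(rho, np.where(zero, np.nan, 1.0))
    return CorrelationMatrix(matrix=rho, residue_ids=list(atraj.residue_ids),
                             mode=mode)


@dataclass
class DeltaCorrelation:
    delta: np.ndarray  # raw d_rho = target - reference
    thresholded: np.ndarray  # entries with |d_rho| < threshold zeroed
    threshold: float
    residue_ids: list
    top_positive: list[tuple]  # (res_i, res_j, d_rho), i < j
    top_negative: list[tuple]


def delta_correlation(target: CorrelationMatrix, reference: CorrelationMatrix,
                      threshold: float = 0.5, top_k: int = 25
                      ) -> DeltaCorrelation:
    """Differential correlation map, d_rho = target - reference.

    Returns the raw map, a copy with sub-threshold entries zeroed, and the
    ``top_k`` most positive / most negative upper-triangle pairs (pairs where
    either map is undefined are excluded from ranking).
    """
    if target.residue_ids != reference.residue_ids:
        only_t = set(map(tuple_or_id, target.residue_ids)) - \
            set(map(tuple_or_id, reference.residue_ids))
        only_r = set(map(tuple_or_id, reference.residue_ids)) - \
            set(map(tuple_or_id, target.residue_ids))
        raise ValueError(f"residue indexing mismatch; only in target: "
                         f"{sorted(only_t)}, only in reference: {sorted(only_r)}")
    delta = target.matrix - reference.matrix
    thresholded = np.where(np.abs(delta) >= threshold, delta, 0.0)
    thresholded = np.where(np.isnan(delta), np.nan, thresholded)
    iu, ju = np.triu_indices(delta.shape[0], k=1)
    vals = delta[iu, ju]
    ok = np.isfinite(vals)
    iu, ju, vals = iu[ok], ju[ok], vals[ok]
    order = np.argsort(vals)
    ids = target.residue_ids

    def pairs(indices) -> list[tuple]:
        return [(ids[iu[k]], ids[ju[k]], float(vals[k])) for k in indices]

    top_neg = pairs([k for k in order[:top_k] if vals[k] < 0])
    top_pos = pairs([k for k in order[::-1][:top_k] if vals[k] > 0])
    return DeltaCorrelation(delta=delta, thresholded=thresholded,
                            threshold=threshold, residue_ids=list(ids),
                            top_positive=top_pos, top_negative=top_neg)


def tuple_or_id(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x
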