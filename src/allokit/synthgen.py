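"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage gets a generator whose output is drawn from the exact
model the corresponding analysis fits, with the generating parameters echoed
back as ``truth``. Defaults mirror the study conditions: pseudo-first-order
inhibition progress curves with multiplicative noise, linear stoichiometry
titrations, two-state melting curves on a 20–85 °C scan, a wild-type
fluorescence preset with a 40% pentasaccharide gain, minimal conformer pairs
with prescribed distal-carbon displacements, low-rank collective-mode
trajectories with isotropic noise, and mutant rate tables built from single
and pairwise interaction energies.

All generators are deterministic functions of their seed (numpy Generator,
fixed bit stream), so identical inputs give bit-identical fixtures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .kinfit import ProgressCurve
from .mutcycle import MutantRateTable, R_KCAL
from .structio import AtomRecord, Residue, StructureModel
from .thermflr import FluorescenceSeries, MeltCurve, KELVIN
from .trajdyn import AlignedTrajectory, Trajectory

__all__ = [
    "SynthSpec",
    "random_rotation",
    "make_conformer_pair",
    "make_kinetics_dataset",
    "make_titration",
    "make_fluorescence_dataset",
    "make_melt_curve",
    "make_trajectory",
    "make_rate_table",
    "as_aligned",
]

STAGES = ("conformers", "kinetics", "titration", "melt", "fluorescence",
          "trajectory", "rate_table")


@dataclass
class SynthSpec:
    """Seed + stage + parameters; ``truth`` is filled in by ``generate``."""

    seed: int
    stage: str
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; one of {STAGES}")

    def generate(self):
        maker = {
            "conformers": make_conformer_pair,
            "kinetics": make_kinetics_dataset,
            "titration": make_titration,
            "melt": make_melt_curve,
            "fluorescence": make_fluorescence_dataset,
            "trajectory": make_trajectory,
            "rate_table": make_rate_table,
        }[self.stage]
        out = maker(seed=self.seed, **self.params) if self.stage != "rate_table" \
            else maker(**self.params)
        self.truth = out[-1]
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=_jsonable, sort_keys=True)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, frozenset):
        return sorted(x)
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# ---------------------------------------------------------------------------
# Conformer pairs
# ---------------------------------------------------------------------------

def make_conformer_pair(n_residues: int = 20,
                        displaced: Mapping[int, Sequence[float]] | None = None,
                        seed: int = 0,
                        rigid_motion: bool = True
                        ) -> tuple[StructureModel, StructureModel, dict]:
    """Synthetic poly-alanine conformer pair with prescribed displacements.

    Both models share an identical (idealized, non-collinear) backbone; in the
    second model each listed residue's distal carbon (CB) is shifted by the
    prescribed 3-vector, and optionally the whole mobile copy is subjected to
    a random rigid motion. Truth maps residue number -> displacement length Å.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    displaced = {int(k): np.asarray(v, dtype=float)
                 for k, v in (displaced or {}).items()}
    if any(not 1 <= k <= n_residues for k in displaced):
        raise ValueError("displaced residue numbers out of range")
    rng = np.random.default_rng(seed)

    def build(shift: Mapping[int, np.ndarray]) -> StructureModel:
        residues = []
        for i in range(1, n_residues + 1):
            ca = np.array([3.8 * i, 2.2 * math.sin(0.6 * i),
                           2.2 * math.cos(0.6 * i)])
            offsets = {
                "N": ca + np.array([-1.2, 0.8 * math.cos(i), 0.4 * math.sin(i)]),
                "CA": ca,
                "C": ca + np.array([1.2, 0.7 * math.sin(i + 1),
                                    0.5 * math.cos(i + 1)]),
                "CB": ca + np.array([0.3, 1.3, 0.6]) + shift.get(i, 0.0),
            }
            key = ("A", i, "", "ALA")
            res = Residue(key=key)
            for name, xyz in offsets.items():
                res.atoms[name] = AtomRecord(name=name, element="C" if
                                             name != "N" else "N",
                                             coords=xyz, altloc="",
                                             occupancy=1.0, residue_key=key)
            residues.append(res)
        return StructureModel(id="SYNTH", chains={"A": residues})

    a = build({})
    b = build(displaced)
    if rigid_motion:
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, size=3)
        for res in b.residues():
            for name, atom in list(res.atoms.items()):
                res.atoms[name] = AtomRecord(
                    name=atom.name, element=atom.element,
                    coords=R @ atom.coords + t, altloc=atom.altloc,
                    occupancy=atom.occupancy, residue_key=atom.residue_key)
    truth = {"displacements": {k: float(np.linalg.norm(v))
                               for k, v in displaced.items()},
             "rigid_motion": rigid_motion, "n_residues": n_residues}
    return a, b, truth


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def make_kinetics_dataset(k2_true: float = 4e3, inhibitor_conc: float = 5e-7,
                          SI_true: float = 1.0, noise_frac: float = 0.02,
                          n_points: int = 12, A0: float = 1.0,
                          seed: int = 0) -> tuple[ProgressCurve, dict]:
    """Pseudo-first-order progress curve with multiplicative Gaussian noise.

    The encoded observed rate is k_obs = k2_true * [inhibitor] / SI_true;
    sampling spans about three half-life equivalents so the decay is well
    observed.
    """
    if min(k2_true, inhibitor_conc, SI_true, A0) <= 0:
        raise ValueError("parameters must be positive")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    k_obs = k2_true * inhibitor_conc / SI_true
    t = np.linspace(0.0, 3.0 / k_obs, n_points)
    A = A0 * np.exp(-k_obs * t)
    if noise_frac > 0:
        A = A * (1.0 + noise_frac * rng.standard_normal(n_points))
        A = np.clip(A, 1e-12, None)
    curve = ProgressCurve(times=t, residual_activity=A,
                          inhibitor_conc=inhibitor_conc,
                          protease_conc=inhibitor_conc / 10.0)
    truth = {"k2": k2_true, "k_obs": k_obs, "SI": SI_true, "A0": A0,
             "inhibitor_conc": inhibitor_conc, "noise_frac": noise_frac}
    return curve, truth


def make_titration(SI_true: float = 1.4, noise_sd: float = 3.0,
                   n_points: int = 9, a0: float = 100.0, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Linear stoichiometry titration: activity declines to zero at ratio = SI."""
    if SI_true <= 0:
        raise ValueError("SI_true must be positive")
    rng = np.random.default_rng(seed)
    ratios = np.linspace(0.0, 1.2 * SI_true, n_points)
    activities = np.maximum(a0 * (1.0 - ratios / SI_true), 0.0)
    if noise_sd > 0:
        activities = activities + noise_sd * rng.standard_normal(n_points)
    truth = {"SI": SI_true, "a0": a0, "noise_sd": noise_sd}
    return ratios, activities, truth


# ---------------------------------------------------------------------------
# Fluorescence
# ---------------------------------------------------------------------------

def make_fluorescence_dataset(baseline_slope: float = 2e8,
                              gain_frac: float = 0.40,
                              noise_frac: float = 0.01,
                              n_conc: int = 8, conc_max: float = 2.5e-6,
                              n_replicates: int = 6, seed: int = 0
                              ) -> tuple[FluorescenceSeries, np.ndarray,
                                         np.ndarray, dict]:
    """Concentration titration plus a saturating-pentasaccharide gain step.

    Wild-type preset: 40% gain with 1% multiplicative noise (the activated
    conformer's tryptophan fluorescence enhancement). Returns the linear
    series, replicate baseline readings at the final concentration, replicate
    post-saturation readings, and the truth.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = np.random.default_rng(seed)
    conc = np.linspace(conc_max / n_conc, conc_max, n_conc)
    F = baseline_slope * conc
    if noise_frac > 0:
        F = F * (1.0 + noise_frac * rng.standard_normal(n_conc))
    series = FluorescenceSeries(concentrations=conc, fluorescence=F)
    f_base_true = baseline_slope * conc_max
    f_sat_true = f_base_true * (1.0 + gain_frac)
    base_reads = f_base_true * (1.0 + noise_frac *
                                rng.standard_normal(n_replicates))
    sat_reads = f_sat_true * (1.0 + noise_frac *
                              rng.standard_normal(n_replicates))
    truth = {"baseline_slope": baseline_slope, "gain_frac": gain_frac,
             "percent_gain": 100.0 * gain_frac, "noise_frac": noise_frac,
             "f_base": f_base_true, "f_sat": f_sat_true}
    return series, base_reads, sat_reads, truth


# ---------------------------------------------------------------------------
# Melting curves
# ---------------------------------------------------------------------------

def make_melt_curve(tm_true_c: float = 63.0, dh_true: float = 150.0,
                    baselines: tuple[tuple[float, float],
                                     tuple[float, float]] =
                    ((180.0, -0.25), (20.0, 0.12)),
                    noise_frac: float = 0.0, step_c: float = 3.0,
                    t_min_c: float = 20.0, t_max_c: float = 85.0,
                    seed: int = 0) -> tuple[MeltCurve, dict]:
    """Two-state van't Hoff melting curve on the standard 20–85 °C scan grid.

    ``baselines`` are (intercept, slope-per-K) pairs for the native and
    unfolded states evaluated at absolute temperature.
    """
    if not t_min_c < tm_true_c < t_max_c:
        raise ValueError("Tm must lie inside the scanned range")
    rng = np.random.default_rng(seed)
    tc = np.arange(t_min_c, t_max_c + 1e-9, step_c)
    T = tc + KELVIN
    tm_k = tm_true_c + KELVIN
    K = np.exp(-(dh_true / R_KCAL) * (1.0 / T - 1.0 / tm_k))
    f = 1.0 / (1.0 + K)
    (an, bn), (au, bu) = baselines
    F = (an + bn * T) * f + (au + bu * T) * (1.0 - f)
    if noise_frac > 0:
        F = F * (1.0 + noise_frac * rng.standard_normal(len(F)))
    curve = MeltCurve(temperatures_c=tc, fluorescence=F)
    truth = {"tm_c": tm_true_c, "dh_vh": dh_true, "baselines": baselines,
             "noise_frac": noise_frac}
    return curve, truth


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def make_trajectory(n_atoms: int = 60, n_frames: int = 1000,
                    mode_stds: Sequence[float] = (),
                    modes: Sequence[np.ndarray] | None = None,
                    noise_std: float = 0.1,
                    coupled_blocks: tuple[Sequence[int], Sequence[int],
                                          float] | None = None,
                    spacing_ps: float = 20.0,
                    seed: int = 0) -> tuple[Trajectory, dict]:
    """Low-rank collective-mode trajectory plus isotropic coordinate noise.

    frame_t = base + sum_i a_i(t) v_i + eps, with mode amplitudes a_i Gaussian
    of the stated std over orthonormalized 3N-vectors v_i and eps isotropic
    Gaussian of std ``noise_std`` per coordinate.

    ``coupled_blocks = (atoms_a, atoms_b, rho)`` adds one extra shared mode
    confined to the two atom blocks (all block atoms moving in phase along x)
    whose amplitude is chosen analytically so the block-to-block DCCM entry is
    ``rho`` on top of independent noise: Var(a) = rho * 3*noise_std^2/(1-rho).
    The base modes and the noise stream are generated from sub-seeds that do
    not depend on ``coupled_blocks``, so the coupled trajectory and its
    uncoupled twin (same seed) share every other displacement bit-for-bit.

    Truth includes analytic PCA variance ratios and the injected block
    correlation.
    """
    if n_frames <= 10:
        raise ValueError("need more than 10 frames")
    if not mode_stds and modes is None and noise_std <= 0 \
            and coupled_blocks is None:
        raise ValueError("degenerate: no modes and no noise")
    rng_modes = np.random.default_rng([seed, 1])
    rng_amps = np.random.default_rng([seed, 2])
    rng_noise = np.random.default_rng([seed, 3])
    rng_coupling = np.random.default_rng([seed, 4])

    dim = 3 * n_atoms
    base = np.zeros((n_atoms, 3))
    base[:, 0] = 3.8 * np.arange(n_atoms)
    base[:, 1] = 1.5 * np.sin(0.4 * np.arange(n_atoms))
    base[:, 2] = 1.5 * np.cos(0.4 * np.arange(n_atoms))

    if modes is not None:
        V = np.array([np.asarray(v, dtype=float).ravel() for v in modes])
        if V.shape[1] != dim:
            raise ValueError("mode vectors must have length 3*n_atoms")
    elif mode_stds:
        V = rng_modes.standard_normal((len(mode_stds), dim))
    else:
        V = np.empty((0, dim))
    if len(V):
        # orthonormalize (QR on the transpose keeps the spanned order)
        Q, _ = np.linalg.qr(V.T)
        V = Q.T[: len(V)]
    stds = np.asarray(mode_stds, dtype=float)
    if len(stds) != len(V):
        raise ValueError("mode_stds and modes must have matching lengths")

    X = np.tile(base.ravel(), (n_frames, 1))
    if len(V):
        # Gaussian amplitudes, standardized to exact sample moments (zero
        # mean, unit std, zero cross-correlation) so the stated mode
        # variances are the *sample* variances and the analytic variance
        # ratios hold exactly at zero noise.
        A = rng_amps.standard_normal((n_frames, len(V)))
        A -= A.mean(axis=0)
        cov = A.T @ A / n_frames
        A = A @ np.linalg.inv(np.linalg.cholesky(cov)).T
        X += (A * stds) @ V
    if noise_std > 0:
        X += noise_std * rng_noise.standard_normal((n_frames, dim))

    block_rho = None
    coupled_std = 0.0
    if coupled_blocks is not None:
        atoms_a, atoms_b, rho = coupled_blocks
        if not 0.0 < rho < 1.0:
            raise ValueError("target block correlation must be in (0, 1)")
        if noise_std <= 0:
            raise ValueError("coupled blocks need a noise floor to dilute")
        u = np.zeros(dim)
        for idx in list(atoms_a) + list(atoms_b):
            u[3 * idx] = 1.0  # in-phase x motion, unit per atom
        coupled_std = noise_std * math.sqrt(3.0 * rho / (1.0 - rho))
        z = rng_coupling.standard_normal(n_frames)
        z = (z - z.mean()) / z.std()
        X += np.outer(coupled_std * z, u)
        block_rho = rho

    mode_vars = np.sort(stds ** 2)[::-1] if len(stds) else np.array([])
    noise_var = noise_std ** 2
    eigs = np.concatenate([mode_vars + noise_var,
                           np.full(dim - len(mode_vars), noise_var)])
    ratios = eigs / eigs.sum() if eigs.sum() > 0 else eigs
    truth = {
        "mode_stds": list(map(float, stds)),
        "noise_std": noise_std,
        "analytic_variance_ratios": ratios[: max(len(stds), 1)].tolist(),
        "block_correlation": block_rho,
        "coupled_mode_std": coupled_std,
    }
    traj = Trajectory(coords=X.reshape(n_frames, n_atoms, 3),
                      residue_ids=list(range(1, n_atoms + 1)),
                      atom_names=["CA"] * n_atoms, spacing_ps=spacing_ps,
                      source=f"synth(seed={seed})")
    return traj, truth


def as_aligned(traj: Trajectory, reference: int = 0) -> AlignedTrajectory:
    """Wrap a trajectory that is already in a common frame (no re-fitting)."""
    return AlignedTrajectory(coords=traj.coords, residue_ids=traj.residue_ids,
                             atom_names=traj.atom_names,
                             spacing_ps=traj.spacing_ps, source=traj.source,
                             reference_frame=reference, window_start=0)


# ---------------------------------------------------------------------------
# Mutant rate tables
# ---------------------------------------------------------------------------

def make_rate_table(single_energies: Mapping[str, float],
                    pair_energies: Mapping[frozenset | tuple, float]
                    | None = None,
                    k2_wt: float = 4e3, T: float = 298.15,
                    singles_only: bool = False
                    ) -> tuple[MutantRateTable, dict]:
    """Rate table generated from an explicit energy model.

    k2(S) = k2_wt * exp[sum_m e_m/(RT)] * exp[-sum_{(a,b) in S} e_ab/(RT)]
    over every subset S of the mutations, so the coupling index of any pair
    is exactly exp(e_ab/(RT)). ``singles_only`` restricts the table to the
    wild type plus single mutants (for missing-combination reporting).
    """
    pair_energies = {frozenset(k): float(v)
                     for k, v in (pair_energies or {}).items()}
    muts = sorted(single_energies)
    rt = R_KCAL * T
    rates: dict[frozenset, float] = {}

    def k2_of(subset: frozenset) -> float:
        e = sum(single_energies[m] for m in subset)
        e_pair = sum(v for pair, v in pair_energies.items()
                     if pair <= subset)
        return k2_wt * math.exp(e / rt) * math.exp(-e_pair / rt)

    subsets = [frozenset()]
    if singles_only:
        subsets += [frozenset({m}) for m in muts]
    else:
        for i in range(1, 2 ** len(muts)):
            subsets.append(frozenset(m for j, m in enumerate(muts)
                                     if i >> j & 1))
    for s in subsets:
        rates[s] = k2_of(s)
    truth = {"single_energies": dict(single_energies),
             "pair_energies": {";".join(sorted(k)): v
                               for k, v in pair_energies.items()},
             "k2_wt": k2_wt, "T": T}
    return MutantRateTable(rates), truth
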