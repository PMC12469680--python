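"""Double- and triple-mutant thermodynamic coupling on rate-constant tables.

Mutation effects on a second-order rate constant are energetically additive
when they combine multiplicatively: k_ab/k_0 = (k_a/k_0)(k_b/k_0). The
coupling index

    CI = (k_a * k_b) / (k_0 * k_ab)        (over an optional background set)

equals 1 for additive effects and exceeds 1 when the double mutant gains less
than the multiplicative prediction — the signature of two residues performing
a common, cooperative function. The interaction free energy is
dG_int = R*T*ln(CI) with R = 1.987e-3 kcal mol^-1 K^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "R_KCAL",
    "MutantRateTable",
    "CouplingResult",
    "MissingCombination",
    "coupling_index",
    "coupling_matrix",
    "three_body_term",
    "multiplicative_fold_prediction",
    "read_rate_table_tsv",
    "write_rate_table_tsv",
]

R_KCAL = 1.987e-3  # kcal mol^-1 K^-1
DEFAULT_T = 298.15  # K, assays at 25 °C


def _key(mutations: Iterable[str]) -> frozenset[str]:
    return frozenset(mutations)


class MutantRateTable:
    """Rate constants keyed by (order-insensitive) mutation sets.

    The wild type is the empty mutation set and must be present; all rates
    must be positive. Standard errors are optional and propagate to CI errors
    in log space when available.
    """

    def __init__(self, rates: Mapping[frozenset | tuple | str, float],
                 errors: Mapping[frozenset | tuple | str, float] | None = None):
        self._rates: dict[frozenset, float] = {}
        self._errors: dict[frozenset, float] = {}
        for muts, k2 in rates.items():
            key = _key([muts] if isinstance(muts, str) else muts)
            if k2 <= 0:
                raise ValueError(f"rate for {set(key) or 'WT'} must be > 0")
            self._rates[key] = float(k2)
        for muts, se in (errors or {}).items():
            key = _key([muts] if isinstance(muts, str) else muts)
            self._errors[key] = float(se)
        if frozenset() not in self._rates:
            raise ValueError("wild-type entry (empty mutation set) required")

    def __contains__(self, mutations) -> bool:
        return _key(mutations) in self._rates

    def k2(self, mutations: Iterable[str] = ()) -> float:
        key = _key(mutations)
        if key not in self._rates:
            raise KeyError(f"missing rate for mutation set {set(key) or 'WT'}")
        return self._rates[key]

    def se(self, mutations: Iterable[str] = ()) -> float | None:
        return self._errors.get(_key(mutations))

    def mutation_sets(self) -> list[frozenset]:
        return list(self._rates)

    def singles(self) -> list[str]:
        return sorted(m for key in self._rates if len(key) == 1
                      for m in key)


@dataclass(frozen=True)
class CouplingResult:
    pair: tuple[str, str]
    background: frozenset[str]
    CI: float
    dG_int: float  # kcal/mol
    temperature: float  # K
    convention: str = "cooperative_gt1"
    CI_se: float | None = None


@dataclass(frozen=True)
class MissingCombination:
    pair: tuple[str, str]
    background: frozenset[str]
    missing: tuple[frozenset, ...]


def coupling_index(table: MutantRateTable, a: str, b: str,
                   background: Iterable[str] = (),
                   T: float = DEFAULT_T,
                   convention: str = "cooperative_gt1") -> CouplingResult:
    """Coupling index of mutations a and b over an optional background set.

    Requires the four cycle corners bg, bg+a, bg+b, bg+a+b. The default
    convention reports CI > 1 for cooperative (sub-multiplicative) linkage;
    ``convention="reciprocal"`` flips to the inverse definition. The
    convention used is stamped into the result.
    """
    bg = _key(background)
    if a == b or a in bg or b in bg:
        raise ValueError("mutations a, b must be distinct and outside background")
    corners = [bg, bg | {a}, bg | {b}, bg | {a, b}]
    missing = [c for c in corners if c not in table.mutation_sets()]
    if missing:
        raise KeyError("missing rate(s) for mutation set(s): "
                       + ", ".join(str(set(c) or {"WT"}) for c in missing))
    k0, ka, kb, kab = (table.k2(c) for c in corners)
    ci = (ka * kb) / (k0 * kab)
    if convention == "reciprocal":
        ci = 1.0 / ci
    elif convention != "cooperative_gt1":
        raise ValueError(f"unknown convention {convention!r}")
    ci_se = None
    ses = [table.se(c) for c in corners]
    if all(se is not None for se in ses):
        rel = sum((se / table.k2(c)) ** 2
                  for se, c in zip(ses, corners))
        ci_se = ci * math.sqrt(rel)
    return CouplingResult(pair=(a, b), background=bg, CI=ci,
                          dG_int=R_KCAL * T * math.log(ci), temperature=T,
                          convention=convention, CI_se=ci_se)


def coupling_matrix(table: MutantRateTable, mutations: list[str],
                    T: float = DEFAULT_T,
                    convention: str = "cooperative_gt1"
                    ) -> tuple[list[CouplingResult], list[MissingCombination]]:
    """All pairwise CIs plus conditional CIs over single-mutation backgrounds.

    Combinations the table cannot support are reported, never fabricated.
    """
    results: list[CouplingResult] = []
    missing: list[MissingCombination] = []
    backgrounds: list[frozenset] = [frozenset()]
    backgrounds += [frozenset({m}) for m in mutations]
    available = set(table.mutation_sets())
    for bg in backgrounds:
        for i, a in enumerate(mutations):
            for b in mutations[i + 1:]:
                if a in bg or b in bg:
                    continue
                corners = [bg, bg | {a}, bg | {b}, bg | {a, b}]
                absent = tuple(c for c in corners if c not in available)
                if absent:
                    missing.append(MissingCombination(pair=(a, b),
                                                      background=bg,
                                                      missing=absent))
                else:
                    results.append(coupling_index(table, a, b, bg, T,
                                                  convention))
    return results, missing


def three_body_term(table: MutantRateTable, a: str, b: str, c: str,
                    T: float = DEFAULT_T) -> float:
    """Higher-order coupling: dG_int(a,b | {c}) - dG_int(a,b | WT), kcal/mol.

    Zero whenever the table is generated by single and pairwise energies only;
    nonzero values indicate that the a-b linkage depends on the presence of c
    (the pattern seen when a third network residue gates a coupling).
    """
    with_c = coupling_index(table, a, b, {c}, T)
    without = coupling_index(table, a, b, (), T)
    return with_c.dG_int - without.dG_int


def multiplicative_fold_prediction(*folds: float) -> float:
    """Fold activation expected from independent (energy-additive) mutations.

    Energetic additivity on a rate constant is multiplicative on folds, so
    the prediction for a combined mutant is simply the product of the single
    folds (e.g. 31-fold x 3.6-fold -> 111.6-fold).
    """
    if any(f <= 0 for f in folds):
        raise ValueError("folds must be positive")
    return math.prod(folds)


# ---------------------------------------------------------------------------
# TSV dialect: columns mutations (semicolon-joined, empty = WT), k2_M1s1, se
# ---------------------------------------------------------------------------

def read_rate_table_tsv(path: str | Path) -> MutantRateTable:
    df = pd.read_csv(path, sep="\t", dtype={"mutations": str})
    rates: dict[frozenset, float] = {}
    errors: dict[frozenset, float] = {}
    for _, row in df.iterrows():
        raw = row["mutations"]
        muts = frozenset() if pd.isna(raw) or not str(raw).strip() else \
            frozenset(m.strip() for m in str(raw).split(";") if m.strip())
        rates[muts] = float(row["k2_M1s1"])
        if "se" in df.columns and pd.notna(row.get("se")):
            errors[muts] = float(row["se"])
    return MutantRateTable(rates, errors or None)


def write_rate_table_tsv(table: MutantRateTable, path: str | Path) -> None:
    rows = []
    for key in sorted(table.mutation_sets(), key=lambda k: (len(k), sorted(k))):
        rows.append({"mutations": ";".join(sorted(key)),
                     "k2_M1s1": table.k2(key),
                     "se": table.se(key)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
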