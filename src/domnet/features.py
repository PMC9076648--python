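"""Peak-list processing: S/N and blank filtering, molecular-formula
assignment from exact mass, and assembly of the relative-intensity
feature matrix.

Peak lists are plain :class:`pandas.DataFrame` objects with columns
``mz``, ``intensity`` and ``sn``; the feature matrix has one row per
canonical sum-formula string and one column per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    MONOISOTOPIC_MASS,
    SumFormula,
    neutral_mass_from_mz,
    ppm_error,
)

PEAK_COLUMNS = ("mz", "intensity", "sn")

#: Default S/N cutoff; peaks must exceed it strictly.
DEFAULT_SN_THRESHOLD = 4.0
#: Default acquisition window (m/z) of the direct-infusion method.
DEFAULT_MZ_WINDOW = (175.0, 1000.0)


def _as_peak_frame(peaks) -> pd.DataFrame:
    df = pd.DataFrame(peaks, columns=list(PEAK_COLUMNS)) if not isinstance(peaks, pd.DataFrame) else peaks
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing columns {sorted(missing)}")
    return df


def filter_peaks(
    peaks,
    blanks=None,
    sn_threshold: float = DEFAULT_SN_THRESHOLD,
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
    blank_ppm_tolerance: float = 2.0,
) -> pd.DataFrame:
    """Apply S/N, acquisition-window and blank-mass exclusion filters.

    A peak survives iff its signal-to-noise ratio is strictly greater
    than ``sn_threshold``, its m/z lies within ``mz_window`` (inclusive),
    and no blank peak lies within ``blank_ppm_tolerance`` ppm of its m/z.
    The operation is idempotent.
    """
    df = _as_peak_frame(peaks)
    if (df["intensity"] < 0).any():
        raise ValueError("negative intensities in peak list")
    if (df["sn"] < 0).any():
        raise ValueError("negative signal-to-noise ratios in peak list")
    lo, hi = mz_window
    keep = (df["sn"] > sn_threshold) & (df["mz"] >= lo) & (df["mz"] <= hi)
    out = df.loc[keep].reset_index(drop=True)
    if blanks is not None and len(out):
        bmz = np.sort(np.asarray(_as_peak_frame(blanks)["mz"], dtype=float))
        if bmz.size:
            mz = out["mz"].to_numpy(dtype=float)
            tol = mz * blank_ppm_tolerance * 1e-6
            idx = np.searchsorted(bmz, mz)
            near_hi = np.where(idx < bmz.size, np.abs(bmz[np.minimum(idx, bmz.size - 1)] - mz), np.inf)
            near_lo = np.where(idx > 0, np.abs(mz - bmz[np.maximum(idx - 1, 0)]), np.inf)
            blank_hit = np.minimum(near_hi, near_lo) <= tol
            out = out.loc[~blank_hit].reset_index(drop=True)
    return out


@dataclass(frozen=True)
class ElementRanges:
    """Inclusive (min, max) count ranges for each element considered
    during formula enumeration. Defaults follow common DOM Orbitrap
    practice and are deliberately generous."""

    c: tuple[int, int] = (1, 100)
    h: tuple[int, int] = (0, 200)
    n: tuple[int, int] = (0, 5)
    o: tuple[int, int] = (0, 80)
    s: tuple[int, int] = (0, 2)

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid element range for {name!r}: ({lo}, {hi})")


@dataclass(frozen=True)
class PlausibilityFilters:
    """Chemical QC applied to candidate formulas. Each rule can be
    switched off independently.

    * elemental-ratio windows: 0.3 <= H/C <= 2.5 and O/C <= 1.2 span the
      van Krevelen space occupied by natural organic matter;
    * even-electron rule: H+N must be even and the ring-plus-double-bond
      count non-negative for a stable neutral molecule.
    """

    hc_range: tuple[float, float] = (0.3, 2.5)
    oc_max: float = 1.2
    check_ratios: bool = True
    check_even_electron: bool = True

    def accept(self, f: SumFormula) -> bool:
        if self.check_ratios:
            if f.c == 0:
                return False
            hc = f.h / f.c
            if not (self.hc_range[0] <= hc <= self.hc_range[1]):
                return False
            if f.o / f.c > self.oc_max:
                return False
        if self.check_even_electron:
            if (f.h + f.n) % 2 != 0:
                return False
            if f.dbe < 0:
                return False
        return True


@dataclass
class FormulaAssignment:
    """Assignment result for one peak: all candidates within tolerance,
    sorted by |ppm error| (ties: fewer heteroatoms, then lower H), and
    the chosen best candidate (``None`` when unassigned)."""

    mz: float
    candidates: list[tuple[SumFormula, float]] = field(default_factory=list)

    @property
    def best(self) -> SumFormula | None:
        return self.candidates[0][0] if self.candidates else None

    @property
    def best_ppm(self) -> float | None:
        return self.candidates[0][1] if self.candidates else None


class _CandidateIndex:
    """Sorted mass index over the (C, N, O, S) sub-grid; hydrogen counts
    are solved per query, which keeps enumeration exhaustive without
    materialising the full 5-element grid."""

    def __init__(self, ranges: ElementRanges):
        self.ranges = ranges
        cs = np.arange(ranges.c[0], ranges.c[1] + 1)
        ns = np.arange(ranges.n[0], ranges.n[1] + 1)
        os_ = np.arange(ranges.o[0], ranges.o[1] + 1)
        ss = np.arange(ranges.s[0], ranges.s[1] + 1)
        C, N, O, S = np.meshgrid(cs, ns, os_, ss, indexing="ij")
        self.c = C.ravel()
        self.n = N.ravel()
        self.o = O.ravel()
        self.s = S.ravel()
        m = MONOISOTOPIC_MASS
        base = (
            self.c * m["C"] + self.n * m["N"] + self.o * m["O"] + self.s * m["S"]
        )
        order = np.argsort(base, kind="stable")
        self.base = base[order]
        self.c, self.n, self.o, self.s = (
            self.c[order],
            self.n[order],
            self.o[order],
            self.s[order],
        )

    def candidates(self, neutral_mass: float, ppm_tolerance: float) -> list[tuple[SumFormula, float]]:
        mH = MONOISOTOPIC_MASS["H"]
        hmin, hmax = self.ranges.h
        # absolute window, slightly widened; the exact ppm criterion
        # (relative to the candidate mass) is applied per candidate below
        delta = neutral_mass * ppm_tolerance * 1e-6 * 1.001 + 1e-9
        lo = np.searchsorted(self.base, neutral_mass - delta - mH * hmax)
        hi = np.searchsorted(self.base, neutral_mass + delta - mH * hmin, side="right")
        if hi <= lo:
            return []
        base = self.base[lo:hi]
        h_floor = np.floor((neutral_mass - base) / mH)
        out: list[tuple[SumFormula, float]] = []
        for h_arr in (h_floor, h_floor + 1.0):
            ok = (h_arr >= hmin) & (h_arr <= hmax)
            cand_mass = base + h_arr * mH
            err = 1e6 * (neutral_mass - cand_mass) / cand_mass
            ok &= np.abs(err) <= ppm_tolerance
            for i in np.nonzero(ok)[0]:
                j = lo + i
                cand = SumFormula(
                    c=int(self.c[j]), h=int(h_arr[i]), n=int(self.n[j]), o=int(self.o[j]), s=int(self.s[j])
                )
                out.append((cand, float(err[i])))
        return out


_INDEX_CACHE: dict[ElementRanges, _CandidateIndex] = {}


def _index_for(ranges: ElementRanges) -> _CandidateIndex:
    idx = _INDEX_CACHE.get(ranges)
    if idx is None:
        idx = _INDEX_CACHE[ranges] = _CandidateIndex(ranges)
    return idx


def _sort_key(item: tuple[SumFormula, float]):
    f, err = item
    return (abs(err), f.n + f.s, f.h)


def assign_formulas(
    peaks,
    ranges: ElementRanges = ElementRanges(),
    ppm_tolerance: float = 2.0,
    filters: PlausibilityFilters | None = PlausibilityFilters(),
) -> list[FormulaAssignment]:
    """Assign CHNOS sum formulas to peaks by exhaustive enumeration.

    Neutral mass is taken as m/z + proton mass (singly deprotonated,
    negative mode). Candidates within ``ppm_tolerance`` that pass the
    plausibility ``filters`` are returned sorted by |ppm error|; the
    first is the chosen assignment.
    """
    if ranges.c[1] < ranges.c[0]:
        raise ValueError("empty element ranges")
    df = _as_peak_frame(peaks)
    index = _index_for(ranges)
    out = []
    for mz in df["mz"].to_numpy(dtype=float):
        cands = index.candidates(neutral_mass_from_mz(mz), ppm_tolerance)
        if filters is not None:
            cands = [c for c in cands if filters.accept(c[0])]
        cands.sort(key=_sort_key)
        out.append(FormulaAssignment(mz=float(mz), candidates=cands))
    return out


def assignment_table(peaks, assignments: list[FormulaAssignment]) -> pd.DataFrame:
    """Tabulate assignments next to their peaks (one row per peak)."""
    df = _as_peak_frame(peaks).reset_index(drop=True)
    if len(df) != len(assignments):
        raise ValueError("peak list and assignment list lengths differ")
    return pd.DataFrame(
        {
            "mz": df["mz"],
            "intensity": df["intensity"],
            "formula": [str(a.best) if a.best is not None else "" for a in assignments],
            "ppm_error": [a.best_ppm if a.best_ppm is not None else np.nan for a in assignments],
            "n_candidates": [len(a.candidates) for a in assignments],
        }
    )


def build_feature_matrix(
    sample_assignments: dict[str, pd.DataFrame],
    normalization: str = "sum",
) -> pd.DataFrame:
    """Assemble the formula x sample relative-intensity matrix.

    ``sample_assignments`` maps sample id to an assignment table with
    ``formula`` and ``intensity`` columns (rows with empty formula are
    ignored). Duplicate formulas within a sample are summed; formulas
    absent from a sample are zero. With ``normalization="sum"`` each
    sample column is divided by its total so columns sum to one.
    """
    if normalization not in ("sum", "none"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    columns = {}
    for sample, table in sample_assignments.items():
        tab = table.loc[table["formula"].astype(str) != ""]
        if tab.empty:
            raise ValueError(f"sample {sample!r} has no retained, assigned peaks")
        col = tab.groupby("formula")["intensity"].sum()
        columns[sample] = col
    matrix = pd.DataFrame(columns).fillna(0.0)
    matrix = matrix.sort_index()
    matrix.index.name = "formula"
    if normalization == "sum":
        totals = matrix.sum(axis=0)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"samples with zero total intensity: {bad}")
        matrix = matrix / totals
    return matrix
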