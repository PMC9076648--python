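"""Synthetic litter-decomposition HR-MS data with known planted
structure.

The generator emulates the study design the pipeline is built for: four
litter types (beech, oak, pine, grass) decomposed at two sites in three
replicates, leached on days 2, 4, 8, 15 and 22 (120 leachate samples;
day 0 stands for the initial litter material). Molecular features are
organised in correlated blocks driven by additive latent profiles
(litter indicator x time ramp), which plants litter-specific and
convergence module structure with a tunable within-block Pearson
correlation; intensities carry lognormal multiplicative noise because
HR-MS peak intensities are positive and right-skewed. A configurable
fraction of features receives pathway annotations with isomer
multiplicity, mirroring the fact that only a minority of DOM formulas
has database matches, each with several structure suggestions.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import PROTON_MASS, SumFormula

DEFAULT_LITTERS = ("beech", "oak", "pine", "grass")
DEFAULT_SITES = ("hainich", "linde")
DEFAULT_DAYS = (0, 2, 4, 8, 15, 22)


@dataclass(frozen=True)
class StudyDesign:
    """The factorial sampling design of the decomposition experiment."""

    litter_types: tuple[str, ...] = DEFAULT_LITTERS
    sites: tuple[str, ...] = DEFAULT_SITES
    replicates: int = 3
    time_points: tuple[int, ...] = DEFAULT_DAYS
    seed: int = 0

    @property
    def leachate_days(self) -> tuple[int, ...]:
        """Days with leachate sampling (all non-zero time points)."""
        return tuple(d for d in self.time_points if d > 0)

    @property
    def n_samples(self) -> int:
        """Number of leachate samples in the design (default 120)."""
        return (
            len(self.litter_types) * len(self.sites) * self.replicates * len(self.leachate_days)
        )

    def metadata(self, include_day0: bool = False) -> pd.DataFrame:
        """Sample metadata table: sample_id, litter, site, replicate, day."""
        days = self.time_points if include_day0 else self.leachate_days
        rows = [
            {
                "sample_id": f"{lit}_{site}_r{rep}_d{day}",
                "litter": lit,
                "site": site,
                "replicate": rep,
                "day": day,
            }
            for lit in self.litter_types
            for site in self.sites
            for rep in range(1, self.replicates + 1)
            for day in days
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Block:
    """One planted feature block and its latent driver.

    drivers: ``litter`` (indicator of one litter type x time ramp),
    ``convergence`` (indicator of a litter subset x time ramp),
    ``time`` (time ramp in every sample) and ``noise`` (no shared
    signal).
    """

    n_features: int
    driver: str
    litters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.driver not in ("litter", "convergence", "time", "noise"):
            raise ValueError(f"unknown block driver {self.driver!r}")
        if self.driver in ("litter", "convergence") and not self.litters:
            raise ValueError(f"driver {self.driver!r} needs a litter subset")


@dataclass(frozen=True)
class PlantedStructure:
    """Ground-truth structure planted into the feature matrix."""

    blocks: tuple[Block, ...] = (
        Block(50, "litter", ("beech",)),
        Block(50, "litter", ("pine",)),
        Block(50, "convergence", ("oak", "grass")),
        Block(50, "noise"),
    )
    target_r: float = 0.9
    noise_sigma: float = 0.2
    annotation_fraction: float = 0.2
    multiplicity_poisson_mean: float = 1.9  # multiplicity = 1 + Poisson(mean)
    # mean intensity of background (noise-driver) features relative to the
    # responsive blocks; a heavy unstructured background keeps sample
    # totals stable so compositional closure does not correlate everything
    background_weight: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_r <= 1.0:
            raise ValueError("within-block correlation target must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not 0.0 <= self.annotation_fraction <= 1.0:
            raise ValueError("annotation fraction must lie in [0, 1]")
        if self.background_weight <= 0:
            raise ValueError("background weight must be positive")

    @property
    def n_features(self) -> int:
        return sum(b.n_features for b in self.blocks)


def _block_label(block: Block, idx: int) -> str:
    if block.driver in ("litter", "convergence"):
        return f"{block.driver}:{'+'.join(block.litters)}"
    return f"{block.driver}:{idx}"


def random_formulas(n: int, rng: np.random.Generator) -> list[SumFormula]:
    """Distinct, DOM-plausible CHO formulas with [M-H]- well inside the
    default 175-1000 acquisition window."""
    out: dict[str, SumFormula] = {}
    while len(out) < n:
        c = int(rng.integers(10, 41))
        # H/C in ~[0.6, 1.9], even H+N so the formula is even-electron
        h = int(rng.integers(max(4, int(0.6 * c)) // 2, int(1.9 * c) // 2 + 1)) * 2
        o = int(rng.integers(1, max(2, int(0.9 * c))))
        f = SumFormula(c=c, h=h, o=o)
        if f.dbe < 0 or not (200.0 <= f.mass <= 900.0):
            continue
        out.setdefault(str(f), f)
    return list(out.values())[:n]


def _latent_profiles(design: StudyDesign, structure: PlantedStructure, meta: pd.DataFrame) -> np.ndarray:
    """One latent profile z (over samples) per block; the ramp rises
    linearly with day so litter-specific signals consolidate with time."""
    max_day = max(design.time_points) or 1
    ramp = meta["day"].to_numpy(dtype=float) / max_day
    profiles = []
    for block in structure.blocks:
        if block.driver == "noise":
            z = np.zeros(len(meta))
        elif block.driver == "time":
            z = ramp.copy()
        else:
            indicator = meta["litter"].isin(block.litters).to_numpy(dtype=float)
            z = indicator * ramp
        profiles.append(z)
    return np.asarray(profiles)


def generate_feature_matrix(
    design: StudyDesign = StudyDesign(),
    structure: PlantedStructure = PlantedStructure(),
    include_day0: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate the formula x sample relative-intensity matrix.

    Returns (matrix, metadata, truth): ``matrix`` has non-negative
    entries and column sums of one; ``truth`` labels every feature with
    its planted block. Log intensities are baseline + b * z + sigma *
    eps, with b chosen per block so the within-block Pearson correlation
    targets ``structure.target_r`` (exactly 1 in the noise-free limit).
    """
    if structure.n_features == 0:
        raise ValueError("structure has zero features")
    meta = design.metadata(include_day0=include_day0)
    if meta.empty:
        raise ValueError("design yields zero samples")
    rng = np.random.default_rng(design.seed)
    formulas = random_formulas(structure.n_features, rng)
    z_profiles = _latent_profiles(design, structure, meta)
    n_samples = len(meta)
    baseline_sd = 0.5
    sigma = structure.noise_sigma
    log_intensity = np.empty((structure.n_features, n_samples))
    truth_labels = []
    row = 0
    for bi, block in enumerate(structure.blocks):
        z = z_profiles[bi]
        z_sd = z.std()
        if block.driver == "noise" or z_sd == 0:
            b = 0.0
        elif sigma == 0 or structure.target_r >= 1.0:
            b = 1.0 / z_sd
        else:
            b = sigma * np.sqrt(structure.target_r / (1.0 - structure.target_r)) / z_sd
        baseline_mean = np.log(structure.background_weight) if block.driver == "noise" else 0.0
        baselines = rng.normal(baseline_mean, baseline_sd, size=block.n_features)
        eps = rng.standard_normal((block.n_features, n_samples))
        log_intensity[row : row + block.n_features] = (
            baselines[:, None] + b * z[None, :] + sigma * eps
        )
        truth_labels += [_block_label(block, bi)] * block.n_features
        row += block.n_features
    intensity = np.exp(log_intensity)
    intensity /= intensity.sum(axis=0, keepdims=True)
    matrix = pd.DataFrame(
        intensity, index=[str(f) for f in formulas], columns=meta["sample_id"]
    )
    matrix.index.name = "formula"
    truth = pd.Series(truth_labels, index=matrix.index, name="block")
    return matrix, meta, truth


def generate_peak_lists(
    matrix: pd.DataFrame,
    seed: int = 0,
    ppm_jitter: float = 0.0,
    sn_low_fraction: float = 0.0,
    sn_range: tuple[float, float] = (5.0, 50.0),
    blank_masses: tuple[float, ...] = (),
    intensity_scale: float = 1e6,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Invert the feature matrix into per-sample peak lists.

    Peak m/z is the deprotonated monoisotopic mass of the feature's
    formula, uniformly jittered within ``ppm_jitter``; a
    ``sn_low_fraction`` of peaks is assigned S/N <= 4 (removed by the
    default filter); ``blank_masses`` are injected into every sample and
    returned as the blank peak list. With jitter, low-S/N fraction and
    blanks all zero, filtering + assignment + matrix building recovers
    ``matrix`` exactly.
    """
    rng = np.random.default_rng(seed)
    masses = np.array([SumFormula.parse(f).mass for f in matrix.index])
    base_mz = masses - PROTON_MASS
    peak_lists: dict[str, pd.DataFrame] = {}
    for sample in matrix.columns:
        intens = matrix[sample].to_numpy(dtype=float) * intensity_scale
        jitter = rng.uniform(-ppm_jitter, ppm_jitter, size=base_mz.size) * 1e-6
        mz = base_mz * (1.0 + jitter)
        sn = rng.uniform(*sn_range, size=base_mz.size)
        n_low = int(round(sn_low_fraction * base_mz.size))
        if n_low:
            # S/N tracks intensity: low-S/N peaks are drawn weighted
            # toward the weakest intensities, never uniformly at random
            weights = 1.0 / np.maximum(intens, 1e-300)
            weights /= weights.sum()
            low = rng.choice(base_mz.size, size=n_low, replace=False, p=weights)
            sn[low] = rng.uniform(0.0, 4.0, size=n_low)
        df = pd.DataFrame({"mz": mz, "intensity": intens, "sn": sn})
        if blank_masses:
            bl = pd.DataFrame(
                {
                    "mz": list(blank_masses),
                    "intensity": rng.uniform(0.5, 2.0, len(blank_masses)) * intensity_scale * 1e-3,
                    "sn": rng.uniform(5.0, 50.0, len(blank_masses)),
                }
            )
            df = pd.concat([df, bl], ignore_index=True)
        peak_lists[sample] = df.sort_values("mz", ignore_index=True)
    blank = pd.DataFrame(
        {
            "mz": list(blank_masses),
            "intensity": [intensity_scale * 1e-3] * len(blank_masses),
            "sn": [10.0] * len(blank_masses),
        }
    )
    return peak_lists, blank


def planted_recovery_ari(truth: pd.Series, labels: pd.Series) -> float:
    """Adjusted Rand index between planted blocks and detected modules.

    Only planted (non-noise) features are compared; background features
    carry no block signal, so where they land says nothing about
    recovery of the planted structure.
    """
    from sklearn.metrics import adjusted_rand_score

    planted = truth.index[~truth.str.startswith("noise")].intersection(labels.index)
    if len(planted) == 0:
        raise ValueError("no planted features shared between truth and labels")
    return float(adjusted_rand_score(truth[planted], labels[planted]))


def generate_pathway_db(
    formulas,
    annotation_fraction: float = 0.2,
    multiplicity_poisson_mean: float = 1.9,
    n_pathways: int = 20,
    pathways_per_compound_extra: float = 0.2,
    seed: int = 0,
):
    """Generate a KEGG-style compound -> pathway annotation table.

    A fraction of formulas is annotated; each annotated formula maps to
    1 + Poisson(mean) isomeric compounds (mean 1.9 gives on average 2.9
    structure suggestions per matched formula); each compound belongs to
    one pathway plus occasional extras. Pathway sizes are the member
    count inflated by unseen members, so coverages stay below one.
    """
    from .pathways import PathwayDB

    if not 0.0 <= annotation_fraction <= 1.0:
        raise ValueError("annotation fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    formulas = [str(f) for f in formulas]
    pathway_ids = [f"map{i + 1:05d}" for i in range(n_pathways)]
    records = []
    compound_counter = 0
    n_annotated = int(round(annotation_fraction * len(formulas)))
    chosen = rng.choice(len(formulas), size=n_annotated, replace=False) if n_annotated else []
    annotated = [formulas[i] for i in sorted(chosen)]
    for f in annotated:
        multiplicity = 1 + int(rng.poisson(multiplicity_poisson_mean))
        for _ in range(multiplicity):
            compound_counter += 1
            cid = f"CPD{compound_counter:05d}"
            n_pw = 1 + int(rng.random() < pathways_per_compound_extra)
            chosen = rng.choice(n_pathways, size=min(n_pw, n_pathways), replace=False)
            for pi in chosen:
                records.append(
                    {"compound_id": cid, "formula": f, "pathway_id": pathway_ids[pi]}
                )
    rec = pd.DataFrame(records, columns=["compound_id", "formula", "pathway_id"])
    if rec.empty:
        rec["pathway_size"] = pd.Series(dtype=int)
        return PathwayDB(records=rec)
    members = rec.groupby("pathway_id")["compound_id"].nunique()
    sizes = {
        p: int(members[p] + 5 + rng.poisson(20.0)) for p in members.index
    }
    rec["pathway_size"] = rec["pathway_id"].map(sizes)
    return PathwayDB(records=rec.reset_index(drop=True))
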