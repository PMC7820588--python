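"""Seeded synthetic-data generators with recorded ground truth.

The generators emulate the processed shape of the study's three data
layers so every downstream module can be exercised against known truth:

* a glycoform quantitation table over a 2-genotype-model x 2-sex x
  2-region design with n = 3 biological replicates per group, log-normal
  intensities, glycan compositions drawn from a mammalian N-glycan
  grammar, GO CC annotation constructed so category membership is known,
  and log2 effects planted per subcellular category with per-genotype
  direction (divergent in vesicle / extracellular / plasma-membrane
  compartments, convergent in lysosome / Golgi, mirroring the biology of
  a secretory-pathway lesion);
* fragment-ion pair tables whose light/heavy split encodes a known
  acetylation stoichiometry per site, with optional multiplicative
  log-normal noise;
* cargo tracks with a known released fraction, built deterministically
  around the 2 um / 3 min release rule.

Every generator is a pure function of its config: the single integer
seed fans out into independent substreams per generator, so adding one
generator never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from glycosecretome.differential_stats import QuantTable
from glycosecretome.glycan_typing import classify_glycan, parse_composition
from glycosecretome.imaging_metrics import Track

__all__ = [
    "CategoryEffect",
    "SyntheticConfig",
    "GroundTruth",
    "simulate_glycoproteome",
    "simulate_fragment_table",
    "simulate_tracks",
]

# substream ids: appending new generators must not disturb existing ones
_STREAM_GLYCO = 1
_STREAM_FRAGMENTS = 2
_STREAM_TRACKS = 3


@dataclass(frozen=True)
class CategoryEffect:
    """Planted perturbation for glycoforms of one subcellular category."""

    affected_fraction: float
    log2_effect: float
    direction: Mapping[str, int]  # genotype -> +1 / -1

    def __post_init__(self) -> None:
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if any(d not in (-1, 1) for d in self.direction.values()):
            raise ValueError("directions must be +1 or -1")


def _default_effects() -> dict[str, CategoryEffect]:
    divergent = {"sTg": +1, "S113R": -1}
    convergent_up = {"sTg": +1, "S113R": +1}
    convergent_down = {"sTg": -1, "S113R": -1}
    return {
        "vesicle": CategoryEffect(0.8, 4.0, divergent),
        "extracellular": CategoryEffect(0.8, 4.0, divergent),
        "plasma_membrane": CategoryEffect(0.8, 4.0, divergent),
        "lysosome": CategoryEffect(0.8, 4.0, convergent_up),
        "Golgi": CategoryEffect(0.8, 4.0, convergent_down),
    }


#: One GO CC term per category, chosen so the keyword rules assign
#: exactly that category and no other.
_CATEGORY_TERMS = {
    "plasma_membrane": "plasma membrane",
    "other_membrane": "mitochondrial membrane",
    "neural": "axon",
    "ER": "endoplasmic reticulum",
    "Golgi": "Golgi apparatus",
    "cell_surface": "cell surface",
    "synapse": "synapse",
    "extracellular": "extracellular space",
    "vesicle": "transport vesicle",
    "lysosome": "lysosome",
    "secreted": "secretory granule",
    "none_listed": "cytoplasm",
}

_DEFAULT_CATEGORY_WEIGHTS = {
    "plasma_membrane": 0.12,
    "other_membrane": 0.10,
    "neural": 0.06,
    "ER": 0.12,
    "Golgi": 0.08,
    "cell_surface": 0.06,
    "synapse": 0.06,
    "extracellular": 0.10,
    "vesicle": 0.12,
    "lysosome": 0.08,
    "secreted": 0.05,
    "none_listed": 0.05,
}

_DEFAULT_TYPE_PROPORTIONS = {
    "high_mannose": 0.30,
    "paucimannose": 0.08,
    "complex_hybrid": 0.22,
    "fucose": 0.20,
    "sialic_acid": 0.20,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration shared by the three generators.

    Defaults reproduce the study design: genotypes WT / sTg / S113R,
    both sexes and brain regions, n = 3 replicates per group, ~150
    glycoproteins giving a few hundred glycoforms, log2 intensity noise
    SD 0.25, and planted log2 effects of 4 in secretory compartments.
    """

    seed: int = 0

    # glycoproteome design
    n_proteins: int = 150
    mean_extra_sites: float = 0.5       # sites/protein = 1 + Poisson(mean)
    mean_extra_glycans: float = 0.6     # glycans/site = 1 + Poisson(mean)
    genotypes: Sequence[str] = ("WT", "sTg", "S113R")
    sexes: Sequence[str] = ("F", "M")
    regions: Sequence[str] = ("cortex", "hippocampus")
    n_per_group: int = 3
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 0.25
    effects: Mapping[str, CategoryEffect] = field(default_factory=_default_effects)
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_WEIGHTS))
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TYPE_PROPORTIONS))

    # acetylation fragment table
    stoichiometry_grid: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 1))
    sites_per_stoichiometry: int = 2
    n_fragments: int = 10
    n_fractions: int = 2
    fragment_noise_sd: float = 0.05     # sigma of multiplicative log-normal noise
    base_fragment_area: float = 1e5

    # cargo tracks
    n_cells: int = 5
    tracks_per_cell: int = 20
    released_fraction: float = 0.5
    release_threshold_um: float = 2.0
    release_window_s: float = 180.0
    frame_interval_s: float = 3.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd < 0 or self.fragment_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.released_fraction <= 1.0:
            raise ValueError("released_fraction must lie in [0, 1]")
        if any(not 0.0 <= s <= 1.0 for s in self.stoichiometry_grid):
            raise ValueError("stoichiometry grid values must lie in [0, 1]")
        for weights in (self.category_weights, self.type_proportions):
            total = sum(weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"weights must sum to 1, got {total}")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream generator for one data layer."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


@dataclass
class GroundTruth:
    """Recorded truth for whichever layer a generator produced."""

    glycoforms: pd.DataFrame | None = None       # per-glycoform effects
    protein_category: dict[str, str] | None = None
    stoichiometries: pd.DataFrame | None = None  # per-site true occupancy
    tracks: pd.DataFrame | None = None           # per-track released flag


def _draw_composition(rng: np.random.Generator, glycan_type: str) -> str:
    """A composition string of the requested glycan type (by construction)."""
    if glycan_type == "high_mannose":
        return f"HexNAc(2)Hex({rng.integers(5, 10)})"
    if glycan_type == "paucimannose":
        return f"HexNAc(2)Hex({rng.integers(2, 5)})"
    if glycan_type == "complex_hybrid":
        return f"HexNAc({rng.integers(3, 7)})Hex({rng.integers(3, 8)})"
    if glycan_type == "fucose":
        return (f"HexNAc({rng.integers(2, 7)})Hex({rng.integers(3, 8)})"
                f"Fuc({rng.integers(1, 3)})")
    if glycan_type == "sialic_acid":
        fuc = rng.integers(0, 2)
        fuc_part = f"Fuc({fuc})" if fuc else ""
        return (f"HexNAc({rng.integers(3, 7)})Hex({rng.integers(4, 8)})"
                f"{fuc_part}NeuAc({rng.integers(1, 4)})")
    raise ValueError(f"unknown glycan type {glycan_type!r}")


def simulate_glycoproteome(
    config: SyntheticConfig,
) -> tuple[QuantTable, dict[str, list[str]], GroundTruth]:
    """Generate a glycoform quantitation table with annotation and truth.

    Each protein receives one true subcellular category (drawn from
    ``category_weights``) and a GO CC term that maps to exactly that
    category under the keyword rules.  Glycoforms on proteins of a
    perturbed category are shifted by ``log2_effect`` with the genotype's
    direction (with probability ``affected_fraction``); intensities are
    log-normal around per-glycoform baselines.
    """
    rng = config.rng(_STREAM_GLYCO)

    categories = list(config.category_weights)
    weights = np.array([config.category_weights[c] for c in categories], dtype=float)
    weights = weights / weights.sum()
    type_labels = list(config.type_proportions)
    type_weights = np.array([config.type_proportions[t] for t in type_labels])
    type_weights = type_weights / type_weights.sum()

    protein_category: dict[str, str] = {}
    annotation: dict[str, list[str]] = {}
    truth_rows = []
    feature_keys: list[tuple[str, int, str]] = []
    baselines: list[float] = []

    for p in range(config.n_proteins):
        protein = f"P{p:04d}"
        category = categories[rng.choice(len(categories), p=weights)]
        protein_category[protein] = category
        annotation[protein] = [_CATEGORY_TERMS[category]]
        effect = config.effects.get(category)

        n_sites = 1 + rng.poisson(config.mean_extra_sites)
        site_positions = sorted(rng.choice(np.arange(30, 900), size=n_sites,
                                           replace=False))
        for site in site_positions:
            n_glycans = 1 + rng.poisson(config.mean_extra_glycans)
            compositions: set[str] = set()
            while len(compositions) < n_glycans:
                glycan_type = type_labels[rng.choice(len(type_labels), p=type_weights)]
                compositions.add(_draw_composition(rng, glycan_type))
            for composition in sorted(compositions):
                affected = bool(effect is not None
                                and rng.random() < effect.affected_fraction)
                row = {
                    "protein_id": protein,
                    "site": int(site),
                    "composition": composition,
                    "glycan_type": classify_glycan(
                        parse_composition(composition)).label,
                    "category": category,
                    "affected": affected,
                    "log2_effect": effect.log2_effect if affected else 0.0,
                }
                for genotype in config.genotypes:
                    if genotype == "WT" or not affected or effect is None:
                        row[f"direction_{genotype}"] = 0
                    else:
                        row[f"direction_{genotype}"] = effect.direction.get(genotype, 0)
                truth_rows.append(row)
                feature_keys.append((protein, int(site), composition))
                baselines.append(rng.normal(config.baseline_log2_mean,
                                            config.baseline_log2_sd))

    truth = pd.DataFrame(truth_rows)
    baselines = np.asarray(baselines)

    samples = []
    meta_rows = []
    for genotype in config.genotypes:
        for sex in config.sexes:
            for region in config.regions:
                for rep in range(1, config.n_per_group + 1):
                    samples.append(f"{genotype}_{sex}_{region}_{rep}")
                    meta_rows.append({
                        "genotype": genotype, "sex": sex, "region": region,
                        "batch": 1 + (rep - 1) % 2,
                    })
    meta = pd.DataFrame(meta_rows, index=pd.Index(samples, name="sample_id"))

    log2 = np.empty((len(feature_keys), len(samples)))
    for j, sample in enumerate(samples):
        genotype = meta.loc[sample, "genotype"]
        shift = truth[f"direction_{genotype}"].to_numpy() * truth["log2_effect"].to_numpy()
        log2[:, j] = (baselines + shift
                      + rng.normal(0.0, config.noise_sd, size=len(feature_keys)))

    values = pd.DataFrame(
        np.power(2.0, log2),
        index=pd.MultiIndex.from_tuples(feature_keys,
                                        names=["protein_id", "site", "composition"]),
        columns=samples,
    )
    table = QuantTable(values=values, meta=meta)
    return table, annotation, GroundTruth(glycoforms=truth,
                                          protein_category=protein_category)


def simulate_fragment_table(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a light/heavy fragment-pair table with known stoichiometries.

    For each value on the stoichiometry grid, ``sites_per_stoichiometry``
    sites are generated with ``n_fragments`` fragments spread over
    ``n_fractions`` fractions.  Each fragment's total area is log-normal
    around ``base_fragment_area`` and split light : heavy = s : (1 - s);
    with ``fragment_noise_sd`` > 0 both areas receive independent
    multiplicative log-normal noise (noiseless split is exact).
    """
    rng = config.rng(_STREAM_FRAGMENTS)
    rows = []
    truth_rows = []
    site_counter = 0
    for s in config.stoichiometry_grid:
        for _ in range(config.sites_per_stoichiometry):
            site_counter += 1
            protein = f"A{site_counter:04d}"
            site = int(rng.integers(5, 500))
            truth_rows.append({"protein_id": protein, "site": site,
                               "true_stoichiometry": float(s)})
            for frag in range(config.n_fragments):
                total = config.base_fragment_area * rng.lognormal(0.0, 0.5)
                light = s * total
                heavy = (1.0 - s) * total
                if config.fragment_noise_sd > 0:
                    light *= rng.lognormal(0.0, config.fragment_noise_sd)
                    heavy *= rng.lognormal(0.0, config.fragment_noise_sd)
                rows.append({
                    "protein_id": protein,
                    "site": site,
                    "fragment_id": f"y{frag + 2}",
                    "fraction": f"F{1 + frag % config.n_fractions}",
                    "light_area": light,
                    "heavy_area": heavy,
                    "n_chem_acetyl": 1,
                    "charge": int(rng.integers(1, 4)),
                })
    columns = ["protein_id", "site", "fragment_id", "fraction",
               "light_area", "heavy_area", "n_chem_acetyl", "charge"]
    table = pd.DataFrame(rows, columns=columns)
    return table, GroundTruth(stoichiometries=pd.DataFrame(truth_rows))


def simulate_tracks(config: SyntheticConfig) -> tuple[list[Track], GroundTruth]:
    """Generate cargo tracks with a known released fraction per cell.

    Released tracks move ballistically to twice the release threshold
    within the window; retained tracks execute an out-and-back excursion
    peaking at 40% of the threshold, so net displacement stays below
    threshold under the displacement convention.  Per cell, exactly
    ``round(released_fraction * tracks_per_cell)`` tracks are released.
    """
    rng = config.rng(_STREAM_TRACKS)
    n_frames = int(config.release_window_s / config.frame_interval_s) + 1
    times = np.arange(n_frames) * config.frame_interval_s
    n_released = int(round(config.released_fraction * config.tracks_per_cell))

    tracks: list[Track] = []
    truth_rows = []
    for c in range(config.n_cells):
        cell = f"cell{c + 1}"
        origin = rng.uniform(0.0, 50.0, size=2)
        for t in range(config.tracks_per_cell):
            track_id = f"{cell}_t{t + 1}"
            angle = rng.uniform(0.0, 2.0 * np.pi)
            unit = np.array([np.cos(angle), np.sin(angle)])
            released = t < n_released
            if released:
                reach = 2.0 * config.release_threshold_um
                radial = np.linspace(0.0, reach, n_frames)
            else:
                reach = 0.4 * config.release_threshold_um
                # out-and-back: peaks mid-window, returns to origin
                radial = reach * np.sin(np.linspace(0.0, np.pi, n_frames))
            positions = origin + np.outer(radial, unit)
            tracks.append(Track(track_id=track_id, cell_id=cell,
                                times=times.copy(), positions=positions))
            truth_rows.append({"cell_id": cell, "track_id": track_id,
                               "released": released})
    return tracks, GroundTruth(tracks=pd.DataFrame(truth_rows))
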