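"""Schema-validated tabular I/O and the end-to-end pipeline.

All tables are tab-separated UTF-8 with ``.`` decimals and no thousands
separators; track and intensity tables are comma-separated.  Missing
intensities are empty fields, never 0 (zero is a legal area; the two must
not be conflated in ratio statistics).  Glycosites are 1-based residue
positions.  Every randomised step takes an explicit seed; the run log
written by :func:`run_pipeline` records the seed, package and library
versions, and every parameter, which suffices to reproduce any output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from glycosecretome.acetyl_stoichiometry import FragmentPair, aggregate_fractions
from glycosecretome.differential_stats import (
    QuantTable,
    glycoform_differential,
    records_to_frame,
)
from glycosecretome.glycan_typing import GlycanParseError, classify_glycan, parse_composition
from glycosecretome.imaging_metrics import (
    IntensitySeries,
    Track,
    mean_max_speed,
    percent_release_by_cell,
)
from glycosecretome.secretome_topology import (
    build_signed_vectors,
    euclidean_distance_matrix,
    glycan_protein_network,
    glycans_per_site,
    intersect_datasets,
    sites_per_protein,
)
from glycosecretome.subcellular_annotation import (
    SUBCELLULAR_CATEGORIES,
    assign_all,
    location_glycan_summary,
)
from glycosecretome.synthetic_data import (
    SyntheticConfig,
    simulate_fragment_table,
    simulate_glycoproteome,
    simulate_tracks,
)

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_glycoform_table",
    "write_glycoform_table",
    "read_sample_metadata",
    "read_annotation",
    "write_annotation",
    "read_fragment_table",
    "fragment_frame_to_pairs",
    "read_tracks",
    "write_tracks",
    "read_intensity_series",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

GLYCOFORM_KEY_COLUMNS = ("protein_id", "site", "composition")


class SchemaError(ValueError):
    """Raised when an input table violates its documented schema."""


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one end-to-end pipeline run."""

    seed: int = 0
    out_dir: str | Path = "pipeline_out"
    alpha: float = 0.05
    f_test_alpha: float = 0.05
    release_threshold_um: float = 2.0
    release_window_s: float = 180.0
    overlap_denominator: str = "union"
    categories: Sequence[str] = SUBCELLULAR_CATEGORIES
    synthetic: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0.0 < self.f_test_alpha < 1.0:
            raise ValueError("f_test_alpha must lie in (0, 1)")
        if self.release_threshold_um <= 0 or self.release_window_s <= 0:
            raise ValueError("imaging thresholds must be positive")

    def synthetic_config(self) -> SyntheticConfig:
        if self.synthetic is not None:
            return self.synthetic
        return SyntheticConfig(seed=self.seed)


# ---------------------------------------------------------------------------
# readers / writers


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, genotype, sex, region, batch)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "genotype", "sex", "region", "batch"}
    missing = required - set(meta.columns)
    if missing:
        raise SchemaError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids")
    return meta.set_index("sample_id")


def read_glycoform_table(
    path: str | Path, meta_path: str | Path | None = None
) -> QuantTable:
    """Read a glycoform quantitation TSV into a :class:`QuantTable`.

    Expected header: ``protein_id  site  composition  <sample columns>``.
    Sites must be positive 1-based integers; compositions are validated
    through the glycan parser; duplicate (protein, site, composition)
    rows and non-numeric intensities are schema errors reported with the
    offending line number (1-based, header = line 1).  Without a metadata
    file, samples get empty metadata.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "composition": str})
    missing = [c for c in GLYCOFORM_KEY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    sample_cols = [c for c in frame.columns if c not in GLYCOFORM_KEY_COLUMNS]
    if not sample_cols:
        raise SchemaError(f"{path}: no sample columns")

    sites = pd.to_numeric(frame["site"], errors="coerce")
    bad = sites.isna() | (sites < 1) | (sites != sites.round())
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(f"{path}: line {line}: site must be a positive integer")
    frame["site"] = sites.astype(int)

    for i, composition in enumerate(frame["composition"]):
        try:
            parse_composition(composition)
        except GlycanParseError as exc:
            raise SchemaError(f"{path}: line {i + 2}: bad composition: {exc}") from exc

    duplicated = frame.duplicated(subset=list(GLYCOFORM_KEY_COLUMNS))
    if duplicated.any():
        line = int(duplicated.idxmax()) + 2
        raise SchemaError(
            f"{path}: line {line}: duplicate (protein, site, composition) row")

    for column in sample_cols:
        numeric = pd.to_numeric(frame[column], errors="coerce")
        bad = numeric.isna() & frame[column].notna() & (frame[column].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{path}: line {line}: non-numeric intensity in column {column!r}")
        frame[column] = numeric

    values = frame.set_index(list(GLYCOFORM_KEY_COLUMNS))[sample_cols]
    if meta_path is not None:
        meta = read_sample_metadata(meta_path)
    else:
        meta = pd.DataFrame(index=pd.Index(sample_cols, name="sample_id"))
    return QuantTable(values=values, meta=meta)


def write_glycoform_table(table: QuantTable, path: str | Path) -> None:
    """Write a QuantTable back to the glycoform TSV schema (NaN -> empty)."""
    frame = table.values.reset_index()
    frame.to_csv(path, sep="\t", index=False, na_rep="")


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index().to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, list[str]]:
    """Read an annotation TSV (protein_id, cc_terms semicolon-separated)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein_id", "cc_terms"} <= set(frame.columns):
        raise SchemaError(f"{path}: annotation needs protein_id and cc_terms columns")
    annotation: dict[str, list[str]] = {}
    for row in frame.itertuples(index=False):
        terms = [] if pd.isna(row.cc_terms) else [
            t.strip() for t in str(row.cc_terms).split(";") if t.strip()]
        annotation[row.protein_id] = terms
    return annotation


def write_annotation(annotation: Mapping[str, Sequence[str]], path: str | Path) -> None:
    frame = pd.DataFrame(
        {"protein_id": list(annotation),
         "cc_terms": ["; ".join(terms) for terms in annotation.values()]})
    frame.to_csv(path, sep="\t", index=False)


def read_fragment_table(path: str | Path) -> pd.DataFrame:
    """Read a fragment-pair TSV and validate its schema."""
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "fragment_id": str,
                                               "fraction": str})
    required = {"protein_id", "site", "fragment_id", "fraction",
                "light_area", "heavy_area", "n_chem_acetyl", "charge"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing fragment columns {sorted(missing)}")
    return frame


def fragment_frame_to_pairs(frame: pd.DataFrame) -> list[FragmentPair]:
    return [
        FragmentPair(
            protein_id=row.protein_id, site=int(row.site),
            fragment_id=str(row.fragment_id), fraction=str(row.fraction),
            light_area=float(row.light_area), heavy_area=float(row.heavy_area),
            n_chemical_acetyl=int(row.n_chem_acetyl), charge=int(row.charge),
        )
        for row in frame.itertuples(index=False)
    ]


def read_tracks(path: str | Path) -> list[Track]:
    """Read a track CSV (cell_id, track_id, t_s, x_um, y_um)."""
    frame = pd.read_csv(path, dtype={"cell_id": str, "track_id": str})
    required = {"cell_id", "track_id", "t_s", "x_um", "y_um"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing track columns {sorted(missing)}")
    tracks = []
    for (cell, track_id), group in frame.groupby(["cell_id", "track_id"], sort=True):
        group = group.sort_values("t_s")
        tracks.append(Track(
            track_id=track_id, cell_id=cell,
            times=group["t_s"].to_numpy(float),
            positions=group[["x_um", "y_um"]].to_numpy(float),
        ))
    return tracks


def write_tracks(tracks: Sequence[Track], path: str | Path) -> None:
    rows = []
    for track in tracks:
        for t, (x, y) in zip(track.times, track.positions):
            rows.append({"cell_id": track.cell_id, "track_id": track.track_id,
                         "t_s": t, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_intensity_series(path: str | Path) -> list[IntensitySeries]:
    """Read an intensity CSV (cell_id, t_min, intensity)."""
    frame = pd.read_csv(path, dtype={"cell_id": str})
    required = {"cell_id", "t_min", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing intensity columns {sorted(missing)}")
    series = []
    for cell, group in frame.groupby("cell_id", sort=True):
        group = group.sort_values("t_min")
        series.append(IntensitySeries(
            cell_id=cell, times=group["t_min"].to_numpy(float),
            values=group["intensity"].to_numpy(float)))
    return series


# ---------------------------------------------------------------------------
# end-to-end pipeline


def classify_table(table: QuantTable) -> pd.DataFrame:
    """Glycan-type classification for every glycoform of a quant table."""
    rows = []
    for protein, site, composition in table.values.index:
        label = classify_glycan(parse_composition(composition)).label
        rows.append({"protein_id": protein, "site": site,
                     "composition": composition, "glycan_type": label})
    return pd.DataFrame(rows)


def _dataset_comparisons(table: QuantTable) -> dict[str, tuple[dict, dict]]:
    """Non-WT (genotype, sex, region) groups vs their matched WT group."""
    meta = table.meta
    comparisons = {}
    groups = meta[["genotype", "sex", "region"]].drop_duplicates()
    for row in groups.itertuples(index=False):
        if row.genotype == "WT":
            continue
        name = f"{row.genotype}_{row.sex}_{row.region}"
        comparisons[name] = (
            {"genotype": row.genotype, "sex": row.sex, "region": row.region},
            {"genotype": "WT", "sex": row.sex, "region": row.region},
        )
    return comparisons


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run simulate -> classify -> diff -> stoich -> annotate -> topology -> imaging.

    Writes every stage's table under ``config.out_dir`` plus a JSON run
    log, and returns a name -> path map of the emitted files.  The run is
    a pure function of the config (seed included).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    syn = config.synthetic_config()
    current_stage = "setup"

    def _stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("pipeline stage: %s", name)

    try:
        _stage("simulate")
        table, annotation, truth = simulate_glycoproteome(syn)
        fragments, frag_truth = simulate_fragment_table(syn)
        tracks, track_truth = simulate_tracks(syn)

        paths["glycoforms"] = out / "glycoforms.tsv"
        write_glycoform_table(table, paths["glycoforms"])
        paths["samples"] = out / "samples.tsv"
        write_sample_metadata(table.meta, paths["samples"])
        paths["annotation"] = out / "annotation.tsv"
        write_annotation(annotation, paths["annotation"])

        _stage("classify")
        classified = classify_table(table)
        paths["glycan_types"] = out / "glycan_types.tsv"
        classified.to_csv(paths["glycan_types"], sep="\t", index=False)

        _stage("diff")
        diff_frames = []
        diff_records = {}
        for dataset, (sel_a, sel_b) in _dataset_comparisons(table).items():
            records = glycoform_differential(table, sel_a, sel_b, alpha=config.alpha)
            diff_records[dataset] = records
            frame = records_to_frame(records)
            frame.insert(0, "dataset", dataset)
            diff_frames.append(frame)
        differential = pd.concat(diff_frames, ignore_index=True)
        paths["differential"] = out / "differential.tsv"
        differential.to_csv(paths["differential"], sep="\t", index=False)

        _stage("stoich")
        stoich = aggregate_fractions(fragment_frame_to_pairs(fragments))
        stoich_frame = pd.DataFrame([
            {"protein_id": r.protein_id, "site": r.site,
             "stoichiometry": r.stoichiometry, "n_fragments": r.n_fragments,
             "n_fractions": r.n_fractions} for r in stoich])
        paths["stoichiometry"] = out / "stoichiometry.tsv"
        stoich_frame.to_csv(paths["stoichiometry"], sep="\t", index=False)

        _stage("annotate")
        assignment = assign_all(annotation)
        assignment_frame = pd.DataFrame(
            {"protein_id": list(assignment),
             "categories": ["; ".join(sorted(c)) for c in assignment.values()]})
        paths["subcellular"] = out / "subcellular.tsv"
        assignment_frame.to_csv(paths["subcellular"], sep="\t", index=False)

        type_by_key = classified.set_index(
            ["protein_id", "site", "composition"])["glycan_type"]
        sig = differential[differential["significant"]].copy()
        sig["glycan_type"] = [
            type_by_key[(r.protein_id, r.site, r.composition)]
            for r in sig.itertuples(index=False)]
        summary = location_glycan_summary(
            sig.drop_duplicates(subset=["protein_id", "site", "composition"]),
            assignment)
        paths["location_summary"] = out / "location_glycan_summary.tsv"
        summary.to_csv(paths["location_summary"], sep="\t")

        _stage("topology")
        vectors = build_signed_vectors(diff_records, assignment,
                                       list(config.categories))
        distances = euclidean_distance_matrix(vectors)
        paths["distances"] = out / "distance_matrix.tsv"
        distances.to_csv(paths["distances"], sep="\t")

        protein_sets = {
            dataset: {r.feature[0] for r in records if r.significant}
            for dataset, records in diff_records.items()}
        upset = intersect_datasets(protein_sets)
        upset_frame = pd.DataFrame(
            [{"pattern": "&".join(sorted(pattern)), "count": count}
             for pattern, count in sorted(upset["patterns"].items(),
                                          key=lambda kv: ("&".join(sorted(kv[0]))))])
        paths["upset"] = out / "upset.tsv"
        upset_frame.to_csv(paths["upset"], sep="\t", index=False)

        het_rows = []
        for dataset, records in diff_records.items():
            sig_frame = records_to_frame([r for r in records if r.significant])
            if sig_frame.empty:
                sig_frame = pd.DataFrame(
                    columns=["protein_id", "site", "composition"])
            site_dist = glycans_per_site(sig_frame)
            prot_dist = sites_per_protein(sig_frame)
            het_rows.append({
                "dataset": dataset,
                "n_sites": site_dist["n_single"] + site_dist["n_multi"],
                "multi_glycan_sites": site_dist["n_multi"],
                "fraction_multi_glycan_sites": site_dist["fraction_multi"],
                "n_proteins": prot_dist["n_single"] + prot_dist["n_multi"],
                "multi_site_proteins": prot_dist["n_multi"],
                "fraction_multi_site_proteins": prot_dist["fraction_multi"],
            })
        paths["heterogeneity"] = out / "heterogeneity.tsv"
        pd.DataFrame(het_rows).to_csv(paths["heterogeneity"], sep="\t", index=False)

        edges = glycan_protein_network(sig)
        paths["network"] = out / "network_edges.tsv"
        edges.to_csv(paths["network"], sep="\t", index=False)

        _stage("imaging")
        paths["tracks"] = out / "tracks.csv"
        write_tracks(tracks, paths["tracks"])
        release = percent_release_by_cell(
            tracks, distance_threshold=config.release_threshold_um,
            window=config.release_window_s)
        by_cell: dict[str, list[Track]] = {}
        for track in tracks:
            by_cell.setdefault(track.cell_id, []).append(track)
        imaging_frame = pd.DataFrame(
            [{"cell_id": cell, "percent_release": release[cell],
              "mean_max_speed_um_s": mean_max_speed(by_cell[cell])}
             for cell in sorted(by_cell)])
        paths["imaging"] = out / "imaging_metrics.tsv"
        imaging_frame.to_csv(paths["imaging"], sep="\t", index=False)

        _stage("report")
        from glycosecretome import __version__ as pkg_version

        log = {
            "seed": config.seed,
            "package_version": pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "parameters": {
                "alpha": config.alpha,
                "f_test_alpha": config.f_test_alpha,
                "release_threshold_um": config.release_threshold_um,
                "release_window_s": config.release_window_s,
                "overlap_denominator": config.overlap_denominator,
                "categories": list(config.categories),
                "synthetic": _jsonable(asdict(syn)),
            },
            "outputs": {name: str(path) for name, path in paths.items()},
        }
        paths["run_log"] = out / "run_log.json"
        paths["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {current_stage!r}: {exc}") from exc
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
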