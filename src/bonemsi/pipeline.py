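"""Config-driven orchestration of the full analysis.

Stages: load (imzML + ROI masks) -> preprocess (RMS normalization, overall
mean spectrum, peak picking, datacubes) -> segment (pLSA with background
identification, peak association, PCA) -> annotate (metabolites + glycans,
exogenous filter) -> stats (volcano, class composition, pathway enrichment)
-> network (spatial Spearman correlation graph).  Every output table starts
with a comment line carrying the config hash; a run log echoes parameters
and the package version.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    annotate_glycans,
    annotate_peaks,
    filter_exogenous,
    write_annotations,
)
from .db import MetaboliteDB, load_default_db
from .io import MSIDataset, ROIMask, read_imzml, read_roi_mask
from .network import build_network, export_graph, network_tables
from .preprocess import (
    DataCube,
    PeakList,
    build_datacube,
    mean_spectrum,
    pick_peaks,
    rms_normalize,
)
from .segmentation import assign_peaks, fit_pca, fit_plsa, identify_background, segment_pixels
from .stats import CORTICAL_LABELS, class_composition, compute_group_stats, ora_enrichment

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("preprocess", "segment", "annotate", "stats", "network")


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    ``sections`` lists (imzml path, mask path, group) triples; groups must
    take exactly two values, the first of ``groups`` being the reference.
    """

    sections: list[dict] = field(default_factory=list)
    db_path: str | None = None           # None -> bundled reference table
    groups: tuple[str, str] = ("WT", "Hyp")
    snr: float = 3.0
    tol_ppm: float = 4.0
    fc_cut: float = 1.0
    alpha: float = 0.05
    n_components: int = 4
    seed: int = 0
    noise_window: float = 1.0            # Da, MAD window for peak picking
    min_peak_separation_ppm: float = 50.0  # merge maxima closer than this
    roi_labels: tuple[str, ...] = CORTICAL_LABELS
    outdir: str = "bonemsi_out"

    def validate(self) -> None:
        if not self.sections:
            raise ValueError("config lists no sections")
        for sec in self.sections:
            for key in ("imzml", "mask", "group"):
                if key not in sec:
                    raise ValueError(f"section entry missing {key!r}: {sec}")
            for key in ("imzml", "mask"):
                if not Path(sec[key]).exists():
                    raise FileNotFoundError(f"missing input file {sec[key]}")
            if sec["group"] not in self.groups:
                raise ValueError(
                    f"section group {sec['group']!r} not in {self.groups}"
                )
        if self.db_path is not None and not Path(self.db_path).exists():
            raise FileNotFoundError(f"missing database file {self.db_path}")
        if not (self.snr > 0 and self.tol_ppm > 0 and self.fc_cut >= 0):
            raise ValueError("snr, tol_ppm must be positive; fc_cut >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = PipelineConfig(**raw)
        cfg.groups = tuple(cfg.groups)
        cfg.roi_labels = tuple(cfg.roi_labels)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["groups"] = list(self.groups)
        payload["roi_labels"] = list(self.roi_labels)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc
        return inner
    return wrap


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


@_stage("load")
def _load(config: PipelineConfig):
    datasets, masks = [], []
    for i, sec in enumerate(config.sections):
        ds = read_imzml(sec["imzml"], group=sec["group"])
        mask = read_roi_mask(
            sec["mask"], ds, group=sec["group"],
            section_id=sec.get("section_id", ds.section_id),
        )
        datasets.append(ds)
        masks.append(mask)
    return datasets, masks


@_stage("preprocess")
def _preprocess(config: PipelineConfig, datasets, outdir: Path, cfg_hash: str):
    normalized = [rms_normalize(ds) for ds in datasets]
    # overall mean spectrum: per-section means averaged on the first
    # section's axis (sections may carry different calibration jitter)
    axis, acc = None, None
    for ds in normalized:
        mz, spec = mean_spectrum(ds)
        if axis is None:
            axis, acc = mz, spec.copy()
        else:
            acc += np.interp(axis, mz, spec, left=0.0, right=0.0)
    overall = acc / len(normalized)
    peaks = pick_peaks(axis, overall, snr_threshold=config.snr,
                       noise_window=config.noise_window,
                       min_separation_ppm=config.min_peak_separation_ppm)
    cubes = [
        build_datacube(ds, peaks, tol_ppm=config.tol_ppm) for ds in normalized
    ]
    peaks.to_tsv(outdir / "peaklist.tsv", header_comment=f"config_sha256={cfg_hash}")
    cubes[0].to_tsv(outdir / "datacube_section0.tsv",
                    header_comment=f"config_sha256={cfg_hash}")
    return peaks, cubes


@_stage("segment")
def _segment(config: PipelineConfig, cubes, masks, outdir: Path, cfg_hash: str):
    # single-section pLSA on the first section of the non-reference group
    idx = next(
        (i for i, m in enumerate(masks) if m.group == config.groups[1]), 0
    )
    cube, mask = cubes[idx], masks[idx]
    model = fit_plsa(cube, config.n_components, seed=config.seed)
    model.background = identify_background(model, _background_pixels(cube, mask))
    labels, counts = assign_peaks(model)
    seg = segment_pixels(model)

    seg_df = pd.DataFrame(seg)
    _write_table(seg_df, outdir / "segmentation_labels.tsv", cfg_hash)
    assoc = pd.DataFrame(
        {"peak_mz": cube.peak_centers, "component": labels}
    )
    _write_table(assoc, outdir / "peak_components.tsv", cfg_hash)
    scores, loadings, evr = fit_pca(cube, min(3, cube.n_peaks))
    _write_table(
        pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])]),
        outdir / "pca_scores.tsv", cfg_hash,
    )

    # group-level pLSA on per-section cortical mean spectra
    roi_means, groups = [], []
    for c, m in zip(cubes, masks):
        sel = _roi_pixels(c, m, config.roi_labels)
        roi_means.append(c.values[sel].mean(axis=0))
        groups.append(m.group)
    group_cube = DataCube(
        np.asarray(roi_means),
        np.column_stack([np.arange(len(roi_means)), np.zeros(len(roi_means), int)]),
        cube.peak_centers,
    )
    gmodel = fit_plsa(group_cube, 2, seed=config.seed)
    gscores = gmodel.pixel_scores()
    _write_table(
        pd.DataFrame(
            {"section": [m.section_id for m in masks], "group": groups,
             "score_c1": gscores[:, 0], "score_c2": gscores[:, 1]}
        ),
        outdir / "group_plsa_scores.tsv", cfg_hash,
    )
    return model, labels, counts


def _background_pixels(cube: DataCube, mask: ROIMask) -> np.ndarray:
    xs, ys = cube.coordinates[:, 0], cube.coordinates[:, 1]
    return np.flatnonzero(mask.labels[ys, xs] == mask.index_of("background"))


def _roi_pixels(cube: DataCube, mask: ROIMask, labels) -> np.ndarray:
    wanted = [mask.index_of(lb) for lb in labels]
    xs, ys = cube.coordinates[:, 0], cube.coordinates[:, 1]
    return np.flatnonzero(np.isin(mask.labels[ys, xs], wanted))


@_stage("annotate")
def _annotate(config: PipelineConfig, peaks: PeakList, db: MetaboliteDB,
              outdir: Path, cfg_hash: str):
    annos = filter_exogenous(
        annotate_peaks(peaks, db, tol_ppm=config.tol_ppm)
    )
    glycans = annotate_glycans(peaks, tol_ppm=config.tol_ppm)
    write_annotations(
        annos + glycans, outdir / "annotations.tsv",
        header_comment=f"config_sha256={cfg_hash}",
    )
    return annos, glycans


@_stage("stats")
def _stats(config: PipelineConfig, cubes, masks, annos, db: MetaboliteDB,
           outdir: Path, cfg_hash: str):
    table, counts = compute_group_stats(
        list(zip(cubes, masks)), *config.groups,
        roi_labels=config.roi_labels, fc_cut=config.fc_cut, alpha=config.alpha,
    )
    _write_table(table, outdir / "stat_table.tsv", cfg_hash)
    classes = class_composition(annos, table)
    _write_table(classes, outdir / "class_composition.tsv", cfg_hash)

    annotated_mz = {a.peak_mz for a in annos}
    changed = table[table["direction"] != "ns"]
    best_id: dict[float, str] = {}
    for a in sorted(annos, key=lambda r: (r.peak_mz, abs(r.ppm), r.record_id)):
        best_id.setdefault(a.peak_mz, a.record_id)
    background_ids = {best_id[mz] for mz in table["peak_mz"] if mz in best_id}
    hit_ids = {best_id[mz] for mz in changed["peak_mz"] if mz in best_id}
    enrichment = ora_enrichment(hit_ids, db.pathway_sets(), background_ids)
    _write_table(enrichment, outdir / "enrichment.tsv", cfg_hash)
    return table, counts, enrichment


@_stage("network")
def _network(config: PipelineConfig, annos, table, cubes, masks,
             outdir: Path, cfg_hash: str):
    idx = next(
        (i for i, m in enumerate(masks) if m.group == config.groups[1]), 0
    )
    net = build_network(
        annos, table, cubes[idx], masks[idx],
        roi_labels=config.roi_labels, alpha=config.alpha,
    )
    export_graph(net, outdir / "network.graphml")
    node_df, edge_df = network_tables(net)
    _write_table(node_df, outdir / "network_nodes.tsv", cfg_hash)
    _write_table(edge_df, outdir / "network_edges.tsv", cfg_hash)
    return net


def run_pipeline(
    config: PipelineConfig,
    datasets: list[MSIDataset] | None = None,
    masks: list[ROIMask] | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Run the analysis end to end, writing all artifacts under
    ``config.outdir``.

    ``datasets``/``masks`` may be passed directly (e.g. fresh from the
    phantom generator) to skip the load stage; otherwise they are read from
    the paths in the config.  Returns the in-memory results keyed by stage.
    Any stage error aborts with a stage-named message; artifacts written by
    earlier stages are preserved.
    """
    if datasets is None:
        config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    db = (
        MetaboliteDB.from_tsv(config.db_path)
        if config.db_path
        else load_default_db()
    )
    if datasets is None:
        datasets, masks = _load(config)
    if masks is None or len(masks) != len(datasets):
        raise PipelineError("stage 'load': masks missing or mismatched")

    results: dict = {"config_hash": cfg_hash}
    peaks, cubes = _preprocess(config, datasets, outdir, cfg_hash)
    results["peaks"], results["cubes"] = peaks, cubes
    if "segment" in stages:
        model, labels, counts = _segment(config, cubes, masks, outdir, cfg_hash)
        results["model"], results["peak_components"] = model, labels
        results["component_counts"] = counts
    if "annotate" in stages or "stats" in stages or "network" in stages:
        annos, glycans = _annotate(config, peaks, db, outdir, cfg_hash)
        results["annotations"], results["glycans"] = annos, glycans
    if "stats" in stages or "network" in stages:
        table, counts, enrichment = _stats(
            config, cubes, masks, annos, db, outdir, cfg_hash
        )
        results["stat_table"], results["volcano_counts"] = table, counts
        results["enrichment"] = enrichment
    if "network" in stages:
        results["network"] = _network(
            config, annos, table, cubes, masks, outdir, cfg_hash
        )

    log = outdir / "run_log.txt"
    with open(log, "w") as fh:
        fh.write(f"bonemsi {__version__}\nconfig_sha256={cfg_hash}\n")
        for key, val in sorted(asdict(config).items()):
            if key != "sections":
                fh.write(f"{key} = {val}\n")
        fh.write(f"n_sections = {len(datasets)}\n")
        fh.write(f"n_peaks = {len(peaks)}\n")
        if "volcano_counts" in results:
            fh.write(f"volcano = {results['volcano_counts']}\n")
    results["log"] = log
    return results
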