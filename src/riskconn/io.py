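"""Formats, run configuration, and the end-to-end pipeline driver.

Volumes are NIfTI-1 (via nibabel), tables are tab-separated with a header
row, and every pipeline run writes a JSON manifest listing each artifact
with its SHA-256 hash and the fully resolved configuration, so reruns with
identical seeds are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import fcd, grp, inference, preprocess, rsfc, synthetic
from .grid import BOLDSeries, BrainGrid


# ---------------------------------------------------------------------------
# volumes and tables


def write_volume(path: str | Path, volume: np.ndarray, grid: BrainGrid) -> Path:
    """Write a 3D/4D volume as NIfTI-1 with the grid's affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer) and data.itemsize > 4:
        data = data.astype(np.int32)  # NIfTI-1 has no portable 64-bit int
    img = nib.Nifti1Image(data, affine=grid.affine)
    img.header.set_zooms((grid.voxel_size,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, expected_grid: BrainGrid | None = None):
    """Read a NIfTI-1 volume; returns (data, grid). Validates dims/affine
    against ``expected_grid`` when given."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine
    dims = tuple(int(d) for d in data.shape[:3])
    voxel = float(abs(affine[0, 0]))
    grid = BrainGrid(dims=dims, voxel_size=voxel, affine=affine)
    if expected_grid is not None:
        if dims != tuple(expected_grid.dims):
            raise ValueError(
                f"volume dims {dims} do not match expected grid {expected_grid.dims}")
        if not np.allclose(affine, expected_grid.affine, atol=1e-4):
            raise ValueError("volume affine does not match the expected grid")
    return data, grid


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run.

    Defaults follow the reference analysis protocol: discard 10 volumes,
    0.01-0.1 Hz band, connectivity threshold r > 0.6, 26-neighbourhood,
    8 mm FWHM smoothing, cluster-forming voxel p < 0.001 (0.005 for the
    seed-level maps), family-wise alpha 0.05, 1000 Monte Carlo iterations.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    # cohort
    n_recruited: int = 60
    exclusions: dict = field(default_factory=lambda: {
        "missing_behavior": 1, "raw_error": 1, "bad_raw": 1, "excess_motion": 2})
    sex_split: tuple[int, int] | None = None
    # acquisition
    grid_dims: tuple[int, int, int] = (16, 16, 12)
    voxel_size: float = 3.0
    n_volumes: int = 180
    tr: float = 2.0
    # preprocessing
    k_discard: int = 10
    f_lo: float = 0.01
    f_hi: float = 0.1
    filter_method: str = "butterworth"
    trans_limit_mm: float = 2.0
    rot_limit_deg: float = 2.0
    # FCD
    r_min: float = 0.6
    adjacency: int = 26
    fwhm_mm: float = 8.0
    # group inference
    voxel_p: float = 0.001
    rsfc_voxel_p: float = 0.005
    fwe_alpha: float = 0.05
    n_iter: int = 1000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        if self.sex_split is not None:
            d["sex_split"] = list(self.sex_split)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "grid_dims" in raw:
            raw["grid_dims"] = tuple(raw["grid_dims"])
        if raw.get("sex_split") is not None:
            raw["sex_split"] = tuple(raw["sex_split"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-cohort analysis and return the manifest.

    Stages: simulate -> motion QC -> preprocess -> trait-score extraction ->
    FCD mapping -> FCD-arm group inference -> seed selection -> seed-based
    connectivity -> RSFC-arm group inference -> simple-slopes probe. Every
    artifact lands under ``config.out_dir`` and is listed in
    ``manifest.json`` with its SHA-256.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def record(path: Path) -> None:
        artifacts[str(path.relative_to(out))] = sha256_file(path)

    grid = BrainGrid(dims=config.grid_dims, voxel_size=config.voxel_size)
    rng = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(
                 ["roster", "scores", "motion", "bold", "mc"], rng.spawn(5))}

    # --- simulate ---------------------------------------------------------
    roster = synthetic.generate_roster(
        config.n_recruited, config.exclusions, config.sex_split,
        seed=seeds["roster"])
    table, latent = synthetic.generate_questionnaire_scores(
        roster, seed=seeds["scores"])
    traces = synthetic.generate_motion_traces(
        roster, n_volumes=config.n_volumes, seed=seeds["motion"])
    record(write_table(out / "roster.tsv", roster.table))
    record(write_table(out / "questionnaire.tsv", table))

    # --- trait score ------------------------------------------------------
    grp_scores, pca = grp.extract_grp(table)
    record(write_table(out / "grp_loadings.tsv",
                       pca.loadings_frame().reset_index(names="variable")))
    record(write_table(out / "grp_scores.tsv", grp_scores.frame()))
    adequacy = pd.DataFrame([{
        "kmo": grp.sampling_adequacy(table),
        "bartlett_chi2": grp.bartlett_test(table)[0],
        "bartlett_df": grp.bartlett_test(table)[1],
        "bartlett_p": grp.bartlett_test(table)[2],
        "retained_components": pca.retained_k,
    }])
    record(write_table(out / "grp_adequacy.tsv", adequacy))

    # --- BOLD + QC + preprocessing + FCD ----------------------------------
    spec = synthetic.two_roi_spec(grid)
    bolds = synthetic.generate_bold_dataset(
        roster, grid, spec, grp_scores.score, n_volumes=config.n_volumes,
        tr=config.tr, seed=seeds["bold"])
    mask = next(iter(bolds.values())).mask
    record(write_volume(out / "mask.nii", mask, grid))

    qc_rows, kept_ids, norm_short, norm_long = [], [], [], []
    zero_variance_total = 0
    for sid, bold in bolds.items():
        qc = preprocess.motion_qc(traces[sid], config.trans_limit_mm,
                                  config.rot_limit_deg)
        qc_rows.append({"subject_id": sid, "decision": qc.decision,
                        "offending_kind": qc.offending_kind or "",
                        "offending_axis": qc.offending_axis or ""})
        if not qc.keep:
            continue
        clean = preprocess.preprocess_subject(
            bold, traces[sid], config.k_discard, config.f_lo, config.f_hi,
            config.filter_method)
        maps = fcd.compute_fcd_maps(clean, config.r_min, config.adjacency)
        zero_variance_total += maps.n_zero_variance
        normed = fcd.smooth_and_normalize(maps, grid, config.fwhm_mm)
        norm_short.append(normed.short)
        norm_long.append(normed.long)
        kept_ids.append(sid)
    record(write_table(out / "motion_qc.tsv", pd.DataFrame(qc_rows)))
    if len(kept_ids) <= 4:
        raise RuntimeError("too few subjects survive motion QC for group inference")

    keep_mask = grp_scores.frame()["subject_id"].isin(kept_ids).to_numpy()
    grp_kept = grp_scores.score[keep_mask]
    sex_kept = roster.retained["sex"].to_numpy()[keep_mask]
    design = inference.build_design(grp_kept, sex_kept)

    # --- FCD-arm group inference -----------------------------------------
    mc = inference.mc_cluster_threshold(
        mask, grid, config.fwhm_mm, config.voxel_p, config.fwe_alpha,
        config.n_iter, config.adjacency, seed=seeds["mc"])
    cluster_tables = {}
    stat_arms = {"short": np.stack(norm_short), "long": np.stack(norm_long)}
    seed_roi = None
    for arm, data in stat_arms.items():
        stats_maps = inference.voxelwise_glm(data, design, mask)
        record(write_volume(out / f"fcd_{arm}_t_grp.nii",
                            stats_maps.t["grp"], grid))
        record(write_volume(out / f"fcd_{arm}_f_interaction.nii",
                            stats_maps.f_interaction, grid))
        clusters = inference.extract_clusters(
            stats_maps.f_interaction, mask, grid, stats_maps.df_resid,
            config.voxel_p, mc.min_extent_mm3, config.adjacency, stat="F")
        cluster_tables[arm] = clusters
        record(write_table(out / f"fcd_{arm}_interaction_clusters.tsv", clusters))
        if seed_roi is None and len(clusters):
            # largest surviving interaction cluster becomes the RSFC seed
            from scipy import stats as _st

            thr_f = _st.f.isf(config.voxel_p, 1, stats_maps.df_resid)
            sel = (stats_maps.f_interaction > thr_f) & mask
            labels, _ = ndimage_label(sel, config.adjacency)
            sizes = np.bincount(labels.ravel())
            top_lab = int(np.argmax(sizes[1:]) + 1)
            vox = np.argwhere(labels == top_lab)
            seed_roi = rsfc.SeedROI(name=f"fcd_{arm}_interaction_peak", voxels=vox)
    if seed_roi is None:  # no surviving cluster at this scale: planted ROI fallback
        seed_roi = rsfc.SeedROI(name="roi_a", voxels=spec.rois["roi_a"])

    # --- RSFC arm ---------------------------------------------------------
    zmaps = []
    for sid in kept_ids:
        clean = preprocess.preprocess_subject(
            bolds[sid], traces[sid], config.k_discard, config.f_lo,
            config.f_hi, config.filter_method)
        series = rsfc.extract_seed_series(clean, seed_roi)
        zmaps.append(rsfc.compute_rsfc_zmap(clean, series, seed_roi.name))
    conn_mask = rsfc.connectivity_mask(zmaps, voxel_p=0.001)
    # exclude the seed's own voxels from the constrained search
    conn_mask[tuple(seed_roi.voxels.T)] = False
    record(write_volume(out / "rsfc_connectivity_mask.nii", conn_mask, grid))
    rsfc_report = {"seed": seed_roi.name, "connectivity_mask_voxels":
                   int(conn_mask.sum())}
    if conn_mask.sum() >= 2:
        zdata = np.stack([m.z for m in zmaps])
        stats_maps = inference.voxelwise_glm(zdata, design, conn_mask)
        mc_rsfc = inference.mc_cluster_threshold(
            conn_mask, grid, config.fwhm_mm, config.rsfc_voxel_p,
            config.fwe_alpha, config.n_iter, config.adjacency,
            seed=seeds["mc"] + 1)
        clusters = inference.extract_clusters(
            stats_maps.f_interaction, conn_mask, grid, stats_maps.df_resid,
            config.rsfc_voxel_p, mc_rsfc.min_extent_mm3, config.adjacency,
            stat="F")
        record(write_table(out / "rsfc_interaction_clusters.tsv", clusters))
        rsfc_report["mc_min_extent_mm3"] = mc_rsfc.min_extent_mm3
        # ROI-average validation + simple slopes on the other planted region
        target = rsfc.SeedROI(name="roi_b", voxels=spec.rois["roi_b"])
        if conn_mask[tuple(target.voxels.T)].any():
            vox = target.voxels[conn_mask[tuple(target.voxels.T)]]
            target = rsfc.SeedROI(name="roi_b", voxels=vox)
        values = inference.roi_average(zdata, target, mask)
        slopes = inference.probe_interaction(values, grp_kept, sex_kept)
        record(write_table(out / "rsfc_simple_slopes.tsv", slopes.frame()))

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "n_recruited": config.n_recruited,
        "n_retained_roster": roster.n_retained,
        "n_after_motion_qc": len(kept_ids),
        "grp_component_index": int(grp_scores.component_index),
        "mc_min_extent_mm3": mc.min_extent_mm3,
        "mc_min_extent_voxels": mc.min_extent_voxels,
        "fcd_interaction_clusters": {
            arm: int(len(t)) for arm, t in cluster_tables.items()},
        "zero_variance_voxels_logged": zero_variance_total,
        "rsfc": rsfc_report,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def ndimage_label(volume: np.ndarray, adjacency: int):
    from scipy import ndimage

    return ndimage.label(volume, structure=fcd.adjacency_structure(adjacency))
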