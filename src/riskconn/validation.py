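"""Recovery and calibration studies run on synthetic cohorts.

Each function here sets up a planted-truth simulation, runs the analysis
modules on it, and reports how well the truth is recovered. They are used
by the test suite, by the acceptance script and by the numbered analysis
drivers, so the exact study conditions live in one place.

`bruteforce_fcd` is an intentionally naive O(N^2) + breadth-first-search
reference implementation of the density maps, kept free of the production
code path so the two can check each other.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import fcd, grp, inference, preprocess, rsfc, synthetic
from .grid import BOLDSeries, BrainGrid, make_gray_mask

GRAY_MASK_VOXELS = 55342  # gray-matter mask size of the reference analysis

_OFFSETS = {
    6: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
        for dz in (-1, 0, 1) if abs(dx) + abs(dy) + abs(dz) == 1],
    18: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1) if 0 < abs(dx) + abs(dy) + abs(dz) <= 2],
    26: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
         for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)],
}


# ---------------------------------------------------------------------------
# brute-force FCD reference


def bruteforce_fcd(bold: BOLDSeries, r_min: float = 0.6, adjacency: int = 26):
    """Reference global/short/long FCD by explicit pairwise loops and BFS.

    Global: count pairwise Pearson correlations above threshold, one pair at
    a time. Short-range: breadth-first growth from each seed over spatially
    adjacent suprathreshold voxels. Long-range: the difference.
    """
    coords = [tuple(c) for c in np.argwhere(bold.mask)]
    ts = bold.masked_series().astype(float)
    n = len(coords)
    index = {c: i for i, c in enumerate(coords)}
    offsets = _OFFSETS[adjacency]

    def corr(i, j):
        a, b = ts[i], ts[j]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    global_map = np.zeros(bold.grid.dims, dtype=np.int64)
    short_map = np.zeros(bold.grid.dims, dtype=np.int64)
    connected = [[corr(i, j) > r_min if i != j else False for j in range(n)]
                 for i in range(n)]
    for i, ci in enumerate(coords):
        global_map[ci] = sum(connected[i])
        # BFS growth: start at the seed, expand through adjacent voxels that
        # are themselves connected to the seed, until closure
        members = {i}
        frontier = [i]
        while frontier:
            nxt = []
            for m in frontier:
                cm = coords[m]
                for off in offsets:
                    c2 = (cm[0] + off[0], cm[1] + off[1], cm[2] + off[2])
                    j = index.get(c2)
                    if j is None or j in members or not connected[i][j]:
                        continue
                    members.add(j)
                    nxt.append(j)
            frontier = nxt
        short_map[ci] = len(members) - 1
    return global_map, short_map, global_map - short_map


def fcd_oracle_agreement(n_grids: int = 25, seed: int = 0,
                         max_dim: int = 6, n_volumes: int = 20) -> float:
    """Fraction of random small grids on which the production FCD maps equal
    the brute-force reference exactly (all three maps, every voxel)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_grids):
        dims = tuple(int(d) for d in rng.integers(3, max_dim + 1, size=3))
        grid = BrainGrid(dims=dims)
        mask = rng.random(dims) < 0.8
        mask.flat[:2] = True  # at least two in-mask voxels
        # a few shared latent signals make both short- and long-range edges
        latents = rng.standard_normal((3, n_volumes))
        assign = rng.integers(0, 4, size=dims)
        data = rng.standard_normal(dims + (n_volumes,))
        for lab in range(3):
            data[assign == lab] = latents[lab] + 0.4 * data[assign == lab]
        bold = BOLDSeries(data=data, tr=2.0, grid=grid, mask=mask)
        adjacency = int(rng.choice([6, 18, 26]))
        maps = fcd.compute_fcd_maps(bold, r_min=0.6, adjacency=adjacency)
        g, s, ln = bruteforce_fcd(bold, r_min=0.6, adjacency=adjacency)
        if (np.array_equal(maps.global_, g) and np.array_equal(maps.short, s)
                and np.array_equal(maps.long, ln)):
            agree += 1
    return agree / n_grids


# ---------------------------------------------------------------------------
# headline procedure-determined numbers


def exclusion_cascade_count(seed: int = 0) -> int:
    """Retained-subject count after the staged exclusion cascade
    (324 recruited; 5 behavioural, 3 raw-error, 12 bad-raw, 15 motion)."""
    roster = synthetic.generate_roster(
        n_recruited=324,
        per_stage_exclusions={"missing_behavior": 5, "raw_error": 3,
                              "bad_raw": 12, "excess_motion": 15},
        sex_split=(131, 158),
        seed=seed,
    )
    return roster.n_retained


def full_scale_mc_threshold(seed: int = 0, n_iter: int = 1000,
                            adjacency: int = 26) -> inference.MCThreshold:
    """Monte Carlo cluster-extent threshold at the reference scale: a
    55,342-voxel gray-matter mask on the 61 x 73 x 61 3 mm grid, 8 mm FWHM,
    two-sided voxel p < 0.001, family-wise alpha 0.05."""
    grid = BrainGrid.mni_3mm()
    mask = make_gray_mask(grid, GRAY_MASK_VOXELS)
    return inference.mc_cluster_threshold(
        mask, grid, fwhm=8.0, voxel_p=0.001, fwe_alpha=0.05,
        n_iter=n_iter, adjacency=adjacency, seed=seed)


# ---------------------------------------------------------------------------
# statistical calibration


def bartlett_type1_error(n_reps: int = 1000, n: int = 300, p: int = 15,
                         alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of Bartlett's sphericity test on independent normal
    data (true null)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    cols = synthetic.QUESTIONNAIRE_VARS[:p]
    hits = 0
    for _ in range(n_reps):
        table = pd.DataFrame(rng.standard_normal((n, p)), columns=cols)
        _, _, pval = grp.bartlett_test(table, variables=list(cols))
        hits += pval < alpha
    return hits / n_reps


def interaction_f_type1_error(n_voxels: int = 1000, n: int = 100,
                              alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of pure-noise voxels whose interaction F is significant."""
    rng = np.random.default_rng(seed)
    grp_scores = rng.standard_normal(n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    # guarantee both sexes present
    sex[:3] = "male"
    sex[3:6] = "female"
    design = inference.build_design(grp_scores, sex)
    mask = np.ones((n_voxels, 1, 1), dtype=bool)
    maps = rng.standard_normal((n, n_voxels, 1, 1))
    stat_maps = inference.voxelwise_glm(maps, design, mask)
    fcrit = stats.f.isf(alpha, 1, stat_maps.df_resid)
    return float((stat_maps.f_interaction[mask] > fcrit).mean())


# ---------------------------------------------------------------------------
# planted-coupling recovery


def rsfc_slope_recovery(n_seeds: int = 20, n: int = 200, seed: int = 0,
                        male_slope: float = -0.2, female_slope: float = 0.0,
                        n_volumes: int = 170):
    """Seed-target Fisher-z slope recovery across simulated cohorts.

    For each replicate a cohort with the given sex-specific coupling between
    two regions is generated, the seed-based z of the target region is
    probed with the moderated regression, and the male/female conditional
    slopes are recorded. Returns (male_sign_correct, female_null_retained,
    male_slopes, female_slopes) with the first two as fractions of seeds.
    """
    grid = BrainGrid(dims=(10, 10, 6))
    spec = synthetic.two_roi_spec(grid, roi_size=2, male_slope=male_slope,
                                  female_slope=female_slope)
    base = np.random.SeedSequence(seed)
    male_ok = female_null = 0
    male_slopes, female_slopes = [], []
    for child in base.spawn(n_seeds):
        rng = np.random.default_rng(child)
        sub_seed = int(rng.integers(0, 2 ** 31))
        roster = synthetic.generate_roster(n, seed=sub_seed)
        grp_scores = rng.standard_normal(n)
        bolds = synthetic.generate_bold_dataset(
            roster, grid, spec, grp_scores, n_volumes=n_volumes,
            seed=sub_seed + 1)
        seed_roi = rsfc.SeedROI("roi_a", spec.rois["roi_a"])
        target = rsfc.SeedROI("roi_b", spec.rois["roi_b"])
        values = []
        for bold in bolds.values():
            series = rsfc.extract_seed_series(bold, seed_roi)
            zmap = rsfc.compute_rsfc_zmap(bold, series)
            values.append(float(zmap.z[tuple(target.voxels.T)].mean()))
        slopes = inference.probe_interaction(
            np.array(values), grp_scores, roster.retained["sex"])
        male_slopes.append(slopes.slope_male)
        female_slopes.append(slopes.slope_female)
        male_ok += np.sign(slopes.slope_male) == np.sign(male_slope)
        female_null += slopes.p_female > 0.05
    return (male_ok / n_seeds, female_null / n_seeds,
            np.array(male_slopes), np.array(female_slopes))


def _four_roi_spec(grid: BrainGrid, male_slope: float, roi_size: int = 2):
    """Two coupled corner ROIs (a-b) plus a stable pair (c-d) so every
    subject keeps some long-range edges (normalization stays defined)."""
    s = roi_size
    nx, ny, nz = grid.dims

    def block(x0, y0, z0):
        return np.array([(x0 + i, y0 + j, z0 + k)
                         for i in range(s) for j in range(s) for k in range(s)])

    rois = {
        "roi_a": block(1, 1, 1),
        "roi_b": block(nx - 1 - s, ny - 1 - s, nz - 1 - s),
        "roi_c": block(nx - 1 - s, 1, 1),
        "roi_d": block(1, ny - 1 - s, nz - 1 - s),
    }
    return synthetic.NetworkSpec(
        rois=rois,
        baseline_corr={("roi_a", "roi_b"): 0.71, ("roi_c", "roi_d"): 0.71},
        coupling={("roi_a", "roi_b"): (male_slope, 0.0)},
        noise_sd=0.5,
    )


def fcd_interaction_recovery(n_seeds: int = 10, n: int = 200, seed: int = 0,
                             male_slope: float = -0.2, n_volumes: int = 170,
                             dice_threshold: float = 0.3, fwhm: float = 0.0):
    """End-to-end recovery of a male-only long-range FCD coupling.

    Per replicate: generate a cohort with the coupling planted on one region
    pair, band-pass, compute normalized long-range FCD maps, fit the
    voxelwise moderation GLM, threshold the interaction F-map at the Monte
    Carlo cluster-extent threshold for this mask, and measure the Dice
    overlap of the surviving clusters with the planted pair. Returns
    (fraction of seeds with Dice > threshold, dice values).

    Smoothing defaults to off here: synthetic subjects share one grid with
    no anatomical misalignment, so smoothing only dilutes the planted blobs
    (on real cohorts it absorbs registration error). The Monte Carlo
    threshold is computed at the same smoothness, keeping the correction
    consistent with the maps it thresholds.
    """
    grid = BrainGrid(dims=(12, 12, 6))
    mask = np.ones(grid.dims, dtype=bool)
    spec = _four_roi_spec(grid, male_slope)
    planted = np.zeros(grid.dims, dtype=bool)
    planted[tuple(spec.rois["roi_a"].T)] = True
    planted[tuple(spec.rois["roi_b"].T)] = True
    base = np.random.SeedSequence(seed)
    mc = inference.mc_cluster_threshold(
        mask, grid, fwhm=fwhm, voxel_p=0.001, fwe_alpha=0.05, n_iter=1000,
        adjacency=26, seed=int(base.generate_state(1)[0] % (2 ** 31)))
    dices = []
    for child in base.spawn(n_seeds):
        rng = np.random.default_rng(child)
        sub_seed = int(rng.integers(0, 2 ** 31))
        roster = synthetic.generate_roster(n, seed=sub_seed)
        grp_scores = rng.standard_normal(n)
        bolds = synthetic.generate_bold_dataset(
            roster, grid, spec, grp_scores, n_volumes=n_volumes,
            seed=sub_seed + 1)
        long_maps = []
        for bold in bolds.values():
            # band-pass as in the pipeline: removes the out-of-band noise
            # power that would otherwise attenuate the planted correlations
            clean = preprocess.bandpass_filter(bold)
            maps = fcd.compute_fcd_maps(clean, r_min=0.6, adjacency=26)
            sm = fcd.smooth_volume(maps.long, grid, fwhm=fwhm, mask=mask)
            if sm[mask].mean() > 0:
                sm = fcd.normalize_by_global_mean(sm, mask)
            # else: a subject with no long-range edge at all keeps the
            # all-zero map (its normalized map is undefined; zero is the
            # natural continuation and preserves the planted contrast)
            long_maps.append(sm)
        design = inference.build_design(grp_scores, roster.retained["sex"])
        stat_maps = inference.voxelwise_glm(np.stack(long_maps), design, mask)
        clusters = inference.extract_clusters(
            stat_maps.f_interaction, mask, grid, stat_maps.df_resid,
            voxel_p=0.001, min_extent_mm3=mc.min_extent_mm3, adjacency=26,
            stat="F")
        fcrit = stats.f.isf(0.001, 1, stat_maps.df_resid)
        surviving = np.zeros(grid.dims, dtype=bool)
        if len(clusters):
            from scipy import ndimage

            lab, _ = ndimage.label((stat_maps.f_interaction > fcrit) & mask,
                                   structure=fcd.adjacency_structure(26))
            min_vox = int(np.ceil(mc.min_extent_mm3 / grid.voxel_volume_mm3))
            sizes = np.bincount(lab.ravel())
            for lab_id in range(1, len(sizes)):
                if sizes[lab_id] >= min_vox:
                    surviving |= lab == lab_id
        inter = (surviving & planted).sum()
        denom = surviving.sum() + planted.sum()
        dices.append(2.0 * inter / denom if denom else 0.0)
    dices = np.array(dices)
    return float((dices > dice_threshold).mean()), dices


# ---------------------------------------------------------------------------
# trait-score construction


def grp_recovery(seed: int = 0, n_large: int = 2000, n_cohort: int = 289,
                 n_seeds: int = 100):
    """Recovery of the planted risk factor by the varimax component score.

    Returns (score-factor correlation at ``n_large``, fraction of cohorts
    whose male > female score difference is significant at p < 0.001,
    observed male/female means of the last cohort).
    """
    base = np.random.SeedSequence(seed)
    s_large, *cohort_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                              for s in base.spawn(n_seeds + 1)]
    roster = synthetic.generate_roster(n_large, seed=s_large)
    table, latent = synthetic.generate_questionnaire_scores(
        roster, seed=s_large + 1)
    scores, _ = grp.extract_grp(table)
    corr = float(np.corrcoef(scores.score, latent["factor_1"])[0, 1])

    hits = 0
    comp = None
    for s in cohort_seeds:
        roster = synthetic.generate_roster(n_cohort, sex_split=(131, 158), seed=s)
        table, _ = synthetic.generate_questionnaire_scores(roster, seed=s + 1)
        cohort_scores, _ = grp.extract_grp(table)
        comp = grp.compare_sexes(cohort_scores.score, table["sex"])
        if comp.p < 0.001 and comp.male_mean > comp.female_mean:
            hits += 1
    return corr, hits / n_seeds, comp
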