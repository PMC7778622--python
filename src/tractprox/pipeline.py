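"""End-to-end run: simulate -> fit -> track -> threshold -> measure ->
score -> report, with per-stage outputs so any stage can be re-run from
real (non-synthetic) inputs in the same formats.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cohort import CohortConfig, generate_cohort
from .geometry import (Electrode, contact_reference, perpendicular_distance,
                       standardize_threshold, stn_border_lines)
from .phantom import PhantomConfig, generate_phantom
from .stats import render_report, report_tables, summarize_groups, wilcoxon_signed_rank
from .tensor import fit_tensors
from .tracking import HitMap, TrackingParams, track_drt
from .tremor import hemisphere_outcomes, select_visits, tremor_percentage

log = logging.getLogger("tractprox")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    slab_half_mm: float | None = None  # None -> half a voxel of the grid
    max_slab_half_mm: float = 3.0
    visit_rule: str = "latest"
    rng_seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        # one global seed fans out to the stage seeds unless set explicitly
        if self.rng_seed is not None:
            ss = np.random.SeedSequence(self.rng_seed)
            s_ph, s_co, s_tr = ss.spawn(3)
            self.phantom.rng_seed = int(s_ph.generate_state(1)[0] % (2**31))
            self.cohort.rng_seed = int(s_co.generate_state(1)[0] % (2**31))
            self.tracking.rng_seed = int(s_tr.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        if "phantom" in d:
            kwargs["phantom"] = PhantomConfig(**d.pop("phantom"))
        if "cohort" in d:
            kwargs["cohort"] = CohortConfig(**d.pop("cohort"))
        if "tracking" in d:
            kwargs["tracking"] = TrackingParams(**d.pop("tracking"))
        kwargs.update(d)
        cfg = cls(**kwargs)
        return cfg


def electrode_from_row(row) -> Electrode:
    centers = np.array(
        [[row[f"contact{i}_{ax}"] for ax in "xyz"] for i in range(4)], dtype=float
    )
    active = tuple(int(a) for a in str(row["active"]).split(","))
    return Electrode(
        axis=np.array([row["axis_x"], row["axis_y"], row["axis_z"]], dtype=float),
        contact_centers=centers, active=active, mode=str(row["mode"]),
    )


def measure_distances(
    electrodes: pd.DataFrame,
    hit_maps: dict,
    stn_masks: dict,
    affine: np.ndarray,
    slab_half_mm: float | None = None,
    max_slab_half_mm: float = 3.0,
) -> pd.DataFrame:
    """Contact-to-tract distances per hemisphere.

    ``hit_maps`` and ``stn_masks`` map hemisphere side -> HitMap / mask.
    The hit map of each side is thresholded against that side's STN
    border lines, then the in-plane distance from the active-contact
    reference point to the tract border is measured.  ``slab_half_mm``
    defaults to half the grid's voxel size, so boundary voxel centers of
    the contact's own image plane always fall inside the slab.
    """
    if slab_half_mm is None:
        slab_half_mm = float(np.abs(affine[2, 2])) / 2.0
    tract = {}
    taus = {}
    for side, hmap in hit_maps.items():
        lines = stn_border_lines(stn_masks[side], affine)
        taus[side], tract[side] = standardize_threshold(hmap, lines)
    rows = []
    for _, row in electrodes.iterrows():
        e = electrode_from_row(row)
        ref, midpoint_flag = contact_reference(e)
        side = str(row["side"])
        d, flags = perpendicular_distance(
            ref, e.axis, tract[side], slab_half_mm, max_slab_half_mm
        )
        tag = ";".join(
            [k for k, v in flags.items() if v] + (["midpoint_rule"] if midpoint_flag else [])
        )
        rows.append(dict(
            hemisphere=row["hemisphere"], patient=row["patient"], side=side,
            distance_mm=d, threshold=taus[side],
            ref_x=ref[0], ref_y=ref[1], ref_z=ref[2], flags=tag,
        ))
    return pd.DataFrame(rows)


def tremor_prepost_tests(tremor: pd.DataFrame, visit_rule: str = "latest") -> dict:
    """Global and per-side pre/post Wilcoxon tests on tremor percentages."""
    visits = select_visits(tremor, visit_rule)
    out = {}
    for scope in ("global", "right-limbs", "left-limbs"):
        pre = [tremor_percentage(b, scope) for b, _ in visits.values()]
        post = [tremor_percentage(p, scope) for _, p in visits.values()]
        out[f"wilcoxon_{scope.replace('-', '_')}"] = wilcoxon_signed_rank(pre, post)
    return out


def run_analysis(config: RunConfig) -> dict:
    """Run every stage in memory and return all intermediates.

    Returns a dict with keys dwi, rois, truth, field, hit_maps,
    electrodes, tremor, distances, records (per-hemisphere table with
    outcomes and distances), and report.
    """
    log.info("stage simulate: phantom + cohort")
    dwi, rois, truth = generate_phantom(config.phantom)
    electrodes, tremor = generate_cohort(truth, config.cohort)

    log.info("stage fit: diffusion tensors")
    fieldt = fit_tensors(dwi)

    log.info("stage track: probabilistic DRT tracking per hemisphere")
    hit_maps = {}
    for side in ("right", "left"):
        _, hmap = track_drt(
            fieldt, rois.seed[side], rois.filter_masks_for(side), config.tracking
        )
        if hmap.warnings:
            log.warning("side %s: %s", side, "; ".join(hmap.warnings))
        hit_maps[side] = hmap

    log.info("stage distance: STN border standardization + measurement")
    distances = measure_distances(
        electrodes, hit_maps, rois.stn, rois.affine,
        config.slab_half_mm, config.max_slab_half_mm,
    )

    log.info("stage score: tremor outcomes")
    outcomes = hemisphere_outcomes(tremor, config.visit_rule)
    records = outcomes.merge(
        distances[["hemisphere", "distance_mm", "threshold", "flags"]],
        on="hemisphere", how="left",
    )
    records.loc[records["flags"].fillna("").str.contains("missing"), "distance_mm"] = np.nan

    log.info("stage report: statistics")
    report = summarize_groups(records, tremor_prepost_tests(tremor, config.visit_rule))
    return dict(dwi=dwi, rois=rois, truth=truth, field=fieldt, hit_maps=hit_maps,
                electrodes=electrodes, tremor=tremor, distances=distances,
                records=records, report=report)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage into ``outdir`` and return it.

    Writes per-stage files (DWI + gradient tables, masks, FA maps, hit
    maps, distances TSV, per-hemisphere table, group report) plus a
    provenance JSON; re-running the same config reproduces identical
    tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    res = run_analysis(config)
    rois, truth = res["rois"], res["truth"]
    io.save_dwi(res["dwi"], outdir)
    for name, masks in [("seed", rois.seed), ("red_nucleus", rois.red_nucleus),
                        ("dentate", rois.dentate), ("stn", rois.stn)]:
        for side, m in masks.items():
            io.save_nifti(outdir / f"roi_{name}_{side}.nii.gz", m, rois.affine)
    io.save_table(res["electrodes"], outdir / "electrodes.tsv")
    io.save_table(res["tremor"], outdir / "tremor.tsv")
    io.save_json(
        dict(centerline=truth.centerline, bundle_radius=truth.bundle_radius,
             true_distances=truth.true_distances, effect_params=truth.effect_params),
        outdir / "ground_truth.json",
    )
    io.save_tensor_field(res["field"], outdir)
    for side, hmap in res["hit_maps"].items():
        io.save_nifti(outdir / f"hitmap_{side}.nii.gz", hmap.counts, hmap.affine)
    io.save_table(res["distances"], outdir / "distances.tsv")
    records = res["records"]
    io.save_table(records[records["included"]], outdir / "hemispheres.tsv")
    io.save_table(records[~records["included"]], outdir / "hemispheres_excluded.tsv")
    report = res["report"]
    summary_df, tests_df = report_tables(report)
    io.save_table(summary_df, outdir / "report_summary.tsv")
    io.save_table(tests_df, outdir / "report_tests.tsv")
    (outdir / "report.txt").write_text(render_report(report))
    if config.make_plots:
        _plots(records, outdir)

    cfg_dict = config.to_dict()
    digest = hashlib.sha256(repr(sorted(cfg_dict.items())).encode()).hexdigest()[:16]
    import nibabel, scipy
    io.save_json(
        dict(config=cfg_dict, config_sha256=digest, seed=config.rng_seed,
             versions=dict(numpy=np.__version__, scipy=scipy.__version__,
                           pandas=pd.__version__, nibabel=nibabel.__version__)),
        outdir / "provenance.json",
    )
    return outdir


def _plots(records: pd.DataFrame, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    inc = records[records["included"] & np.isfinite(records["distance_mm"])]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    groups = [inc.loc[inc["responder"], "distance_mm"],
              inc.loc[~inc["responder"], "distance_mm"]]
    axes[0].boxplot([g.to_numpy() for g in groups],
                    tick_labels=["improvement", "no improvement"])
    axes[0].set_ylabel("distance to tract border (mm)")
    axes[1].scatter(inc["distance_mm"], inc["improvement_pct"], s=14)
    axes[1].set_xlabel("distance to tract border (mm)")
    axes[1].set_ylabel("tremor improvement (%)")
    fig.tight_layout()
    fig.savefig(outdir / "report_figures.png", dpi=120)
    plt.close(fig)
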