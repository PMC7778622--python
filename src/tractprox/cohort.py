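"""Synthetic DBS cohort: electrodes at controlled tract distances and
UPDRS-III resting-tremor scores whose improvement decreases with distance.

The cohort mirrors the enrolment structure the analysis assumes: 36
patients implanted bilaterally, 12 of them with unilateral tremor, giving
72 hemispheres of which 60 carry contralateral resting tremor and enter
the imaging analysis.  Every enrolled patient has at least one resting
tremor item scored >= 2 of 4 at baseline (the study's inclusion screen).

Electrodes have four point contacts on a straight trajectory with 1.5 mm
center-to-center spacing (1.0 mm contact length plus the 0.5 mm
inter-contact gap).  The active-contact reference point is placed at a
sampled true distance from the bundle surface, in the axial z = -4 plane,
along the ray from the bundle toward the STN — i.e. where an STN lead
actually sits relative to the DRT.

The distance -> improvement link is logistic by default:

    E[improvement fraction] = max_improvement / (1 + exp((d - d0) / s))

so stimulation essentially on the tract (d -> 0) removes tremor and
stimulation far from it leaves tremor unchanged; ``null_model=True`` cuts
the link (improvement drawn from the same marginal but independent of the
electrode's distance), which is the type-I-error condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import GroundTruth

CONTACT_SPACING_MM = 1.5  # center-to-center: 1.0 mm contact + 0.5 mm gap
N_CONTACTS = 4

# lead trajectory (tip-ward), right hemisphere: enters lateral-anterior-
# superior, runs medial-posterior-inferior toward the STN
AXIS_RIGHT = np.array([-0.30, -0.35, -0.89])
AXIS_RIGHT = AXIS_RIGHT / np.linalg.norm(AXIS_RIGHT)

ITEM_COLUMNS = ["arm_right", "arm_left", "leg_right", "leg_left", "lips_jaw"]


@dataclass
class CohortConfig:
    """Cohort size, distance sampling, and the distance->improvement model.

    ``n_hemispheres`` is the number of hemispheres with contralateral
    tremor (analyzed); together with ``n_unilateral_patients`` it fixes the
    patient count: 60 + 12 -> 36 bilaterally implanted patients.
    """

    n_hemispheres: int = 60
    n_unilateral_patients: int = 12
    distance_range: tuple = (0.2, 4.4)
    effect_model: str = "logistic"  # or "linear"
    d0: float = 2.4  # mm, logistic inflection / linear zero-crossing scale
    s: float = 0.55  # mm, logistic slope scale
    max_improvement_pct: float = 100.0
    noise_sd_items: float = 0.6  # sd of the additive noise on post item sums
    null_model: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hemispheres < 2:
            raise ValueError("n_hemispheres must be >= 2")
        if (self.n_hemispheres + self.n_unilateral_patients) % 2:
            raise ValueError(
                "n_hemispheres + n_unilateral_patients must be even "
                "(bilateral implantation)"
            )
        if self.d0 <= 0 or self.s <= 0:
            raise ValueError("d0 and s must be positive")
        if self.effect_model not in ("logistic", "linear"):
            raise ValueError("effect_model must be 'logistic' or 'linear'")

    @property
    def n_patients(self) -> int:
        return (self.n_hemispheres + self.n_unilateral_patients) // 2

    def improvement_fraction(self, distance_mm) -> np.ndarray:
        """Expected improvement fraction in [0, 1] at a given distance."""
        d = np.asarray(distance_mm, dtype=float)
        m = self.max_improvement_pct / 100.0
        if self.effect_model == "logistic":
            return m / (1.0 + np.exp((d - self.d0) / self.s))
        return m * np.clip(1.0 - d / (2.0 * self.d0), 0.0, 1.0)


def _mirror(p: np.ndarray) -> np.ndarray:
    q = np.array(p, dtype=float)
    q[0] *= -1
    return q


def _place_reference_point(truth: GroundTruth, distance: float,
                           side: str = "right") -> np.ndarray:
    """Point at the requested distance from the bundle surface of
    ``side``, on the z = -4 plane, along the bundle->STN direction
    (solved by bisection on the analytic distance function)."""
    cl = truth.centerline_for(side)
    c0 = cl[np.argmin(np.abs(cl[:, 2] + 4.0))]
    u = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)  # toward the STN (lateral-anterior)
    if side == "left":
        u = _mirror(u)

    def dist_at(t):
        return float(truth.distance_to_tube(c0 + t * u, side)[0])

    lo, hi = truth.bundle_radius * 0.5, truth.bundle_radius + distance + 6.0
    if dist_at(hi) < distance:
        raise ValueError(f"requested distance {distance:.2f} mm unreachable within grid")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if dist_at(mid) < distance:
            lo = mid
        else:
            hi = mid
    return c0 + 0.5 * (lo + hi) * u


def _electrode_row(p_ref: np.ndarray, side: str, mode: str, rng: np.random.Generator):
    """Contacts along the trajectory such that the active-contact
    reference point (contact center, or midpoint of an active pair)
    equals ``p_ref`` exactly."""
    axis = AXIS_RIGHT if side == "right" else _mirror(AXIS_RIGHT)
    if mode == "monopolar":
        active = [int(rng.integers(1, 3))]
        anchor = float(active[0])
    else:  # bipolar / double_monopolar use the mid-pair reference
        active = [1, 2]
        anchor = 1.5
    centers = [p_ref + (i - anchor) * CONTACT_SPACING_MM * axis for i in range(N_CONTACTS)]
    return axis, centers, active


def generate_cohort(truth: GroundTruth, config: CohortConfig | None = None):
    """Generate electrode and tremor tables; fills ``truth.true_distances``
    and ``truth.effect_params``.

    Returns ``(electrode_table, tremor_table)`` as DataFrames matching the
    TSV schemas used throughout the pipeline.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    n_pat = cfg.n_patients

    # patients 1..n_uni are unilateral; tremor side alternates
    unilateral = np.zeros(n_pat, dtype=bool)
    unilateral[: cfg.n_unilateral_patients] = True
    order = rng.permutation(n_pat)  # scatter unilateral patients through ids
    unilateral = unilateral[order]

    electrode_rows = []
    tremor_rows = []
    true_distances: dict = {}

    for pat in range(1, n_pat + 1):
        uni = unilateral[pat - 1]
        tremor_limb_sides = (
            ["right" if pat % 2 else "left"] if uni else ["right", "left"]
        )

        # baseline items on tremor-affected limbs
        items = {c: 0 for c in ITEM_COLUMNS}
        for limb in tremor_limb_sides:
            items[f"arm_{limb}"] = int(rng.choice([1, 2, 3], p=[0.25, 0.5, 0.25]))
            items[f"leg_{limb}"] = int(rng.choice([0, 1, 2], p=[0.5, 0.4, 0.1]))
        items["lips_jaw"] = int(rng.choice([0, 1], p=[0.7, 0.3]))
        if max(items.values()) < 2:  # enrolment screen: any item >= 2
            items[f"arm_{tremor_limb_sides[0]}"] = 2
        non_tremor_motor = int(rng.integers(15, 36))
        base_total = sum(items.values()) + non_tremor_motor
        tremor_rows.append(
            dict(
                patient=pat, visit_month=0, state="OFF-MED",
                **items, updrs3_total=base_total,
            )
        )

        # electrodes: bilateral implantation; distance per hemisphere
        hemi_effect = {}
        for side in ("right", "left"):
            hemi = f"P{pat:02d}-{side[0].upper()}"
            d = float(rng.uniform(*cfg.distance_range))
            p_ref = _place_reference_point(truth, d, side)
            mode = str(rng.choice(
                ["monopolar", "bipolar", "double_monopolar"], p=[0.85, 0.10, 0.05]
            ))
            axis, centers, active = _electrode_row(p_ref, side, mode, rng)
            row = dict(patient=pat, side=side, hemisphere=hemi,
                       axis_x=axis[0], axis_y=axis[1], axis_z=axis[2])
            for i, c in enumerate(centers):
                row[f"contact{i}_x"], row[f"contact{i}_y"], row[f"contact{i}_z"] = c
            row["active"] = ",".join(str(a) for a in active)
            row["mode"] = mode
            electrode_rows.append(row)
            true_distances[hemi] = d
            d_eff = float(rng.uniform(*cfg.distance_range)) if cfg.null_model else d
            hemi_effect[side] = cfg.improvement_fraction(d_eff)

        # follow-up visits (OFF-MED/ON-STIM); the analysis takes the latest
        n_visits = int(rng.choice([1, 2], p=[0.7, 0.3]))
        months = sorted(rng.choice(np.arange(1, 8), size=n_visits, replace=False))
        for month in months:
            post = {c: 0 for c in ITEM_COLUMNS}
            fr_used = []
            for limb in tremor_limb_sides:
                # the hemisphere CONTRALATERAL to the limb drives the effect
                hemi_side = "left" if limb == "right" else "right"
                fr = hemi_effect[hemi_side]
                fr_used.append(fr)
                pre_sum = items[f"arm_{limb}"] + items[f"leg_{limb}"]
                post_sum = int(np.clip(
                    round(pre_sum * (1.0 - fr) + rng.normal(0.0, cfg.noise_sd_items)),
                    0, 8,
                ))
                post[f"arm_{limb}"] = min(4, post_sum)  # arm-dominant split
                post[f"leg_{limb}"] = post_sum - post[f"arm_{limb}"]
            fbar = float(np.mean(fr_used)) if fr_used else 0.0
            post["lips_jaw"] = int(np.clip(
                round(items["lips_jaw"] * (1.0 - fbar) + rng.normal(0.0, 0.3)), 0, 4
            ))
            stim_gain = rng.uniform(0.3, 0.6)  # non-tremor motor improvement
            total = sum(post.values()) + int(round(non_tremor_motor * (1.0 - stim_gain)))
            tremor_rows.append(
                dict(patient=pat, visit_month=int(month), state="OFF-MED/ON-STIM",
                     **post, updrs3_total=total)
            )

    truth.true_distances = true_distances
    truth.effect_params = dict(
        model=cfg.effect_model, d0=cfg.d0, s=cfg.s,
        max_improvement_pct=cfg.max_improvement_pct,
        noise_sd_items=cfg.noise_sd_items, null_model=cfg.null_model,
    )

    electrodes = pd.DataFrame(electrode_rows)
    tremor = pd.DataFrame(tremor_rows)
    return electrodes, tremor
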