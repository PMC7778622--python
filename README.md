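# tractprox

Contact-to-tract proximity analysis for subthalamic deep brain stimulation
(STN-DBS) tremor outcome.

## The problem

In Parkinson's disease, STN-DBS suppresses resting tremor in most — but
not all — stimulated hemispheres. One candidate explanation is electrical
co-stimulation of the dentato-rubro-thalamic tract (DRT), the
cerebello-thalamic bundle that ascends from the contralateral dentate
nucleus, decussates, passes the red nucleus, and projects toward the
motor cortex through the posterior subthalamic area, a few millimetres
from the STN. If that hypothesis holds, hemispheres whose active
electrode contact sits closer to the DRT should show larger tremor
improvement.

`tractprox` implements the complete analysis chain needed to test this on
imaging + clinical data, and ships a synthetic diffusion phantom and
cohort generator with known ground truth, so every stage is verifiable
end to end:

1. **Tensor fit** — per-voxel diffusion tensor `D` from a single-shell
   acquisition by log-linear least squares on
   `S_i = S0 · exp(−b gᵢᵀ D gᵢ)`; eigenvalues λ₁ ≥ λ₂ ≥ λ₃, principal
   direction e₁, and `FA = √(3/2) · ‖λ − λ̄‖ / ‖λ‖`.
2. **Probabilistic tractography** — streamlines start in the precentral
   (primary motor) seed region, propagate by Euler steps along directions
   drawn from an axial angular-Gaussian about the interpolated e₁ with
   dispersion σ(FA) = σ_max·(1 − FA), and are accepted only if they cross
   both waypoint filters: ipsilateral red nucleus and contralateral
   dentate nucleus. Accepted streamlines accumulate a **hit map** H(v),
   one increment per (voxel, streamline) pair.
3. **Boundary standardization** — on the axial plane 4 mm below the
   intercommissural line, straight lines are placed along the medial and
   posterior STN borders; the hit map is binarized at the smallest
   integer threshold τ\* at which no supra-threshold voxel lies on the
   STN side of either line (the reproducible equivalent of adjusting
   display contrast until the tract no longer crosses the lines).
4. **Distance** — the shortest distance from the active-contact reference
   point (contact center; midpoint for bipolar pairs) to the tract border
   is measured in the plane perpendicular to the electrode axis:
   `min over boundary voxels x of ‖(x−p) − ((x−p)·a)a‖` within a thin
   slab `|(x−p)·a| ≤ h`.
5. **Tremor outcome** — UPDRS-III resting-tremor items (four limbs +
   lips/jaw, 0–4 each) are converted to percentages (global sum / 20,
   per-side limb sum / 8); improvement = pre − post, responders have
   improvement > 0, and a hemisphere is analyzed only if the
   contralateral body half had baseline tremor.
6. **Statistics** — Mann-Whitney (responder vs non-responder distances),
   Wilcoxon signed-rank (pre/post tremor), Spearman Rs and Rs²
   (improvement vs distance), a normality-gated Welch-t/Mann-Whitney
   comparison, and Table-style group summaries.

## Worked example

The whole synthetic pipeline — 36 bilaterally implanted patients, 12 with
unilateral tremor (so 60 of 72 hemispheres enter the analysis), a
30-direction b = 1000 s/mm² phantom at SNR 20 — runs in a few seconds:

```bash
tractprox run-all --out demo --seed 1 --starts-per-voxel 50
```

prints

```
Distance to tract border (mm) by responder class

group             n    mean    min    max     sd    p25    p50    p75
responders       43    2.61   1.17   3.92   0.98   1.63   2.79   3.53
non_responders   17    3.55   1.45   4.62   0.91   3.17   3.86   4.20

distance_mann_whitney: stat=176.000 p=0.001932 [mann-whitney-asymptotic]
improvement_vs_distance_spearman: stat=-0.476 p=0.0001222 [spearman-t-approx]  Rs^2=0.226
wilcoxon_global: stat=426.000 p=6.126e-06 [wilcoxon-asymptotic]
wilcoxon_right_limbs: stat=253.000 p=3.351e-05 [wilcoxon-asymptotic]
wilcoxon_left_limbs: stat=276.000 p=0.0002166 [wilcoxon-asymptotic]
```

Reading: hemispheres whose contacts ended up near the tract responded
(median 2.79 mm vs 3.86 mm for non-responders, Mann-Whitney p ≈ 0.002),
tremor improvement correlates inversely with distance (Rs = −0.48,
explaining Rs² ≈ 23 % of rank variance), and stimulation reduced tremor
across the cohort (global pre/post Wilcoxon p ≈ 6·10⁻⁶). The run
directory additionally holds every intermediate (DWI + bval/bvec, FA
maps, hit maps as NIfTI, per-hemisphere TSV tables, ground truth JSON,
provenance), and each stage is also exposed as its own subcommand
(`simulate`, `fit`, `track`, `distance`, `score`, `report`) reading and
writing those standard formats, so real NIfTI/TSV inputs can replace the
synthetic ones at any stage.

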