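"""Fixed diffusion-gradient direction table.

A 30-direction scheme obtained once by electrostatic repulsion of antipodal
point pairs on the unit sphere and frozen here, so every run of the phantom
generator uses byte-identical gradients.  Minimum angle between distinct
gradient axes: 25.6 degrees.
"""

from __future__ import annotations

import numpy as np

# unit vectors, canonical hemisphere (z >= 0), lexicographically sorted
DIRECTIONS_30: np.ndarray = np.array(
    [
        (-0.97833092, +0.19403446, +0.07224424),
        (-0.89194854, -0.23568706, +0.38584895),
        (-0.83213408, +0.20793367, +0.51411717),
        (-0.76268910, -0.63840908, +0.10363004),
        (-0.75036874, +0.60471084, +0.26696732),
        (-0.61234443, -0.55117848, +0.56677736),
        (-0.60707772, -0.10832608, +0.78722430),
        (-0.52041527, +0.43252728, +0.73626632),
        (-0.38106688, -0.90039659, +0.20993812),
        (-0.36663247, +0.81055048, +0.45671495),
        (-0.22576716, +0.10965322, +0.96799037),
        (-0.22274141, -0.36118703, +0.90549997),
        (-0.21863204, -0.74649598, +0.62844554),
        (-0.09113590, +0.57484067, +0.81317431),
        (+0.00006138, +0.99586841, +0.09080810),
        (+0.10340141, +0.85963300, +0.50033914),
        (+0.10658685, -0.93045412, +0.35056294),
        (+0.20203142, -0.60547930, +0.76979096),
        (+0.22452087, +0.25686938, +0.94000452),
        (+0.23764287, -0.18654821, +0.95327102),
        (+0.43222049, +0.58649962, +0.68498441),
        (+0.47239062, -0.88138885, +0.00089793),
        (+0.50172728, +0.82989299, +0.24402326),
        (+0.51533949, -0.73014929, +0.44867275),
        (+0.63077528, -0.34217692, +0.69644634),
        (+0.64254988, +0.12899437, +0.75530795),
        (+0.78298082, +0.46155931, +0.41701803),
        (+0.82744886, -0.51911345, +0.21412524),
        (+0.90601363, -0.07462850, +0.41661720),
        (+0.96595762, +0.24797877, +0.07370487),
    ],
    dtype=float,
)


def direction_table(n_directions: int) -> np.ndarray:
    """Return ``n_directions`` unit vectors.

    All 30 come from the frozen table; larger requests are refused (the
    acquisition emulated here is a 30-direction single-shell scheme).  For
    fewer directions a deterministic greedy max-min-angle subset of the
    table is taken, so even six directions span a well-conditioned design.
    """
    if not 6 <= n_directions <= len(DIRECTIONS_30):
        raise ValueError(
            f"n_directions must be in [6, {len(DIRECTIONS_30)}], got {n_directions}"
        )
    v = DIRECTIONS_30 / np.linalg.norm(DIRECTIONS_30, axis=1, keepdims=True)
    if n_directions == len(v):
        return v.copy()
    chosen = [0]
    cos = np.abs(v @ v.T)  # angle between axes (antipodally symmetric)
    while len(chosen) < n_directions:
        worst = cos[:, chosen].max(axis=1)
        worst[chosen] = np.inf
        chosen.append(int(np.argmin(worst)))
    return v[sorted(chosen)].copy()
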