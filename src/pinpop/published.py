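"""Printed summary values from the original weeping-pinyon study.

These are *inputs* to the package — the pairwise F_ST table among the ten
sampled populations and the best-fit divergence-with-migration model —
used to define generating conditions for synthetic data and as arithmetic
fixtures. Nothing here is computed by this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demography import DemographicModel
from .genotypes import REGION_A, REGION_B

#: populations in table order; first five SMO, last five ChD
POPULATIONS = [
    "Tolantongo", "San Joaquin", "Maguey Verde", "Nunez", "La Florida",
    "El Palmito", "Mazapil", "La Noria", "G. Cepeda", "Sierra Parras",
]

POPULATION_REGION = {p: (REGION_A if i < 5 else REGION_B)
                     for i, p in enumerate(POPULATIONS)}

#: lower triangle of the printed pairwise F_ST table, row by row
_FST_LOWER = [
    [0.0078],
    [0.0099, 0.01],
    [0.01, 0.0185, 0.02],
    [0.0121, 0.021, 0.0214, 0.0128],
    [0.0439, 0.0471, 0.0445, 0.0473, 0.0453],
    [0.0469, 0.0494, 0.0526, 0.0546, 0.0536, 0.0162],
    [0.0482, 0.051, 0.0541, 0.0532, 0.0525, 0.0124, 0.01],
    [0.0536, 0.0575, 0.0596, 0.061, 0.0589, 0.0184, 0.008, 0.008],
    [0.0574, 0.0577, 0.0626, 0.065, 0.0626, 0.0219, 0.008, 0.013, 0.005],
]


def pairwise_fst_table() -> pd.DataFrame:
    """Printed pairwise F_ST among the ten populations, as a symmetric
    DataFrame with zero diagonal."""
    n = len(POPULATIONS)
    m = np.zeros((n, n))
    for i, row in enumerate(_FST_LOWER, start=1):
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=POPULATIONS, columns=POPULATIONS)


def best_fit_model() -> DemographicModel:
    """Best-supported scenario: divergence with asymmetric migration.

    Point estimates — diploid deme sizes 4367 (SMO) and 6740 (ChD),
    divergence 62,250 generations ago (2.49 Ma at 40 y/generation),
    per-generation migration 3.93e-6 from SMO to ChD and 3e-5 in the
    opposite direction; mutation rate 2.91e-8 per base per generation.
    """
    return DemographicModel(
        scenario="DIV_M", n_smo=4367.0, n_chd=6740.0, t_div=62250.0,
        m_smo_to_chd=3.93e-6, m_chd_to_smo=3e-5)


#: printed 95% parametric-bootstrap confidence intervals for the best fit;
#: times in Ma, sizes in diploid individuals. The ChD->SMO migration CI as
#: printed is not internally consistent and is omitted.
BEST_FIT_CI = {
    "t_div_ma": (1.62, 3.28),
    "n_smo": (3775.41, 4958.59),
    "n_chd": (5948.58, 7531.42),
    "m_smo_to_chd": (3.93e-7, 3.93e-5),  # order-of-magnitude band
}
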