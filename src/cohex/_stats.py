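"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    NaN p-values propagate to NaN q-values; the correction is applied over
    the finite entries only. q >= p and q in [0, 1] always hold.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q
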