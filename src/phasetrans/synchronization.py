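"""Synchronization Pattern Analysis: moving-window mean absolute correlation.

Rising coherence among a system's component variables is a known precursor
of critical transitions.  SPA quantifies it as the average of the absolute
Pearson correlations over all variable pairs, computed inside a trailing
window (default width 7).  Pairs in which either variable is flat within the
window are excluded (coarse rating data produce such windows routinely); a
window with no valid pair is undefined and stored as NaN.
"""

from __future__ import annotations

import numpy as np

from .series import DerivedSeries, MultiSeries


def spa(ms: MultiSeries, w: int = 7) -> DerivedSeries:
    """Moving-window mean absolute pairwise Pearson correlation, in [0, 1]."""
    if len(ms.columns) < 2:
        raise ValueError("synchronization analysis needs at least 2 columns")
    if w < 3:
        raise ValueError("SPA window must be >= 3")
    x = ms.matrix()
    n = x.shape[0]
    if n < w:
        raise ValueError(f"series of length {n} shorter than SPA window {w}")
    vals = np.empty(n - w + 1)
    for i in range(n - w + 1):
        win = x[i:i + w, :]
        sd = win.std(axis=0, ddof=1)
        valid = sd > 0
        if valid.sum() < 2:
            vals[i] = np.nan
            continue
        r = np.corrcoef(win[:, valid], rowvar=False)
        iu = np.triu_indices_from(r, k=1)
        vals[i] = float(np.clip(np.abs(r[iu]), 0.0, 1.0).mean())
    return DerivedSeries(vals, window=w, offset=ms.t0 + w - 1)
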