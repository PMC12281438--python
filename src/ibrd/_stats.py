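"""Small statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries (undefined tests, e.g. constant features) are excluded
    from the family and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    mask = np.isfinite(flat)
    out = np.full(flat.shape, np.nan)
    if mask.sum() > 0:
        out[mask] = multipletests(flat[mask], method="fdr_bh")[1]
    return out.reshape(p.shape)


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (report-level rounding; never used internally)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    rounded = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if rounded.ndim == 0:
        return float(rounded)
    return rounded


def spawn_rng(seed: int, *stream: int | str) -> np.random.Generator:
    """Derive an independent substream from a master seed.

    Counter-based: the stream key is hashed into the SeedSequence entropy so
    the order in which substreams are drawn does not affect their content.
    """
    key = [int(seed)]
    for s in stream:
        if isinstance(s, str):
            key.extend(s.encode())
        else:
            key.append(int(s))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(key)))
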