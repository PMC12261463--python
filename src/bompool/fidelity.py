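"""Fidelity-compactness diagnostics for windowed pooling.

Shrinking a token matrix to a bag of window averages trades representation
size against faithfulness to the original per-token embeddings.  This
module quantifies both sides of that trade-off for a window setting
``(k, s)``:

* *compactness* — the token-count ratio ``n / l`` (windows per original
  token; 1 at ``k=s=1``, ``1/l`` at a single whole-sequence window);
* *fidelity error* — assign each token the pooled vector of the window(s)
  covering it (when windows overlap, the mean of all covering windows'
  averages) and measure the mean squared Euclidean deviation between
  tokens and their representatives.  Zero at ``k=1, s=1``; for a single
  whole-sequence window it equals the total variance of the rows about
  the global mean.  The error is driven by the within-window variance of
  the embedding, which the report also aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pooling import WindowConfig, local_avg_pool, _rows

__all__ = ["FidelityReport", "fidelity_error", "fidelity_sweep"]


@dataclass
class FidelityReport:
    k: int
    s: int
    compactness: float  # n / l, pooled tokens per original token
    fidelity_error: float  # mean squared token-to-representative deviation
    per_window_variance: np.ndarray  # mean within-window variance per window

    @property
    def mean_window_variance(self) -> float:
        return float(self.per_window_variance.mean())


def fidelity_error(H, cfg: WindowConfig, include_special: bool = False) -> FidelityReport:
    """Measure how faithfully the (k, s) window bag preserves the tokens."""
    rows = _rows(H, include_special)
    l, d = rows.shape  # noqa: E741
    bag = local_avg_pool(rows, cfg)
    reps = np.zeros((l, d))
    cover = np.zeros(l)
    for omega, start, length in zip(bag.omegas, bag.starts, bag.lengths):
        sl = slice(start - 1, start - 1 + length)
        reps[sl] += omega
        cover[sl] += 1
    covered = cover > 0
    reps[covered] /= cover[covered, None]
    # uncovered tokens (tail disabled) fall back to the nearest window: the last
    if not covered.all():
        reps[~covered] = bag.omegas[-1]
    err = float(np.mean(np.sum((rows - reps) ** 2, axis=1)))
    within_var = np.array(
        [
            np.mean(np.sum((rows[s0 - 1 : s0 - 1 + ln] - om) ** 2, axis=1))
            for om, s0, ln in zip(bag.omegas, bag.starts, bag.lengths)
        ]
    )
    return FidelityReport(
        k=cfg.k,
        s=cfg.s,
        compactness=bag.n / l,
        fidelity_error=err,
        per_window_variance=within_var,
    )


def fidelity_sweep(
    H,
    ks: list[int],
    ss: list[int] | None = None,
    tail: bool = True,
    include_special: bool = False,
) -> pd.DataFrame:
    """Sweep a (k, s) grid and tabulate compactness and fidelity error."""
    ss = ss or [1]
    rows = []
    for s in ss:
        for k in ks:
            rep = fidelity_error(H, WindowConfig(k=k, s=s, tail=tail), include_special)
            rows.append(
                {
                    "k": k,
                    "s": s,
                    "compactness": rep.compactness,
                    "fidelity_error": rep.fidelity_error,
                    "mean_window_variance": rep.mean_window_variance,
                }
            )
    return pd.DataFrame(rows)
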