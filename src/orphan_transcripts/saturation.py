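"""Discovery-saturation analysis: subsampled detection counts and the
one-site binding fit Y = Bmax * X / (Kd + X).

The saturating hyperbola models the number of discoverable transcripts as a
function of the number of sequenced libraries: Bmax is the asymptotic
transcript count, Kd the library count at half saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class SaturationFit:
    bmax: float
    kd: float
    rss: float
    degenerate: bool = False


def subsample_discovery(
    detections: pd.DataFrame,
    sizes: list[int],
    n_rep: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded subsets of libraries; discovered = transcripts seen in >= 1 of them.

    ``detections`` is transcripts x libraries, truthy where the transcript is
    detected (count >= 1) in that library.  Returns a (size, replicate,
    discovered) table.
    """
    det = detections.astype(bool)
    libs = list(det.columns)
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, len(libs)]))
    for size in sizes:
        if size > len(libs):
            raise ValueError(f"subset size {size} exceeds {len(libs)} libraries")
        for rep in range(n_rep):
            if size == 0:
                discovered = 0
            else:
                chosen = rng.choice(len(libs), size=size, replace=False)
                discovered = int(det.iloc[:, sorted(chosen)].any(axis=1).sum())
            rows.append({"size": size, "replicate": rep, "discovered": discovered})
    return pd.DataFrame(rows)


def one_site(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    return bmax * x / (kd + x)


def fit_one_site(x: list[float], y: list[float]) -> SaturationFit:
    """Least-squares fit of the one-site binding curve.

    Deterministic initialization (Bmax0 = max Y, Kd0 = median X) and a 1e-10
    parameter tolerance.  A constant response is degenerate: Bmax = c, Kd = 0.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(np.unique(xa)) < 3:
        raise ValueError("fit_one_site needs >= 3 distinct X values")
    if np.allclose(ya, ya[0]):
        return SaturationFit(bmax=float(ya[0]), kd=0.0, rss=0.0, degenerate=True)

    def resid(theta: np.ndarray) -> np.ndarray:
        return one_site(xa, theta[0], theta[1]) - ya

    x0 = np.array([float(ya.max()), float(np.median(xa))])
    res = least_squares(resid, x0, bounds=([0.0, 0.0], [np.inf, np.inf]),
                        xtol=1e-10, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise RuntimeError(f"one-site fit failed: {res.message} (x0={x0.tolist()})")
    bmax, kd = map(float, res.x)
    return SaturationFit(bmax=bmax, kd=kd, rss=float(np.sum(res.fun**2)),
                        degenerate=kd <= 1e-9)
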