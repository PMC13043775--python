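"""Growth-curve phenomics: parameter estimation and permutation testing.

Plate-reader OD560 series (sampled every 20 min by default) are reduced
to two physiological parameters per replicate:

* **mu** (h^-1): maximum specific growth rate, the maximum of
  d/dt ln(OD560) over the curve.  ln(OD) is smoothed with a centred
  rolling median (default window 5 points; edge points are left raw,
  which is exact for monotone noise-free curves) and differentiated with
  central differences (one-sided at the ends).
* **od_max**: carrying capacity, the maximal OD560 attained.  The
  literature sometimes reports max ln(OD); ln is monotone so the argmax
  is identical and we store the OD-scale value.

Strains are compared with a two-sided permutation test on the difference
in group medians, n = 10,000 random relabelings by default, with the
add-one rule p = (1 + #{|T*| >= |t_obs|}) / n (so p is floored at 1/n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthParams",
    "PermutationTestResult",
    "estimate_growth_params",
    "permutation_test",
    "od_at",
    "curves_from_frame",
    "load_growth_tsv",
    "strain_comparison",
]


@dataclass(frozen=True)
class GrowthCurve:
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # OD560, > 0
    strain: str = ""
    replicate: int = 0

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "od", np.asarray(self.od, float))
        if self.times.size != self.od.size or self.times.size < 10:
            raise ValueError("need matching times/od arrays with >= 10 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("OD readings must be positive")


@dataclass(frozen=True)
class GrowthParams:
    mu: float  # h^-1
    od_max: float
    t_mu: float  # hours at which mu is attained


@dataclass(frozen=True)
class PermutationTestResult:
    t_obs: float  # difference in group medians (a - b)
    n_resamples: int
    p: float
    seed: int


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = x.copy()
    for i in range(half, x.size - half):
        out[i] = np.median(x[i - half : i + half + 1])
    return out


def estimate_growth_params(curve: GrowthCurve, window: int = 5) -> GrowthParams:
    """Estimate mu and carrying capacity from one growth curve."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window >= curve.times.size:
        raise ValueError("window must be smaller than the series length")
    ln_od = _rolling_median(np.log(curve.od), window)
    deriv = np.gradient(ln_od, curve.times)
    i = int(np.argmax(deriv))
    return GrowthParams(
        mu=float(deriv[i]),
        od_max=float(curve.od.max()),
        t_mu=float(curve.times[i]),
    )


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Two-sided permutation test on the difference in group medians."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    if n < 1:
        raise ValueError("n must be >= 1")
    t_obs = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n):
        perm = rng.permutation(pooled)
        t_star = np.median(perm[: a.size]) - np.median(perm[a.size :])
        if abs(t_star) >= abs(t_obs):
            count += 1
    p = min(1.0, (1 + count) / n)
    return PermutationTestResult(t_obs=t_obs, n_resamples=n, p=p, seed=seed)


def od_at(curve: GrowthCurve, t: float) -> float:
    """OD at the sample point nearest to time t (hours)."""
    return float(curve.od[int(np.argmin(np.abs(curve.times - t)))])


def curves_from_frame(frame: pd.DataFrame) -> list:
    """Long-format frame (well, strain, replicate, time_h, od560) -> curves."""
    curves = []
    for (strain, rep), g in frame.groupby(["strain", "replicate"], sort=True):
        g = g.sort_values("time_h")
        curves.append(
            GrowthCurve(
                times=g["time_h"].to_numpy(float),
                od=g["od560"].to_numpy(float),
                strain=str(strain),
                replicate=int(rep),
            )
        )
    return curves


def load_growth_tsv(path) -> list:
    return curves_from_frame(pd.read_csv(path, sep="\t"))


def strain_comparison(
    curves: Sequence[GrowthCurve],
    mutant: str = "mutant",
    reference: str = "reference",
    window: int = 5,
    n: int = 10_000,
    seed: int = 0,
    od_time: float = 24.0,
) -> dict:
    """Per-replicate growth parameters and mutant-vs-reference permutation tests.

    Returns a dict with per-parameter group values, the median and mean
    differences (mutant minus reference), and permutation test results
    for mu, od_max and the OD at ``od_time`` hours.
    """
    params: dict = {mutant: {}, reference: {}}
    for name in (mutant, reference):
        sel = [c for c in curves if c.strain == name]
        if not sel:
            raise ValueError(f"no curves for strain {name!r}")
        est = [estimate_growth_params(c, window) for c in sel]
        params[name] = {
            "mu": np.array([e.mu for e in est]),
            "od_max": np.array([e.od_max for e in est]),
            f"od_{od_time:g}h": np.array([od_at(c, od_time) for c in sel]),
        }
    out = {"groups": params, "tests": {}, "median_diff": {}, "mean_diff": {}}
    for i, key in enumerate(params[mutant]):
        a, b = params[mutant][key], params[reference][key]
        out["tests"][key] = permutation_test(a, b, n=n, seed=seed + i)
        out["median_diff"][key] = float(np.median(a) - np.median(b))
        out["mean_diff"][key] = float(a.mean() - b.mean())
    return out
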