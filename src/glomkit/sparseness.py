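"""Population and lifetime sparseness of glomerular odor responses.

Both statistics are the same ratio applied along different axes of the
glomerulus x odor amplitude matrix:

    S(r) = (sum(r) / N)^2 / (sum(r^2) / N)

For non-negative, not-all-zero r of length N the ratio lies in [1/N, 1]:
1 for perfectly uniform activity, 1/N when a single element carries all the
activity. Population sparseness applies it over glomeruli for one odor
(fraction of the population a stimulus recruits); lifetime sparseness over
odors for one glomerulus (breadth of its odor tuning).

Negative amplitudes — possible in dF/F — are clipped to zero before the
ratio, which is defined for non-negative activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SparsenessResult:
    ps_per_odor: pd.Series  # indexed by odor id
    ls_per_glomerulus: pd.Series  # indexed by glomerulus
    n_glomeruli: int
    n_odors: int

    @property
    def mean_population_sparseness(self) -> float:
        return float(self.ps_per_odor.mean())

    @property
    def mean_lifetime_sparseness(self) -> float:
        return float(self.ls_per_glomerulus.mean())


def _treves_rolls(r: np.ndarray) -> float:
    r = np.clip(np.asarray(r, dtype=float), 0.0, None)
    if r.size == 0:
        raise ValueError("empty response vector")
    denom = np.mean(r**2)
    if denom == 0.0:
        return float("nan")  # all-zero vector: undefined
    return float(np.mean(r) ** 2 / denom)


def population_sparseness(responses: np.ndarray) -> float:
    """Sparseness of one odor's response across the glomerular population.

    ``responses`` holds the amplitude of every glomerulus to a single odor.
    Returns NaN for an all-zero (silent) vector.
    """
    return _treves_rolls(responses)


def lifetime_sparseness(responses: np.ndarray) -> float:
    """Sparseness of one glomerulus's responses across the odor panel."""
    return _treves_rolls(responses)


def sparseness_summary(
    amplitude: np.ndarray,
    odor_ids: list | None = None,
    zero_below: float | None = None,
) -> SparsenessResult:
    """Both sparseness measures over a glomerulus x odor amplitude matrix.

    ``zero_below`` optionally zeroes amplitudes at or below a responsiveness
    threshold before the computation (off by default).
    """
    amp = np.asarray(amplitude, dtype=float)
    if amp.ndim != 2:
        raise ValueError("amplitude must be a glomerulus x odor matrix")
    if zero_below is not None:
        amp = np.where(amp > zero_below, amp, 0.0)
    n_g, n_o = amp.shape
    if odor_ids is None:
        odor_ids = list(range(n_o))
    ps = pd.Series(
        [population_sparseness(amp[:, j]) for j in range(n_o)],
        index=pd.Index(odor_ids, name="odor_id"), name="population_sparseness",
    )
    ls = pd.Series(
        [lifetime_sparseness(amp[i, :]) for i in range(n_g)],
        index=pd.RangeIndex(n_g, name="glomerulus"), name="lifetime_sparseness",
    )
    return SparsenessResult(ps_per_odor=ps, ls_per_glomerulus=ls,
                            n_glomeruli=n_g, n_odors=n_o)
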