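"""75th-percentile scale normalization.

Each sample (column) is multiplied by a scaling factor equal to the median
of all samples' 75th percentiles divided by that sample's own 75th
percentile, so that after normalization every sample's 75th percentile is
the common median value.  Zeros are genuine signal values on the array
platform and are included in the percentile computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ScaleFactors:
    """Audit record of a scale normalization."""

    per_sample_q75: np.ndarray
    global_median_q75: float
    per_sample_factor: np.ndarray
    sample_names: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        names = self.sample_names or [f"s{i}" for i in range(len(self.per_sample_q75))]
        return pd.DataFrame(
            {"sample": names, "q75": self.per_sample_q75, "factor": self.per_sample_factor}
        )

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def percentile75(values: np.ndarray) -> float:
    """75th percentile under linear interpolation between order statistics.

    The value at (zero-based) index ``0.75 * (n - 1)`` of the sorted vector.
    The percentile convention is centralized here so that an alternative
    definition is a one-line change.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take the 75th percentile of an empty vector")
    if not (v > 0).any():
        raise ValueError("all-zero sample: 75th-percentile scaling is undefined")
    return float(np.quantile(v, 0.75))  # default 'linear' method


def scale_normalize(
    signal: np.ndarray, sample_names: list[str] | None = None
) -> tuple[np.ndarray, ScaleFactors]:
    """Scale-normalize a (features x samples) matrix.

    Returns the normalized matrix and the per-sample factors.  Raises
    ``ValueError`` naming the sample if any column has a non-positive 75th
    percentile.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 2:
        raise ValueError("signal must be a 2-d (features x samples) matrix")
    n_samples = x.shape[1]
    names = sample_names if sample_names is not None else [f"s{j}" for j in range(n_samples)]
    q75 = np.empty(n_samples)
    for j in range(n_samples):
        try:
            q75[j] = percentile75(x[:, j])
        except ValueError as e:
            raise ValueError(f"sample {names[j]!r}: {e}") from None
        if q75[j] <= 0:
            raise ValueError(
                f"sample {names[j]!r} has non-positive 75th percentile {q75[j]}"
            )
    global_median = float(np.median(q75))
    factors = global_median / q75
    sf = ScaleFactors(
        per_sample_q75=q75,
        global_median_q75=global_median,
        per_sample_factor=factors,
        sample_names=list(names),
    )
    return x * factors[np.newaxis, :], sf
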