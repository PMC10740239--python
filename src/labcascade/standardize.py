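"""Direct age-standardization of proportions.

A stratum-specific proportion p_b = events_b / n_b observed in 5-year
age bands (30-34 ... 70-74, plus an open-ended 75+) is standardized to
an external age distribution w by

    p_std = sum_b w_b * p_b

with a delta-method standard error

    se = sqrt( sum_b w_b^2 * p_b (1 - p_b) / n_b )

and a normal-approximation 95% CI. Bands with positive weight but no
observations have their weight renormalized over the observed bands
(and the condition is flagged), so the estimate is always defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .simulate import AGE_BANDS

Z95 = 1.959963984540054


@dataclass
class AgeWeights:
    """Normalized band weights with a provenance label."""

    weights: dict
    source: str = "unspecified"

    def __post_init__(self):
        unknown = set(self.weights) - set(AGE_BANDS)
        if unknown:
            raise ValueError(f"unknown age band labels: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("weights must have positive total")
        self.weights = {b: w / total for b, w in self.weights.items()}


@dataclass
class StandardizedEstimate:
    crude_prop: float
    std_prop: float
    se: float
    ci95: tuple
    per_band: pd.DataFrame
    renormalized: bool = False  # weight moved off bands with no data


def direct_standardize(band_counts: dict, weights: AgeWeights) -> StandardizedEstimate:
    """Directly standardize band-level (events, n) counts.

    ``band_counts`` maps band label -> (events, n). Raises if all n are
    zero or any count is negative.
    """
    rows = []
    for band, (events, n) in band_counts.items():
        if band not in AGE_BANDS:
            raise ValueError(f"unknown age band label: {band!r}")
        if events < 0 or n < 0 or events > n:
            raise ValueError(f"invalid counts for band {band}: ({events}, {n})")
        rows.append((band, events, n))
    per_band = pd.DataFrame(rows, columns=["band", "events", "n"])
    if per_band.empty or per_band["n"].sum() == 0:
        raise ValueError("no observations in any age band")

    observed = per_band[per_band["n"] > 0].copy()
    observed["prop"] = observed["events"] / observed["n"]

    w = pd.Series(weights.weights)
    w_obs = w.reindex(observed["band"]).fillna(0.0).to_numpy()
    dropped = sum(weights.weights.get(b, 0.0) for b in weights.weights
                  if b not in set(observed["band"]))
    renormalized = dropped > 0
    if w_obs.sum() <= 0:
        raise ValueError("no positive weight on any observed band")
    w_obs = w_obs / w_obs.sum()

    p = observed["prop"].to_numpy()
    n = observed["n"].to_numpy()
    std_prop = float(np.sum(w_obs * p))
    se = float(np.sqrt(np.sum(w_obs ** 2 * p * (1 - p) / n)))
    crude = float(observed["events"].sum() / observed["n"].sum())
    observed["weight"] = w_obs
    return StandardizedEstimate(
        crude_prop=crude, std_prop=std_prop, se=se,
        ci95=(std_prop - Z95 * se, std_prop + Z95 * se),
        per_band=observed.reset_index(drop=True),
        renormalized=renormalized,
    )


def load_weights(path=None, source: str | None = None) -> AgeWeights:
    """Load band weights from a two-column delimited file.

    Columns must be ``band`` plus either ``weight`` or ``population``
    (populations are normalized to weights). With no path, the bundled
    synthetic default weights are used — these are a plausible adult
    age pyramid for a middle-income country and explicitly NOT official
    mid-year population estimates.
    """
    if path is None:
        ref = resources.files("labcascade.data") / "age_weights_synthetic.csv"
        with resources.as_file(ref) as p:
            return load_weights(p, source="bundled synthetic default")
    df = pd.read_csv(path)
    if "band" not in df.columns:
        raise ValueError("weights file needs a 'band' column")
    if "weight" in df.columns:
        values = df["weight"]
    elif "population" in df.columns:
        values = df["population"]
    else:
        raise ValueError("weights file needs a 'weight' or 'population' column")
    weights = dict(zip(df["band"].astype(str), values.astype(float)))
    aw = AgeWeights(weights=weights, source=source or str(path))
    if abs(sum(aw.weights.values()) - 1.0) > 1e-9:
        raise ValueError("weights failed to normalize")
    return aw
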