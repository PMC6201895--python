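"""Feature extraction: response sequences to [W, H] or [W, H, E] vectors.

Each participant is summarised by up to three intrinsic-quality features:

* ``W`` — normalized number of decisions (attention span): the decision
  count min-max normalized to [0, 1], either against the cohort's own
  min/max or against the fixed protocol range [200, 800];
* ``H`` — Hurst exponent of the reaction-time sequence (attention
  stability), used raw since it already lives in (0, 1);
* ``E`` — error rate of decisions (distribution-shift of attention): the
  fraction of incorrect decisions, already in [0, 1].

Only W is rescaled: the raw decision count is two to three orders of
magnitude larger than H and E and would otherwise dominate every Euclidean
distance.  The component order is fixed as ``[W, H]`` / ``[W, H, E]``.

``FeatureExtractor`` is a scikit-learn style transformer (``fit`` learns
the normalization bounds, ``transform`` maps a cohort to a feature table),
so the whole pipeline composes with scikit-learn model selection;
``extract_features`` is the one-call functional wrapper.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .hurst import HurstEstimationError, RSConfig, estimate_hurst
from .io import Cohort, ResponseSequence, NOD_RANGE

__all__ = [
    "min_max_normalize",
    "compute_nnod",
    "compute_erd",
    "FeatureExtractor",
    "extract_features",
]

FEATURE_COLUMNS = {2: ["W", "H"], 3: ["W", "H", "E"]}


def min_max_normalize(values: Sequence[float]) -> np.ndarray:
    """Affine map of ``values`` onto [0, 1] sending min to 0 and max to 1."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize values with zero range")
    return (v - lo) / (hi - lo)


def compute_nnod(nod: int, bounds: tuple[float, float] = NOD_RANGE) -> float:
    """Normalized number of decisions ``W = (I - I_min) / (I_max - I_min)``.

    Values outside the bounds are clipped to [0, 1] with a warning.
    """
    lo, hi = bounds
    if hi <= lo:
        raise ValueError(f"bounds must satisfy I_max > I_min, got {bounds}")
    w = (nod - lo) / (hi - lo)
    if not 0.0 <= w <= 1.0:
        warnings.warn(
            f"NoD={nod} outside normalization bounds {bounds}; W clipped",
            stacklevel=2,
        )
        w = min(max(w, 0.0), 1.0)
    return float(w)


def compute_erd(sequence: ResponseSequence) -> float:
    """Error rate of decisions: fraction of events flagged incorrect.

    All decisions — including "Ignore" — count in the denominator.  Stored
    as a fraction in [0, 1]; report layers may display it as a percentage.
    """
    events = sequence.events
    if not events:
        raise ValueError("cannot compute an error rate for an empty sequence")
    return sum(1 for e in events if not e.correct) / len(events)


class FeatureExtractor(BaseEstimator, TransformerMixin):
    """Cohort-to-feature-matrix transformer.

    Parameters
    ----------
    dim : {2, 3}
        2 produces ``[W, H]`` rows, 3 adds the error rate ``E``.
    bounds_mode : {"cohort", "fixed"}
        "cohort" learns ``I_min``/``I_max`` from the fitted cohort's
        decision counts; "fixed" uses ``fixed_bounds`` (the protocol range
        by default).
    fixed_bounds : (float, float)
        Normalization bounds used when ``bounds_mode="fixed"``.
    rs_config : RSConfig or None
        Window schedule for the Hurst regression; None selects the default
        dyadic schedule.
    corrected : bool
        Whether the Hurst estimate uses the finite-sample bias correction.
    concatenate_tasks : bool
        Analyse the tasks as one concatenated reaction-time sequence (the
        default; the test is treated as a single 24-minute session).  When
        False, H is the mean of per-task estimates.

    Attributes
    ----------
    bounds_ : (float, float)
        Normalization bounds actually used, recorded for reproducibility.
    failed_ids_ : list of str
        Participants whose Hurst estimation failed and who were excluded
        (set by ``transform``).
    """

    def __init__(self, dim: int = 2, bounds_mode: str = "cohort",
                 fixed_bounds: tuple[float, float] = NOD_RANGE,
                 rs_config: RSConfig | None = None, corrected: bool = True,
                 concatenate_tasks: bool = True):
        self.dim = dim
        self.bounds_mode = bounds_mode
        self.fixed_bounds = fixed_bounds
        self.rs_config = rs_config
        self.corrected = corrected
        self.concatenate_tasks = concatenate_tasks

    def _validate(self, cohort: Cohort) -> None:
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        if self.bounds_mode not in ("cohort", "fixed"):
            raise ValueError(f"unknown bounds_mode {self.bounds_mode!r}")
        if len(cohort) == 0:
            raise ValueError("cohort is empty")

    def fit(self, cohort: Cohort, y=None) -> "FeatureExtractor":
        self._validate(cohort)
        if self.bounds_mode == "cohort":
            nods = [seq.nod for seq in cohort]
            lo, hi = float(min(nods)), float(max(nods))
            if hi == lo:
                raise ValueError(
                    "cohort bounds are degenerate (all decision counts equal); "
                    "use bounds_mode='fixed'"
                )
            self.bounds_ = (lo, hi)
        else:
            lo, hi = self.fixed_bounds
            if hi <= lo:
                raise ValueError(f"invalid fixed bounds {self.fixed_bounds}")
            self.bounds_ = (float(lo), float(hi))
        return self

    def transform(self, cohort: Cohort) -> pd.DataFrame:
        """Feature table with one row per participant, in cohort order."""
        if not hasattr(self, "bounds_"):
            raise RuntimeError("FeatureExtractor is not fitted")
        self._validate(cohort)
        cols = FEATURE_COLUMNS[self.dim]
        rows, index = [], []
        self.failed_ids_ = []
        for seq in cohort:
            try:
                h = self._hurst(seq)
            except HurstEstimationError as exc:
                warnings.warn(
                    f"participant {seq.participant_id}: Hurst estimation "
                    f"failed ({exc}); row excluded",
                    stacklevel=2,
                )
                self.failed_ids_.append(seq.participant_id)
                continue
            row = [compute_nnod(seq.nod, self.bounds_), h]
            if self.dim == 3:
                row.append(compute_erd(seq))
            rows.append(row)
            index.append(seq.participant_id)
        return pd.DataFrame(rows, columns=cols,
                            index=pd.Index(index, name="participant_id"))

    def _hurst(self, seq: ResponseSequence) -> float:
        config = self.rs_config or RSConfig()
        if self.concatenate_tasks:
            series = [seq.reaction_times]
        else:
            series = [[e.reaction_time_ms for e in task] for task in seq.tasks]
        estimates = [
            estimate_hurst(s, config, corrected=self.corrected).H for s in series
        ]
        return float(np.mean(estimates))


def extract_features(cohort: Cohort, dim: int = 2,
                     rs_config: RSConfig | None = None,
                     bounds_mode: str = "cohort",
                     fixed_bounds: tuple[float, float] = NOD_RANGE,
                     corrected: bool = True) -> pd.DataFrame:
    """Fit-and-transform convenience wrapper around :class:`FeatureExtractor`."""
    fx = FeatureExtractor(dim=dim, bounds_mode=bounds_mode,
                          fixed_bounds=fixed_bounds, rs_config=rs_config,
                          corrected=corrected)
    return fx.fit(cohort).transform(cohort)
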