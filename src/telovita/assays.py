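"""TRAP telomerase quantification and hormone normalisation.

Cq values are read off semi-log amplification plots (log fluorescence vs
cycle) by linear interpolation at the threshold crossing; relative
telomerase activity is the fold change 2^(-dCq) against a designated
reference sample.  Hormone concentrations are normalised by plasma
protein.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import CqUndeterminedError, TelovitaError


def compute_cq(cycles, fluorescence, threshold):
    """Fractional cycle at which fluorescence crosses ``threshold``.

    Interpolates linearly in log-fluorescence against cycle number within
    the first upward crossing.  Raises :class:`CqUndeterminedError` when
    the curve never reaches the threshold, or already exceeds it at the
    first cycle (crossing outside the recorded range).
    """
    cycles = np.asarray(cycles, dtype=float)
    fluorescence = np.asarray(fluorescence, dtype=float)
    if threshold <= 0:
        raise TelovitaError("threshold must be positive (log scale)")
    if fluorescence[0] >= threshold:
        raise CqUndeterminedError("threshold below the first-cycle signal")
    above = fluorescence >= threshold
    if not above.any():
        raise CqUndeterminedError("curve never crosses the threshold")
    k = int(np.argmax(above))
    f0, f1 = np.log(fluorescence[k - 1]), np.log(fluorescence[k])
    return float(cycles[k - 1] + (np.log(threshold) - f0) / (f1 - f0)
                 * (cycles[k] - cycles[k - 1]))


def cq_table(curves, threshold):
    """Per-replicate Cq for a tidy amplification table.

    Undetermined Cq values become NaN with ``flag='undetermined'`` (treated
    as censored, never as zero).
    """
    rows = []
    for (sample, rep), grp in curves.groupby(["sample", "replicate"]):
        grp = grp.sort_values("cycle")
        try:
            cq = compute_cq(grp["cycle"].to_numpy(), grp["fluorescence"].to_numpy(),
                            threshold)
            flag = ""
        except CqUndeterminedError:
            cq, flag = np.nan, "undetermined"
        rows.append((sample, rep, cq, flag))
    return pd.DataFrame(rows, columns=["sample", "replicate", "cq", "flag"])


@dataclass
class TelomeraseResult:
    cq_sample: float
    cq_reference: float

    @property
    def delta_cq(self):
        return self.cq_sample - self.cq_reference

    @property
    def relative_activity(self):
        return 2.0 ** (-self.delta_cq)


def relative_activity(cq_sample, cq_reference):
    """Fold telomerase activity by the 2^(-dCq) method."""
    if not (np.isfinite(cq_sample) and np.isfinite(cq_reference)):
        raise CqUndeterminedError("cannot form dCq from an undetermined Cq")
    return float(2.0 ** (-(cq_sample - cq_reference)))


def summarize_triplicates(cq_frame, how="mean_cq"):
    """Collapse replicate Cq values per sample.

    Default averages Cq before any dCq is formed (standard practice);
    ``how='mean_activity'`` averages 2^-Cq instead and reports the
    equivalent Cq.  NaN replicates are dropped with their flags retained.
    """
    out = []
    for sample, grp in cq_frame.groupby("sample"):
        vals = grp["cq"].dropna().to_numpy()
        if vals.size == 0:
            out.append((sample, np.nan, "undetermined"))
            continue
        if how == "mean_cq":
            cq = float(vals.mean())
        elif how == "mean_activity":
            cq = float(-np.log2(np.mean(2.0 ** (-vals))))
        else:
            raise TelovitaError(f"unknown summary {how!r}")
        flag = "partial" if vals.size < len(grp) else ""
        out.append((sample, cq, flag))
    return pd.DataFrame(out, columns=["sample", "cq", "flag"])


@dataclass
class HormonePanel:
    """Raw or protein-normalised hormone concentrations for one sample."""

    e2: float
    t: float
    kt11: float
    plasma_protein: float  # mg/mL
    units: str = "pg/mL"

    def __post_init__(self):
        if min(self.e2, self.t, self.kt11) < 0:
            raise TelovitaError("hormone concentrations must be >= 0")


def normalize_hormones(panel):
    """Divide each hormone by plasma protein; unit string records the change."""
    if panel.plasma_protein <= 0:
        raise TelovitaError("invalid sample: plasma protein must be positive")
    p = panel.plasma_protein
    return replace(
        panel,
        e2=panel.e2 / p,
        t=panel.t / p,
        kt11=panel.kt11 / p,
        plasma_protein=1.0,
        units=f"{panel.units} per mg protein",
    )
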