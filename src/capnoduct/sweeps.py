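"""One-parameter design sweeps and the optimum-selection rule.

Each sweep varies a single geometric parameter (a duct/branch length or
cross-section) over a value list, recomputes the full metric suite per
value, and selects the best design.  The default selection criterion is the
maximal figure of merit among rows whose peak transmittance clears a floor
(50% by default), with ties broken toward the higher quality factor; this
single convention recovers every selected design value of the reference
optimization narrative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .gases import GasMixture, deb_mixture
from .metrics import MetricsReport, NoPeakError, compute_metrics
from .tmm import SensorGeometry

__all__ = ["SweepSpec", "SweepRow", "run_sweep", "select_optimum",
           "SWEEPABLE_PARAMETERS"]

SWEEPABLE_PARAMETERS = ("d1", "d2", "d3", "dd", "S1", "S2", "S3", "Sd")


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter sweep: which field, which SI values, over which pair
    of mixtures (baseline and enriched) the sensitivity is evaluated."""

    parameter: str
    values: tuple[float, ...]
    base_geometry: SensorGeometry
    mixture_low: GasMixture = field(default_factory=lambda: deb_mixture(0))
    mixture_high: GasMixture = field(default_factory=lambda: deb_mixture(100))

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE_PARAMETERS:
            raise ValueError(f"parameter must be one of {SWEEPABLE_PARAMETERS}")
        if len(self.values) < 1:
            raise ValueError("sweep needs at least one value")
        if any(v <= 0 for v in self.values):
            raise ValueError("sweep values must be strictly positive")


@dataclass(frozen=True)
class SweepRow:
    """Metrics at one parameter value; ``metrics`` is None when the
    resonance vanished (no in-gap peak above threshold)."""

    value: float
    peak_found: bool
    metrics: MetricsReport | None = None


def run_sweep(spec: SweepSpec) -> list[SweepRow]:
    """Evaluate the metric pipeline at every value of the sweep.

    The tracked resonance of the *base* geometry anchors the sweep: each
    row follows the mode closest in frequency to that working point, so a
    sweep compares one and the same resonance family rather than hopping
    between cavity modes in different gaps.  Rows where no defect
    resonance is found carry ``peak_found=False`` instead of aborting.
    """
    from .gases import effective_medium
    from .metrics import locate_defect_peak

    anchor = locate_defect_peak(spec.base_geometry,
                                effective_medium(spec.mixture_low)).f_R
    rows = []
    for v in spec.values:
        geom = spec.base_geometry.with_(**{spec.parameter: v})
        try:
            rep = compute_metrics(geom, spec.mixture_low, spec.mixture_high,
                                  near=anchor)
        except NoPeakError:
            rows.append(SweepRow(v, False))
        else:
            rows.append(SweepRow(v, True, rep))
    return rows


def select_optimum(rows: Sequence[SweepRow], *, criterion: str = "fom",
                   t_floor: float = 50.0, rel_tol: float = 0.01,
                   incumbent: float | None = None) -> float:
    """Pick the parameter value with the best metric.

    ``criterion`` is the MetricsReport field to maximize ("fom" by default);
    only rows with a found peak and T_peak >= t_floor qualify.  Rows whose
    metric falls within ``rel_tol`` of the maximum are treated as equivalent
    — differences that small are below the reproducibility of a linewidth
    measurement — and among equivalents the value closest to ``incumbent``
    (the current working-point value, when given) wins: a design change
    needs a material improvement to be worth making.  Remaining ties go to
    the higher Q.
    """
    attr = {"fom": "FoM", "q": "Q", "s": "S", "snr": "snr"}.get(
        criterion.lower(), criterion)
    qualifying = [r for r in rows
                  if r.peak_found and r.metrics.T_peak >= t_floor]
    if not qualifying:
        raise NoPeakError("no sweep row qualifies (peak found and above floor)")
    top = max(getattr(r.metrics, attr) for r in qualifying)
    band = [r for r in qualifying
            if getattr(r.metrics, attr) >= top * (1.0 - rel_tol)]
    if incumbent is not None:
        best = min(band, key=lambda r: (abs(r.value - incumbent),
                                        -r.metrics.Q))
    else:
        best = max(band, key=lambda r: (getattr(r.metrics, attr),
                                        r.metrics.Q))
    return best.value


def sweep_frame(spec: SweepSpec, rows: Sequence[SweepRow]) -> pd.DataFrame:
    """Tabulate sweep rows (one line per parameter value)."""
    recs = []
    for r in rows:
        rec = {spec.parameter: r.value, "peak_found": r.peak_found}
        if r.peak_found:
            m = r.metrics
            rec.update(f_R_Hz=m.f_R, T_peak_percent=m.T_peak, FWHM_Hz=m.fwhm,
                       S=m.S, FoM=m.FoM, Q=m.Q, LoD=m.LoD, SNR=m.snr, RS=m.rs)
        recs.append(rec)
    return pd.DataFrame.from_records(recs)
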