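"""Published per-patient benchmark rows for the CHB-MIT evaluation.

Reported event-level results (per patient: seizure counts, true/false
positives, mean latency and delay) for the two detectors on the CHB-MIT
scalp-EEG database.  They serve as worked-example inputs for the report
aggregator: pooled sensitivity and the mean latency/delay rows follow
from these printed values by arithmetic, which makes them useful
end-to-end checks of :func:`eegsync.detection.aggregate_reports`.

The "spectral" table covers the 17 patients whose seizures are not
dominated by amplitude depression (which the spectral-network feature
cannot see); the "icon" table covers all 24 cases.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .detection import DetectionReport

__all__ = ["load_benchmark", "benchmark_reports", "spectral_patient_subset"]

_FILES = {
    "spectral": "chbmit_spectral.csv",
    "icon": "chbmit_icon.csv",
}


def load_benchmark(method: str) -> pd.DataFrame:
    """Per-patient benchmark table for ``method`` in {"spectral", "icon"}."""
    if method not in _FILES:
        raise ValueError(f"unknown benchmark: {method!r} (use 'spectral' or 'icon')")
    with resources.files("eegsync.data").joinpath(_FILES[method]).open() as fh:
        return pd.read_csv(fh)


def spectral_patient_subset() -> list[int]:
    """Patients evaluated under the spectral method (no amplitude
    depression), usable to subset the icon table for a like-for-like
    comparison."""
    return load_benchmark("spectral")["patient"].tolist()


def benchmark_reports(method: str, patients: list[int] | None = None) -> list[DetectionReport]:
    """Benchmark rows as summary :class:`DetectionReport` objects."""
    df = load_benchmark(method)
    if patients is not None:
        df = df[df["patient"].isin(patients)]
    return [
        DetectionReport.from_summary(
            ns=int(row.ns),
            tp=int(row.tp),
            fp=int(row.fp),
            mean_delay=float(row.delay_s),
            mean_latency=float(row.latency_s),
        )
        for row in df.itertuples()
    ]
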