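"""Delimited-text ingestion and report writing.

The input dialect is CSV with a header: required columns ``id``, ``time``,
``status``; optional ``entry`` (defaults to 0); every remaining column is a
covariate.  Rows describe half-open at-risk intervals ``(entry, time]``;
time-dependent covariates are encoded as multiple rows per subject with
disjoint intervals.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import ConfidenceBand
from .cox import CoxFit
from .data import DataError, SurvivalSample

__all__ = ["read_survival_csv", "write_survival_csv", "write_band",
           "write_fit_report"]


def read_survival_csv(path, covariate_cols=None) -> SurvivalSample:
    """Read and validate a counting-process CSV.

    Raises :class:`~coxband.data.DataError` naming the offending column or
    (1-based, header excluded) row on invalid input.
    """
    df = pd.read_csv(path)
    try:
        return SurvivalSample.from_dataframe(df, covariate_cols=covariate_cols)
    except DataError as err:
        # data-row indices in messages refer to the frame; keep them 0-based
        raise DataError(f"{path}: {err}") from err


def write_survival_csv(sample: SurvivalSample, path) -> None:
    sample.to_dataframe().to_csv(path, index=False)


def write_fit_report(fit: CoxFit, path) -> None:
    """JSON fit report: coefficients, SEs, and the Breslow step function."""
    report = fit.report()
    report["breslow"] = [
        {"time": float(t), "increment": float(d), "cumulative": float(v)}
        for t, d, v in zip(fit.breslow.times, fit.breslow.increments,
                           fit.breslow.values)
    ]
    Path(path).write_text(json.dumps(report, indent=2))


def write_band(band: ConfidenceBand, csv_path, json_path=None) -> None:
    """Band grid as CSV (t, estimate, lower, upper) plus a JSON header."""
    pd.DataFrame({
        "t": band.times, "estimate": band.estimate,
        "lower": band.lower, "upper": band.upper,
    }).to_csv(csv_path, index=False)
    header = {
        "critical_value": float(band.critical_value),
        "alpha": band.spec.alpha,
        "transform": band.spec.transform,
        "weight": band.spec.weight,
        "interval": [float(x) for x in band.spec.interval],
        "n_replicates": int(band.n_replicates),
        "dropped": int(band.dropped),
    }
    if json_path is not None:
        Path(json_path).write_text(json.dumps(header, indent=2))
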