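"""Published comparator results for the ARC-111 analogue series.

These constants are the literature's reported independent-test metrics
and F statistics for QSAR models of the same 22-compound ARC-111 /
RPMI8402 dataset shipped as this package's fixture. They are kept for
display next to new runs — the descriptor values behind them were never
published, so they cannot be recomputed, only cited.
"""

from __future__ import annotations

__all__ = [
    "LITERATURE_TEST_METRICS",
    "LITERATURE_MODEL_F",
    "LITERATURE_EFFECT_DIRECTIONS",
    "comparator_table",
]

# model -> (number of descriptors, test MSE, test R^2, test R^2_pred)
LITERATURE_TEST_METRICS: dict[str, dict[str, float]] = {
    "stepwise_MLR": {"n_descriptors": 5, "mse": 0.201, "r2": 0.910, "r2_pred": 0.730},
    "PLS":          {"n_descriptors": 7, "mse": 0.167, "r2": 0.890, "r2_pred": 0.775},
    "ANN":          {"n_descriptors": 9, "mse": 0.050, "r2": 0.962, "r2_pred": 0.933},
    "SVR1":         {"n_descriptors": 9, "mse": 0.141, "r2": 0.937, "r2_pred": 0.811},
    "SVR2":         {"n_descriptors": 6, "mse": 0.061, "r2": 0.950, "r2_pred": 0.918},
    "SVR3":         {"n_descriptors": 7, "mse": 0.032, "r2": 0.964, "r2_pred": 0.957},
    "SVR4":         {"n_descriptors": 11, "mse": 0.028, "r2": 0.971, "r2_pred": 0.962},
}

# reported overall regression F statistics with their df
LITERATURE_MODEL_F = {
    "SVR3": {"f": 21.017, "df": (7, 10), "significance": "**"},
    "SVR4": {"f": 7.310, "df": (11, 6), "significance": "*"},
}

# reported per-descriptor importance F values (refit-based, df (1, n-p-1))
LITERATURE_DESCRIPTOR_F = {
    "SVR3": {"c6A": 26.555, "ATS1v": 25.175, "nCIC": 12.210, "MATS3e": 12.114,
             "nCrs": 5.898, "GGI5": 3.687, "QYYv": 2.387},
    "SVR4": {"BELv2": 11.382, "p3-2N": 3.771, "SP20": 3.511, "SEigZ": 2.456,
             "nN": 2.456, "RDF040v": 2.435, "TWC": 2.425, "RDF040p": 2.398,
             "ZM1V": 2.084, "RDF040e": 1.304, "HATS0u": 0.599},
}

# reported single-factor effect directions
LITERATURE_EFFECT_DIRECTIONS = {
    "SVR3": {"positive": ["nCrs"], "negative_count": 6},
    "SVR4": {"positive": ["HATS0u"], "negative_count": 10},
}


def comparator_table() -> "list[dict]":
    """Literature test-set metrics as tidy records for run reports."""
    return [{"model": name, **vals} for name, vals in LITERATURE_TEST_METRICS.items()]
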