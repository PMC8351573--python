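"""Bundled reference parameter values.

The panel below holds published gamma/Erlang carcinogenesis parameter
estimates for ten childhood and young-adulthood cancer types, obtained from
US national incidence data (CDC WONDER, United States Cancer Statistics
1999-2012, crude rates by 5-year age group).  For each cancer type: the
shape ``k`` (average number of driver events), the scale ``b`` (average
interval between events, years) and ``A/1000`` (maximal populational
susceptibility, percent).

These values serve as realistic ground-truth inputs for the synthetic-data
generator and for the waiting-time summary; they are printed estimates, not
something this package recomputes (the underlying incidence export is not
redistributed here).
"""

from __future__ import annotations

import pandas as pd

from .interpretation import CarcinogenesisParams

__all__ = [
    "CHILDHOOD_CANCER_PARAMETERS",
    "childhood_cancer_parameters",
    "childhood_carcinogenesis_params",
]

#: (cancer type, k, b, A/1000 %) — reference gamma/Erlang estimates.
CHILDHOOD_CANCER_PARAMETERS: tuple[tuple[str, float, float, float], ...] = (
    ("Ewing tumour and related sarcomas of bone", 4.3, 4.25, 0.0846),
    ("Extracranial and extragonadal germ cell tumours of childhood", 0.4, 2.35, 0.0322),
    ("Extracranial and extragonadal germ cell tumours of young adulthood", 6.5, 5.3, 0.111),
    ("Hepatoblastoma", 1.55, 1.4, 0.0338),
    ("Intracranial and intraspinal embryonal tumours", 1.0, 14.85, 0.179),
    ("Intracranial and intraspinal germ cell tumours", 5.65, 3.05, 0.0426),
    ("Malignant gonadal germ cell tumours", 8.95, 3.9, 1.966),
    ("Nephroblastoma and other nonepithelial renal tumours", 1.75, 2.2, 0.124),
    ("Neuroblastoma and ganglioneuroblastoma", 1.0, 2.5, 0.179),
    ("Retinoblastoma", 1.3, 1.45, 0.072),
)


def childhood_cancer_parameters() -> pd.DataFrame:
    """The reference panel as a DataFrame (cancer, k, b, susceptibility_percent)."""
    return pd.DataFrame(
        CHILDHOOD_CANCER_PARAMETERS,
        columns=["cancer", "k", "b", "susceptibility_percent"],
    )


def childhood_carcinogenesis_params() -> list[CarcinogenesisParams]:
    """The reference panel as :class:`CarcinogenesisParams` records.

    The amplitude is reconstructed as ``susceptibility_percent * 1000`` and
    the waiting time as ``k * b``.
    """
    return [
        CarcinogenesisParams(
            driver_events=k,
            interval_years=b,
            susceptibility_percent=susc,
            waiting_time_years=k * b,
        )
        for _, k, b, susc in CHILDHOOD_CANCER_PARAMETERS
    ]
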