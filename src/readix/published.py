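"""Published quintile cross-tabulations used as a numerical ground truth.

A pooled analysis of 9,238 health facilities from ten countries' Service
Provision Assessment surveys reported quintile cross-classifications of the
full 649-item readiness index against four candidate indices — the WHO
service readiness index (SRI) as extractable (37-49 of 50 items per country),
50- and 100-item empirically selected indices, and a 100-item enriched SRI —
as row percentages with the quintile Ns, plus the resulting kappa statistics.
Those printed panels are transcribed here; rebuilding the cell counts from
the row percentages and recomputing kappa and percent agreement is an
end-to-end check of the agreement machinery against independently published
numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agreement import (
    cohen_kappa,
    matrix_from_row_percentages,
    percent_agreement,
)

__all__ = [
    "QUINTILE_ROW_NS",
    "PANEL_ROW_PERCENTAGES",
    "PRINTED_KAPPA",
    "PRINTED_AGREEMENT_PCT",
    "reconstruct_panel",
    "reconstruction_report",
    "check_reconstruction",
]

# Quintile sizes of the full-index reference classification (n = 9238).
QUINTILE_ROW_NS = (1848, 1848, 1847, 1848, 1847)

# Row percentages: rows = full-index quintile (1 = best), columns = candidate
# index quintile.
PANEL_ROW_PERCENTAGES = {
    "sri": (
        (67.9, 26.4, 5.2, 0.5, 0.0),
        (22.5, 38.1, 31.1, 7.6, 0.7),
        (7.9, 22.7, 32.3, 27.9, 9.2),
        (1.9, 11.0, 22.6, 38.4, 26.1),
        (0.0, 1.9, 8.5, 25.6, 64.0),
    ),
    "empirical_50": (
        (88.4, 11.6, 0.0, 0.0, 0.0),
        (11.6, 74.7, 13.6, 0.1, 0.0),
        (0.1, 13.6, 72.1, 14.2, 0.0),
        (0.0, 0.2, 14.1, 76.0, 9.7),
        (0.0, 0.0, 0.0, 10.0, 90.0),
    ),
    "empirical_100": (
        (91.9, 8.1, 0.0, 0.0, 0.0),
        (8.1, 82.8, 9.0, 0.0, 0.0),
        (0.0, 9.0, 82.1, 8.9, 0.0),
        (0.0, 0.0, 8.9, 85.0, 6.1),
        (0.0, 0.0, 0.0, 6.1, 93.9),
    ),
    "enriched_sri_100": (
        (89.7, 10.3, 0.0, 0.0, 0.0),
        (10.3, 78.8, 10.9, 0.0, 0.0),
        (0.0, 11.0, 77.2, 11.9, 0.0),
        (0.0, 0.0, 11.9, 78.6, 9.5),
        (0.0, 0.0, 0.0, 9.5, 90.5),
    ),
}

# As printed alongside the panels.
PRINTED_KAPPA = {
    "sri": 0.35,
    "empirical_50": 0.75,
    "empirical_100": 0.84,
    "enriched_sri_100": 0.79,
}
# Percent of facilities on the diagonal, at the precision printed.
PRINTED_AGREEMENT_PCT = {
    "sri": 48.0,
    "empirical_50": 80.0,
    "empirical_100": 87.0,
    "enriched_sri_100": 83.0,
}
_AGREEMENT_DECIMALS = {
    "sri": 0,
    "empirical_50": 0,
    "empirical_100": 0,
    "enriched_sri_100": 1,
}


def reconstruct_panel(name: str):
    """Cross-tabulation of one panel rebuilt from its printed row percentages."""
    return matrix_from_row_percentages(
        QUINTILE_ROW_NS, PANEL_ROW_PERCENTAGES[name]
    )


def reconstruction_report() -> pd.DataFrame:
    """Recomputed vs printed kappa and percent agreement for every panel."""
    rows = []
    for name in PANEL_ROW_PERCENTAGES:
        cm = reconstruct_panel(name)
        kappa = cohen_kappa(cm)
        agree = percent_agreement(cm)
        dec = _AGREEMENT_DECIMALS[name]
        rows.append(
            {
                "panel": name,
                "kappa": kappa,
                "kappa_2dp": round(kappa, 2),
                "printed_kappa": PRINTED_KAPPA[name],
                "agreement_pct": agree,
                "agreement_printed_precision": round(agree, dec),
                "printed_agreement_pct": PRINTED_AGREEMENT_PCT[name],
            }
        )
    df = pd.DataFrame(rows)
    df["kappa_match"] = np.isclose(df["kappa_2dp"], df["printed_kappa"])
    # row percentages are printed at 0.1% resolution, so reconstructed cell
    # counts carry up to 0.05 points of rounding drift on the diagonal share
    dec = np.array([_AGREEMENT_DECIMALS[name] for name in df["panel"]])
    tol = 0.5 * 10.0 ** (-dec) + 0.05
    df["agreement_match"] = (
        np.abs(df["agreement_pct"] - df["printed_agreement_pct"]) <= tol
    )
    return df


def check_reconstruction() -> pd.DataFrame:
    """Raise if any recomputed statistic differs from the printed value."""
    report = reconstruction_report()
    bad = report[~(report["kappa_match"] & report["agreement_match"])]
    if len(bad):
        raise AssertionError(
            "reconstructed statistics differ from the printed values:\n"
            + bad.to_string(index=False)
        )
    return report
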