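"""Published summary values from the Lake Lucerne whitefish gill-net survey.

These printed per-event and per-species summaries are the reference inputs
for the arithmetic cross-checks (column totals, overall diversity row,
linkage-disequilibrium bookkeeping, pairwise differentiation summaries).
They are data, not computed results: every value below is transcribed from
the published survey tables.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = [
    "sampling_summary",
    "diversity_by_species",
    "pairwise_fst_matrix",
    "LOCI",
]

#: The ten microsatellite loci of the survey.
LOCI = [
    "Cocl-Lav49", "Cocl-Lav61", "Cocl-Lav6", "Cocl-Lav68", "Cocl-Lav10",
    "Cisco-157", "Cocl-Lav4", "Cocl-Lav45", "Cocl-Lav18", "BWF-2",
]


def sampling_summary() -> pd.DataFrame:
    """Per-event catch summary: sample sizes and per-SL-class counts.

    ``n_year3`` is the number of three-year-olds entering the population
    genetic analyses (not recorded for the two reference species sampled
    outside the gradient design).
    """
    rows = [
        # name, lat, lon, sample_size, n_year3, n_small, n_int, n_large, n_genetics
        ("Depth gradient", "47°01′36.37″", "8°25′31.56″", 268, 149, 107, 34, 8, 149),
        ("Supp. Large", "47°01′36.37″", "8°25′31.56″", 8, 6, None, None, 6, 6),
        ("Pelagic", "47°01′34.00″", "8°24′47.00″", 66, 19, None, 14, 5, 19),
        ("Large 1", "47°01′44.71″", "8°23′42.23″", 41, 16, None, None, 16, 16),
        ("Large 2", "46°58′31.81″", "8°33′05.74″", 30, 6, None, None, 6, 6),
        ("Large 3", "46°58′24.01″", "8°36′29.52″", 57, 10, None, None, 10, 10),
        ("Int 1", "46°58′24.01″", "8°36′29.52″", 6, 6, None, 6, None, 6),
        ("Small 1", "47°02′37.04″", "8°23′11.80″", 9, 3, 3, None, None, 3),
        ("Small 2", "47°01′40.95″", "8°25′42.53″", 25, 7, 7, None, None, 7),
        ("Small 3", "46°59′53.11″", "8°35′05.27″", 63, 15, 15, None, None, 14),
        ("Small n.s.", "47°02′37.04″", "8°23′11.80″", 16, 5, 5, None, None, 5),
        ("C. nobilis", "46°59′25.55″", "8°29′10.24″", 38, None, None, None, None, 38),
        ("Alpnach", "46°57′52.11″", "8°19′10.49″", 20, None, None, None, None, 20),
    ]
    return pd.DataFrame(
        rows,
        columns=["name", "lat", "lon", "sample_size", "n_year3",
                 "n_small", "n_int", "n_large", "n_genetics"],
    )


def diversity_by_species() -> pd.DataFrame:
    """Per-species genetic diversity summary (six species groupings)."""
    rows = [
        ("Small", 136, 0.48, 0.50, 3.36, 0.04, 3),
        ("Benthic intermediate", 34, 0.54, 0.57, 3.61, 0.06, 1),
        ("Pelagic intermediate", 14, 0.53, 0.58, 3.47, 0.09, 2),
        ("Large", 51, 0.57, 0.59, 3.55, 0.03, 2),
        ("C. nobilis", 38, 0.47, 0.47, 2.95, 0.01, 3),
        ("Alpnach", 20, 0.54, 0.57, 3.43, 0.05, 1),
    ]
    return pd.DataFrame(rows, columns=["species", "n", "ho", "he", "a_r", "fis", "n_ld"])


def pairwise_fst_matrix() -> pd.DataFrame:
    """Published pairwise F_ST between the six species groupings."""
    species = ["Small", "Benthic intermediate", "Pelagic intermediate",
               "Large", "C. nobilis", "Alpnach"]
    lower = {
        ("Benthic intermediate", "Small"): 0.028,
        ("Pelagic intermediate", "Small"): 0.064,
        ("Pelagic intermediate", "Benthic intermediate"): 0.019,
        ("Large", "Small"): 0.124,
        ("Large", "Benthic intermediate"): 0.029,
        ("Large", "Pelagic intermediate"): 0.040,
        ("C. nobilis", "Small"): 0.028,
        ("C. nobilis", "Benthic intermediate"): 0.036,
        ("C. nobilis", "Pelagic intermediate"): 0.065,
        ("C. nobilis", "Large"): 0.107,
        ("Alpnach", "C. nobilis"): 0.092,
        ("Alpnach", "Small"): 0.069,
        ("Alpnach", "Benthic intermediate"): 0.022,
        ("Alpnach", "Pelagic intermediate"): 0.040,
        ("Alpnach", "Large"): 0.050,
    }
    M = pd.DataFrame(np.zeros((6, 6)), index=species, columns=species)
    for (a, b), v in lower.items():
        M.loc[a, b] = M.loc[b, a] = v
    return M


def pairwise_fst_values() -> np.ndarray:
    """The 15 printed pairwise values, as a flat vector."""
    M = pairwise_fst_matrix()
    return np.array([M.iloc[j, i] for i, j in itertools.combinations(range(6), 2)])
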