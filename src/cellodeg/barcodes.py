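"""Species assignment of single-microbe barcodes by majority classification.

Each barcode carries per-species classified read counts (Kraken2/Bracken-
style, treated as opaque upstream output). The species with the highest
read fraction becomes the barcode's identity; that maximum fraction is the
barcode *purity*, and barcodes with purity >= 50% (inclusive) are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeProfile",
    "CellAssignment",
    "assign",
    "assign_batch",
    "filter_features",
]


@dataclass
class BarcodeProfile:
    barcode: str
    species_reads: dict[str, int]


@dataclass
class CellAssignment:
    barcode: str
    species_id: str | None
    purity: float
    kept: bool
    tie_flag: bool
    reason: str = ""  # nonempty when unassignable


def assign(profile: BarcodeProfile, purity_threshold: float = 0.50) -> CellAssignment:
    """Assign a barcode to its majority species.

    Ties at the maximum are broken by lexicographically smallest species id
    and flagged. An all-zero profile is unassignable (kept=False with a
    reason code).
    """
    total = sum(profile.species_reads.values())
    if total <= 0:
        return CellAssignment(profile.barcode, None, 0.0, False, False,
                              reason="no_classified_reads")
    max_reads = max(profile.species_reads.values())
    winners = sorted(s for s, r in profile.species_reads.items() if r == max_reads)
    species = winners[0]
    purity = max_reads / total
    return CellAssignment(
        barcode=profile.barcode,
        species_id=species,
        purity=purity,
        kept=purity >= purity_threshold,
        tie_flag=len(winners) > 1,
    )


def assign_batch(profiles: Iterable[BarcodeProfile],
                 purity_threshold: float = 0.50
                 ) -> tuple[pd.DataFrame, dict]:
    """Assign a batch of barcodes; returns (assignments, summary).

    Summary reports the kept fraction and per-species kept counts; the
    per-category counts sum to the input size.
    """
    rows = [assign(p, purity_threshold) for p in profiles]
    df = pd.DataFrame([vars(a) for a in rows])
    if df.empty:
        df = pd.DataFrame(columns=["barcode", "species_id", "purity", "kept",
                                   "tie_flag", "reason"])
    n = len(df)
    kept = df["kept"].to_numpy(dtype=bool) if n else np.array([], dtype=bool)
    summary = {
        "n_barcodes": n,
        "n_kept": int(kept.sum()),
        "n_dropped": int(n - kept.sum()),
        "kept_fraction": float(kept.mean()) if n else float("nan"),
        "kept_by_species": (
            df.loc[df["kept"], "species_id"].value_counts().to_dict() if n else {}
        ),
    }
    return df, summary


def filter_features(matrix, min_features: int = 15):
    """Remove cells with fewer than `min_features` detected genes.

    A gene is detected in a cell when its UMI count is > 0. Cells with
    exactly `min_features` detected genes are retained.
    """
    n_feat = matrix.n_features_per_cell
    keep = n_feat >= min_features
    if not keep.any():
        warnings.warn("all cells fall below the feature threshold",
                      UserWarning, stacklevel=2)
    return matrix.subset_cells(np.flatnonzero(keep))
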