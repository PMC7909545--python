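"""CANAPE: categorical analysis of neo- and paleo-endemism.

Cells are first tested for significantly concentrated endemism (high PE on
the observed or on the comparison tree); significant cells are then split
by the RPE randomization tails into paleo- (rare long branches), neo-
(rare short branches) and mixed-endemism centres, with super-endemism
centres the highly significant subdivision of the mixed class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .randomization import NullResult

__all__ = ["CanapeClassification", "classify_cells", "CATEGORIES"]

CATEGORIES = ("not_significant", "neo", "paleo", "mixed", "super")


@dataclass
class CanapeClassification:
    cell_ids: np.ndarray
    category: np.ndarray  # array of strings from CATEGORIES
    alpha_primary: float = 0.05
    alpha_rpe_tail: float = 0.025
    alpha_super: float = 0.01

    def counts(self) -> pd.Series:
        s = pd.Series(self.category).value_counts()
        return s.reindex(CATEGORIES, fill_value=0)

    def cells_in(self, category: str) -> np.ndarray:
        return self.cell_ids[self.category == category]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell": self.cell_ids, "category": self.category})


def classify_cells(
    null: NullResult,
    alpha_primary: float = 0.05,
    alpha_rpe_tail: float = 0.025,
    alpha_super: float = 0.01,
) -> CanapeClassification:
    """Classify every cell of a NullResult into an endemism-centre type.

    Step 1: candidate iff p_high(PE_obs) < alpha_primary or
    p_high(PE_alt) < alpha_primary; everything else is not_significant.
    Step 2: candidates with p_high(RPE) < alpha_rpe_tail are paleo, with
    p_low(RPE) < alpha_rpe_tail neo, otherwise mixed (the RPE two-tailed
    test at overall 2*alpha_rpe_tail).
    Step 3: mixed candidates with both PE p-values < alpha_super are super.
    """
    for m in ("PE_obs", "PE_alt", "RPE"):
        if m not in null.p_high:
            raise ValueError(f"NullResult lacks p-values for {m}")

    ph_obs = null.p_high["PE_obs"]
    ph_alt = null.p_high["PE_alt"]
    ph_rpe = null.p_high["RPE"]
    pl_rpe = null.p_low["RPE"]

    candidate = (ph_obs < alpha_primary) | (ph_alt < alpha_primary)
    category = np.full(len(candidate), "not_significant", dtype=object)
    paleo = candidate & (ph_rpe < alpha_rpe_tail)
    neo = candidate & ~paleo & (pl_rpe < alpha_rpe_tail)
    mixed = candidate & ~paleo & ~neo
    super_ = mixed & (ph_obs < alpha_super) & (ph_alt < alpha_super)
    category[paleo] = "paleo"
    category[neo] = "neo"
    category[mixed & ~super_] = "mixed"
    category[super_] = "super"
    return CanapeClassification(
        cell_ids=null.cell_ids.copy(),
        category=np.asarray(category),
        alpha_primary=alpha_primary,
        alpha_rpe_tail=alpha_rpe_tail,
        alpha_super=alpha_super,
    )
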