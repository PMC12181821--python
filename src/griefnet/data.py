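"""Core data containers and the instrument column registry.

The cohort table mirrors the study's assessment battery:

* TGI-SR+ — 22 prolonged-grief items rated 1 (never) to 5 (always);
* CAPS-5 — the clinician-rated PTSD items used by the ICD-11 algorithm
  (items 1, 2, 6, 7, 13, 17, 18, 24, 25 rated 0–4, plus item 22 recorded
  as a 0/1 "symptom duration satisfied" gate);
* COPISAC — five complex-PTSD add-on items CO1–CO5 rated 0–4;
* loss/trauma metadata — bereavement flag, months since the most
  distressing loss, and a Criterion-A trauma flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ItemResponseMatrix",
    "TGI_ITEMS",
    "CAPS_ITEMS",
    "COPISAC_ITEMS",
    "ITEM_COLUMNS",
    "META_COLUMNS",
    "ITEM_RANGES",
    "DICHOTOMOUS",
    "NODE_LABELS",
    "NODE_ITEMS",
    "NODE_COMMUNITIES",
    "scale_of",
]

TGI_ITEMS = tuple(f"TGI_{i:02d}" for i in range(1, 23))
CAPS_ITEMS = ("CAPS_01", "CAPS_02", "CAPS_06", "CAPS_07", "CAPS_13",
              "CAPS_17", "CAPS_18", "CAPS_22", "CAPS_24", "CAPS_25")
COPISAC_ITEMS = tuple(f"COPISAC_CO{i}" for i in range(1, 6))
ITEM_COLUMNS = TGI_ITEMS + CAPS_ITEMS + COPISAC_ITEMS
META_COLUMNS = ("MONTHS_SINCE_LOSS", "BEREAVED", "TRAUMA_A")

#: per-column (min, max) response range
ITEM_RANGES: dict[str, tuple[float, float]] = {
    **{c: (1, 5) for c in TGI_ITEMS},
    **{c: (0, 4) for c in CAPS_ITEMS},
    "CAPS_22": (0, 1),  # duration gate, stored dichotomous
    **{c: (0, 4) for c in COPISAC_ITEMS},
    "MONTHS_SINCE_LOSS": (0, np.inf),
    "BEREAVED": (0, 1),
    "TRAUMA_A": (0, 1),
}

DICHOTOMOUS = frozenset({"CAPS_22", "BEREAVED", "TRAUMA_A"})

#: the 13 network nodes: 7 PGD symptoms, then 6 cPTSD symptom clusters.
#: Four clusters are two-item sums; the rest are single items.
NODE_ITEMS: dict[str, tuple[str, ...]] = {
    "Pr": ("TGI_01",),                  # preoccupation
    "Ye": ("TGI_03",),                  # yearning
    "AL": ("TGI_05",),                  # difficulty accepting the loss
    "BA": ("TGI_08",),                  # bitterness / anger
    "ML": ("TGI_09",),                  # difficulty engaging in activities
    "Nu": ("TGI_10",),                  # emotional numbness
    "PD": ("TGI_21",),                  # lost a part of one's self
    "Re": ("CAPS_01", "CAPS_02"),       # re-experiencing
    "Av": ("CAPS_06", "CAPS_07"),       # avoidance
    "Th": ("CAPS_17", "CAPS_18"),       # sense of current threat
    "ad": ("COPISAC_CO1",),             # affective dysregulation
    "NSC": ("COPISAC_CO2",),            # negative self-concept
    "DR": ("COPISAC_CO3", "CAPS_13"),   # disturbances in relationships
}
NODE_LABELS = tuple(NODE_ITEMS)

NODE_COMMUNITIES: dict[str, str] = {
    **{k: "PGD" for k in ("Pr", "Ye", "AL", "BA", "ML", "Nu", "PD")},
    **{k: "cPTSD" for k in ("Re", "Av", "Th", "ad", "NSC", "DR")},
}


def scale_of(column: str) -> str:
    """Instrument a column belongs to (prefix before the first underscore)."""
    return column.split("_", 1)[0] if column in ITEM_COLUMNS else "META"


@dataclass
class ItemResponseMatrix:
    """Participants x items table with response ranges and a missingness mask.

    ``values`` is a float DataFrame; ``NaN`` marks a missing response.
    ``truth`` optionally carries the pre-masking values so that recovery
    against injected missingness can be evaluated.
    """

    values: pd.DataFrame
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(ITEM_RANGES))
    dichotomous: frozenset[str] = DICHOTOMOUS
    truth: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "ItemResponseMatrix":
        return ItemResponseMatrix(
            self.values.copy(), dict(self.ranges), self.dichotomous,
            None if self.truth is None else self.truth.copy(),
        )

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first out-of-range cell."""
        for col in self.values.columns:
            rng = self.ranges.get(col)
            if rng is None:
                continue
            v = self.values[col].dropna()
            bad = v[(v < rng[0]) | (v > rng[1])]
            if len(bad):
                i = bad.index[0]
                raise ValueError(
                    f"value {bad.iloc[0]!r} at row {i}, column {col!r} outside range {rng}"
                )
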