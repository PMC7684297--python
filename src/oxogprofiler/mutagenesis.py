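"""6-thioguanine (HPRT) induced-mutant-frequency metrics.

Cells that incorporate 6-TG through HPRT1 die; colonies surviving selection
carry inactivating HPRT1 mutations.  The induced mutant frequency divides
the resistant-colony yield per cell plated under selection by the plating
efficiency measured on the unselected control plate:

    frequency = (resistant / cells_plated_selected)
              / (control_colonies / cells_plated_control)

with the assay defaults of 1,000,000 cells under selection and 1,500 control
cells.  Condition effects are reported as fold changes of this frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .stats import fold_change

__all__ = ["ColonyAssay", "mutant_frequency", "frequency_fold", "read_assay_table",
           "frequency_table"]


@dataclass(frozen=True)
class ColonyAssay:
    """Colony counts for one 6-TG resistance assay."""

    resistant_colonies: int
    control_colonies: int
    cells_plated_selected: int = 1_000_000
    cells_plated_control: int = 1_500
    label: str = "sample"

    def __post_init__(self) -> None:
        if self.resistant_colonies < 0 or self.control_colonies < 0:
            raise ValueError("colony counts must be >= 0")
        if self.cells_plated_selected <= 0 or self.cells_plated_control <= 0:
            raise ValueError("plated cell counts must be positive")


def mutant_frequency(assay: ColonyAssay) -> float:
    """Induced mutant frequency, normalized by control plating efficiency."""
    if assay.control_colonies == 0:
        raise ValueError(
            f"{assay.label}: zero control colonies — plating efficiency undefined"
        )
    selected = assay.resistant_colonies / assay.cells_plated_selected
    efficiency = assay.control_colonies / assay.cells_plated_control
    return selected / efficiency


def frequency_fold(test: ColonyAssay, reference: ColonyAssay) -> float:
    """Ratio of induced mutant frequencies, test over reference."""
    ref = mutant_frequency(reference)
    if ref == 0:
        raise ValueError(
            f"{reference.label}: reference mutant frequency is zero — fold undefined"
        )
    return fold_change(mutant_frequency(test), ref)


def read_assay_table(path: str | Path) -> list[ColonyAssay]:
    """Read assays from TSV (label, resistant, plated_selected, control_colonies,
    plated_control); missing plated columns get the assay defaults."""
    frame = pd.read_csv(path, sep="\t")
    required = {"label", "resistant", "control_colonies"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    assays = []
    for row in frame.itertuples(index=False):
        kwargs = {}
        if "plated_selected" in frame.columns:
            kwargs["cells_plated_selected"] = int(row.plated_selected)
        if "plated_control" in frame.columns:
            kwargs["cells_plated_control"] = int(row.plated_control)
        assays.append(
            ColonyAssay(
                resistant_colonies=int(row.resistant),
                control_colonies=int(row.control_colonies),
                label=str(row.label),
                **kwargs,
            )
        )
    return assays


def frequency_table(assays: list[ColonyAssay], reference: str | None = None) -> pd.DataFrame:
    """Frequencies (and folds versus a named reference assay) as a DataFrame."""
    rows = []
    ref_assay = None
    if reference is not None:
        by_label = {a.label: a for a in assays}
        if reference not in by_label:
            raise ValueError(f"reference label {reference!r} not in table")
        ref_assay = by_label[reference]
    for assay in assays:
        row = {"label": assay.label, "mutant_frequency": mutant_frequency(assay)}
        if ref_assay is not None:
            row["fold_vs_" + ref_assay.label] = frequency_fold(assay, ref_assay)
        rows.append(row)
    return pd.DataFrame(rows)
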