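"""Response-to-water-deficit feature vectors: per-OTU DI/FI abundance ratios.

For a compartment with three deficit-irrigation (DI) and three
full-irrigation (FI) replicates, each OTU is described by the nine ratios
DI_i / FI_j taken over all replicate pairs, in lexicographic pair order
(DI1/FI1, DI1/FI2, DI1/FI3, DI2/FI1, ..., DI3/FI3).  Zero abundances are
replaced by a fixed positive value before dividing (default 1, i.e. a zero
numerator contributes 1/FI and a zero denominator contributes DI), so every
ratio is finite and positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import OtuTable, SampleDesign

__all__ = ["RatioMatrix", "compute_ratios"]


@dataclass(frozen=True)
class RatioMatrix:
    """OTU x (DI, FI) replicate-pair matrix of abundance ratios.

    ``data`` has OTU ids as index and pair labels ("DI1/FI1", ...) as
    columns; all entries are strictly positive.
    """

    data: pd.DataFrame
    compartment: str
    zero_replacement: float

    def __post_init__(self) -> None:
        if (self.data.to_numpy() <= 0).any():
            raise ValueError("ratio values must be strictly positive")

    @property
    def otu_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def pair_labels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_pairs(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")


def compute_ratios(
    table: OtuTable,
    design: SampleDesign,
    compartment: str,
    zero_replacement: float = 1.0,
) -> RatioMatrix:
    """Compute the all-pairs DI/FI ratio matrix for one compartment.

    The table may contain counts or relative abundances — the replacement
    value is applied to whichever is passed, so the choice of scale must be
    made (and is recorded) explicitly.
    """
    if zero_replacement <= 0:
        raise ValueError("zero_replacement must be positive")
    di = design.samples(compartment, "DI")
    fi = design.samples(compartment, "FI")
    if not di or not fi:
        raise ValueError(f"compartment {compartment!r} lacks DI or FI samples in the design")
    missing = [s for s in di + fi if s not in table.data.columns]
    if missing:
        raise ValueError(f"design samples missing from table: {missing}")

    di_vals = table.data.loc[:, di].to_numpy(dtype=float)
    fi_vals = table.data.loc[:, fi].to_numpy(dtype=float)
    if (di_vals < 0).any() or (fi_vals < 0).any():
        raise ValueError("negative abundances are not allowed")
    di_vals = np.where(di_vals == 0, zero_replacement, di_vals)
    fi_vals = np.where(fi_vals == 0, zero_replacement, fi_vals)

    # Lexicographic by (DI replicate, FI replicate): DI1/FI1, DI1/FI2, ...
    ratios = (di_vals[:, :, None] / fi_vals[:, None, :]).reshape(len(table.data), -1)
    labels = [
        f"DI{design.replicate_of(d)}/FI{design.replicate_of(f)}"
        for d in di for f in fi
    ]
    frame = pd.DataFrame(ratios, index=table.data.index, columns=labels)
    return RatioMatrix(frame, compartment=compartment, zero_replacement=zero_replacement)
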